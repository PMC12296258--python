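"""Shared geometry fixtures (session-scoped; lofting is the slow part)."""

import numpy as np
import pytest

from ornmorph.geometry import ContourStack, mesh_from_contours


def circle_contour(r_um: float, n: int = 64, center=(0.0, 0.0)) -> np.ndarray:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + r_um * np.cos(th), center[1] + r_um * np.sin(th)]
    )


def cylinder_stack(
    r_um: float, length_um: float, n: int = 64, spacing_um: float = 0.2
) -> ContourStack:
    """Circle contours in SBEM-like pixel units (5 x 5 x 40 nm voxels)."""
    ring_px = circle_contour(r_um, n) / 0.005
    stride = max(1, round(spacing_um / 0.04))
    top = round(length_um / 0.04)
    zs = list(range(0, top + 1, stride))
    if zs[-1] != top:
        zs.append(top)
    return ContourStack([(z, ring_px) for z in zs], (5, 5, 40), "cylinder")


@pytest.fixture(scope="session")
def unit_cube_mesh():
    sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
    return mesh_from_contours(ContourStack([(0, sq), (1, sq)], (1000, 1000, 1000)))


@pytest.fixture(scope="session")
def cylinder_mesh():
    """r = 0.5 µm, L = 10 µm, 64-gon contours every 0.2 µm."""
    return mesh_from_contours(cylinder_stack(0.5, 10.0))


@pytest.fixture(scope="session")
def annulus_pair():
    """Coaxial capped cylinders r_o = 0.5, r_i = 0.3, L = 5 µm."""
    outer = mesh_from_contours(cylinder_stack(0.5, 5.0))
    inner = mesh_from_contours(cylinder_stack(0.3, 5.0))
    return outer, inner
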