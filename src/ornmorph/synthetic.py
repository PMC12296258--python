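"""Parametric sensillum/dendrite geometry with analytic ground truth, and
simulated morphometric populations.

The generator stands in for a segmented EM volume: it emits the same
artifacts a segmentation pipeline would (serial-contour stacks, watertight
meshes, SWC skeletons) for archetypal outer-dendrite shapes — cylinders,
flattened sheets (gently curled, fully curled into tubes, split sheetlets,
mixed tube+wrap), sparsely branched trees — placed inside a tapered cuticle
shell, together with closed-form L/SA/V ground truth for every segment.

Population tables are sampled from the published per-category summary
statistics (truncated normals, so all metrics stay positive); derived
columns (V/L, SA/V, totals) are recomputed per row so the arithmetic
invariants hold exactly.

Geometry is emitted along the cuticle axis (+z, base at z = 0); contour
stacks use 5 x 5 x 40 nm voxel calibration with one contour every 0.2 µm
and 64 vertices per contour by default — resolution at which lofted-mesh
morphometrics agree with the closed forms to well under 2%.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from scipy import stats as sps

from . import reference as ref
from .axis import CuticleAxis, LandmarkSet
from .errors import GeometryError
from .geometry import ContourStack, mesh_from_contours
from .skeleton import SWC_DENDRITE, Skeleton

__all__ = [
    "ArchetypeSpec",
    "SegmentGeometry",
    "SyntheticNeuron",
    "SensillumScene",
    "make_archetype",
    "make_cuticle_shell",
    "make_sensillum",
    "make_dendrite_within_dendrite",
    "archetype_population",
    "sample_population",
    "substream",
]

PIXEL_NM = (5.0, 5.0, 40.0)  # SBEM-like calibration
PLANE_STEP_UM = 0.2
RING_VERTS = 64
DEFAULT_CUTICLE_LENGTH = 9.5  # µm, the mean printed cuticle length


def substream(seed: int, name: str) -> np.random.Generator:
    """Per-object random substream from a run seed and a stable name hash."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % 2**31, zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# Contour primitives (µm, in the section plane)
# ---------------------------------------------------------------------------


def _circle(r: float, center=(0.0, 0.0), n: int = RING_VERTS) -> np.ndarray:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + r * np.cos(th), center[1] + r * np.sin(th)]
    )


def _arc_strip(
    width: float,
    thickness: float,
    curl_angle: float,
    center=(0.0, 0.0),
    n: int = RING_VERTS,
    phase: float = 0.0,
) -> np.ndarray:
    """Cross-section of a sheet of given width bent over ``curl_angle`` rad.

    ``curl_angle`` -> 0 recovers a flat rectangle; 2π closes into a ring
    (use the hollow-pair annulus instead for closed tubes).
    """
    curl_angle = max(curl_angle, 1e-3)
    radius = width / curl_angle
    m = max(8, n // 2)
    th = np.linspace(-curl_angle / 2, curl_angle / 2, m) + phase
    r_out, r_in = radius + thickness / 2, radius - thickness / 2
    outer = np.column_stack([r_out * np.cos(th), r_out * np.sin(th)])
    inner = np.column_stack([r_in * np.cos(th[::-1]), r_in * np.sin(th[::-1])])
    pts = np.vstack([outer, inner])
    pts[:, 0] -= radius * np.cos(phase)  # center the strip on its chord
    pts[:, 1] -= radius * np.sin(phase)
    return pts + np.asarray(center)


def _stack(
    ring_fn,
    z_lo: float,
    z_hi: float,
    object_id: str,
    spacing: float = PLANE_STEP_UM,
) -> ContourStack:
    """Contour stack from a ``z -> (n, 2) µm ring`` function."""
    vz = PIXEL_NM[2] / 1000.0
    px = PIXEL_NM[0] / 1000.0
    i_lo = int(round(z_lo / vz))
    i_hi = int(round(z_hi / vz))
    stride = max(1, int(round(spacing / vz)))
    indices = list(range(i_lo, i_hi + 1, stride))
    if indices[-1] != i_hi:
        indices.append(i_hi)
    contours = [(i, ring_fn(i * vz) / px) for i in indices]
    return ContourStack(contours=contours, voxel_size_nm=PIXEL_NM, object_id=object_id)


def _transformed_stack_mesh(stack: ContourStack, transform: np.ndarray | None):
    mesh = mesh_from_contours(stack)
    if transform is not None:
        mesh.apply_transform(transform)
    return mesh


def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """4x4 rotation taking +z to ``direction``."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    z = np.array([0.0, 0.0, 1.0])
    if np.allclose(d, z):
        return np.eye(4)
    if np.allclose(d, -z):
        return trimesh.transformations.rotation_matrix(np.pi, [1, 0, 0])
    ax = np.cross(z, d)
    ang = float(np.arccos(np.clip(d @ z, -1.0, 1.0)))
    return trimesh.transformations.rotation_matrix(ang, ax)


# ---------------------------------------------------------------------------
# Dataclasses
# ---------------------------------------------------------------------------


@dataclass
class ArchetypeSpec:
    """Parameters of one synthetic dendrite (µm; proportions in (0, 1))."""

    kind: str  # cylinder | sheet | curled_tube | split_sheets | mixed | branched_tree
    length: float = 5.0  # distal segment length along the axis
    radius: float = 0.28  # proximal / cylinder radius
    width: float = 2.0  # sheet width
    thickness: float = 0.09  # sheet thickness
    r_outer: float = 0.37  # curled-tube outer radius
    r_inner: float = 0.28  # curled-tube inner radius
    n_branches: int = 1
    taper: float = 0.0
    fp: float = 0.40  # flattening / primary-branch proportion
    dt: float = 0.89  # terminus proportion
    proximal_length: float = 10.7
    branch_radius: float = 0.056
    branch_length: float = 6.0
    branch_tilt_deg: float = 8.0
    branch_fan_center_deg: float | None = None  # None: full-circle fan
    branch_fan_width_deg: float = 120.0
    curl_angle_deg: float = 100.0
    cuticle_length: float = DEFAULT_CUTICLE_LENGTH
    center: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in (
            "cylinder", "sheet", "curled_tube", "split_sheets", "mixed",
            "branched_tree", "cuticle_shell",
        ):
            raise GeometryError(f"unknown archetype kind {self.kind!r}")
        for name in ("length", "radius", "width", "thickness", "r_outer", "r_inner"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if not 0 < self.fp < 1 or not 0 < self.dt <= 1:
            raise GeometryError("fp/dt proportions must lie in (0, 1)")
        if not 1 <= self.n_branches <= 10:
            raise GeometryError("n_branches must be in 1..10")


@dataclass
class SegmentGeometry:
    """One measurable segment: meshes, hollow pairs, stacks, analytic truth."""

    name: str
    meshes: list = field(default_factory=list)
    hollow_pairs: list = field(default_factory=list)
    stacks: list = field(default_factory=list)
    length: float = 0.0
    surface_area: float = 0.0
    volume: float = 0.0


@dataclass
class SyntheticNeuron:
    neuron_id: str
    orn_type: str
    category: str
    segments: dict[str, SegmentGeometry]
    skeleton: Skeleton
    landmarks: LandmarkSet
    fp: float | None
    bp: float | None
    dt: float
    n_branches: int
    midpoint_components: int  # ground-truth branch count at proportion 0.5
    size: float  # combined soma + inner + outer dendrite surface area, µm²

    @property
    def all_meshes(self) -> tuple[list, list]:
        """(meshes, hollow_pairs) over all segments, for whole-neuron sections."""
        meshes, pairs = [], []
        for seg in self.segments.values():
            off = len(meshes)
            meshes.extend(seg.meshes)
            pairs.extend([(a + off, b + off) for a, b in seg.hollow_pairs])
        return meshes, pairs


@dataclass
class SensillumScene:
    scene_id: str
    cuticle_outer: "trimesh.Trimesh"
    cuticle_lumen: "trimesh.Trimesh"
    cuticle_axis: CuticleAxis
    cuticle_sa: float
    cuticle_v: float
    neurons: list[SyntheticNeuron]
    midpoint_count: int  # ground truth over all neurons


# ---------------------------------------------------------------------------
# Segment builders (analytic SA/V follow the capped-mesh convention)
# ---------------------------------------------------------------------------


def _cylinder_segment(
    name: str, r: float, z_lo: float, z_hi: float, center=(0.0, 0.0),
    transform: np.ndarray | None = None,
) -> SegmentGeometry:
    L = z_hi - z_lo
    stack = _stack(lambda z: _circle(r, center), z_lo, z_hi, name)
    mesh = _transformed_stack_mesh(stack, transform)
    return SegmentGeometry(
        name=name, meshes=[mesh], stacks=[stack], length=L,
        surface_area=2 * np.pi * r * L + 2 * np.pi * r**2,
        volume=np.pi * r**2 * L,
    )


def _sheet_segment(
    name: str, w: float, t: float, curl_deg: float, z_lo: float, z_hi: float,
    center=(0.0, 0.0),
) -> SegmentGeometry:
    L = z_hi - z_lo
    ang = np.deg2rad(curl_deg)
    stack = _stack(lambda z: _arc_strip(w, t, ang, center), z_lo, z_hi, name)
    mesh = _transformed_stack_mesh(stack, None)
    # a bent strip keeps the flat sheet's cross-section area w*t and
    # perimeter 2(w + t), so SA and V match the flat closed forms
    return SegmentGeometry(
        name=name, meshes=[mesh], stacks=[stack], length=L,
        surface_area=2 * (w * L + t * L + w * t),
        volume=w * t * L,
    )


def _curled_tube_segment(
    name: str, r_o: float, r_i: float, z_lo: float, z_hi: float, center=(0.0, 0.0),
) -> SegmentGeometry:
    L = z_hi - z_lo
    st_o = _stack(lambda z: _circle(r_o, center), z_lo, z_hi, f"{name}_outer")
    st_i = _stack(lambda z: _circle(r_i, center), z_lo, z_hi, f"{name}_inner")
    return SegmentGeometry(
        name=name,
        meshes=[mesh_from_contours(st_o), mesh_from_contours(st_i)],
        hollow_pairs=[(0, 1)],
        stacks=[st_o, st_i],
        length=L,
        surface_area=(2 * np.pi * r_o * L + 2 * np.pi * r_o**2)
        + (2 * np.pi * r_i * L + 2 * np.pi * r_i**2),
        volume=np.pi * (r_o**2 - r_i**2) * L,
    )


def _split_segment(
    name: str, w: float, t: float, z_lo: float, z_hi: float, center=(0.0, 0.0),
    gap: float = 0.3,
) -> SegmentGeometry:
    L = z_hi - z_lo
    w_half = w / 2
    seg = SegmentGeometry(name=name, length=L)
    for k, dx in enumerate((-(w_half + gap) / 2, (w_half + gap) / 2)):
        c = (center[0] + dx, center[1])
        st = _stack(
            lambda z, c=c: _arc_strip(w_half, t, np.deg2rad(30), c),
            z_lo, z_hi, f"{name}_{k}",
        )
        seg.meshes.append(mesh_from_contours(st))
        seg.stacks.append(st)
        seg.surface_area += 2 * (w_half * L + t * L + w_half * t)
        seg.volume += w_half * t * L
    return seg


def _mixed_segment(
    name: str, w: float, t: float, z_lo: float, z_hi: float, center=(0.0, 0.0),
) -> SegmentGeometry:
    """Fully curled tube plus a sheetlet wrapping around it."""
    L = z_hi - z_lo
    r_mid = (w / 2) / (2 * np.pi)  # half the sheet closes into the tube
    r_o, r_i = r_mid + t / 2, r_mid - t / 2
    tube = _curled_tube_segment(f"{name}_tube", r_o, r_i, z_lo, z_hi, center)
    wrap_r = r_o + 0.15
    wrap_ang = np.deg2rad(200)
    wrap_w = wrap_r * wrap_ang
    st_w = _stack(
        lambda z: _arc_strip(wrap_w, t, wrap_ang, center)
        + np.array([wrap_r, 0.0]),  # re-center the wrap on the tube
        z_lo, z_hi, f"{name}_wrap",
    )
    seg = SegmentGeometry(
        name=name,
        meshes=tube.meshes + [mesh_from_contours(st_w)],
        hollow_pairs=[(0, 1)],
        stacks=tube.stacks + [st_w],
        length=L,
        surface_area=tube.surface_area + 2 * (wrap_w * L + t * L + wrap_w * t),
        volume=tube.volume + wrap_w * t * L,
    )
    return seg


# ---------------------------------------------------------------------------
# Archetype assembly
# ---------------------------------------------------------------------------

_CATEGORY_KINDS = {
    "loosely_curled": "sheet",
    "fully_curled": "curled_tube",
    "split": "split_sheets",
    "mixed": "mixed",
}
_KIND_CATEGORIES = {v: k for k, v in _CATEGORY_KINDS.items()}


def make_archetype(spec: ArchetypeSpec, neuron_id: str = "n0", orn_type: str = "") -> SyntheticNeuron:
    """Build one synthetic neuron (meshes + stacks + skeleton + ground truth).

    The neuron lives in the cuticle frame: axis along +z, base at z = 0.
    A proximal cylinder runs from the ciliary constriction (below the base)
    to the flattening/branch point; the distal segment takes the archetype's
    shape up to the terminus.
    """
    Lc = spec.cuticle_length
    cx, cy = spec.center
    z_dt = spec.dt * Lc

    if spec.kind == "cylinder":
        z_cc = z_dt - spec.length
        seg = _cylinder_segment("total", spec.radius, z_cc, z_dt, (cx, cy))
        skel = Skeleton.from_points(
            [[cx, cy, z_cc], [cx, cy, (z_cc + z_dt) / 2], [cx, cy, z_dt]],
            radius=spec.radius,
        )
        return SyntheticNeuron(
            neuron_id=neuron_id, orn_type=orn_type, category="unbranched",
            segments={"total": seg}, skeleton=skel,
            landmarks=LandmarkSet(
                ciliary_constriction=np.array([cx, cy, z_cc]),
                dendritic_termini=[np.array([cx, cy, z_dt])],
            ),
            fp=None, bp=None, dt=spec.dt, n_branches=1,
            midpoint_components=int(z_cc < 0.5 * Lc < z_dt),
            size=seg.surface_area,
        )

    if spec.kind == "branched_tree":
        z_bp = spec.fp * Lc
        z_cc = z_bp - spec.proximal_length
        prox = _cylinder_segment("proximal", spec.radius, z_cc, z_bp, (cx, cy))
        rng = substream(spec.seed, neuron_id)
        distal = SegmentGeometry(name="distal")
        nodes = [[cx, cy, z_cc], [cx, cy, z_bp]]
        parents = [-1, 1]
        termini = []
        tilt = np.deg2rad(spec.branch_tilt_deg)
        for k in range(spec.n_branches):
            if spec.branch_fan_center_deg is None:
                az = 2 * np.pi * k / spec.n_branches + float(rng.uniform(0, 0.3))
            else:
                frac = k / max(spec.n_branches - 1, 1) - 0.5
                az = np.deg2rad(
                    spec.branch_fan_center_deg + frac * spec.branch_fan_width_deg
                )
            d = np.array(
                [np.sin(tilt) * np.cos(az), np.sin(tilt) * np.sin(az), np.cos(tilt)]
            )
            Lb = spec.branch_length
            rb = spec.branch_radius
            st = _stack(lambda z: _circle(rb), 0.0, Lb, f"{neuron_id}_b{k}")
            T = np.eye(4)
            T[:3, 3] = [cx, cy, z_bp]
            T = T @ _rotation_to(d)
            distal.meshes.append(_transformed_stack_mesh(st, T))
            distal.stacks.append(st)
            distal.length += Lb
            distal.surface_area += 2 * np.pi * rb * Lb + 2 * np.pi * rb**2
            distal.volume += np.pi * rb**2 * Lb
            end = np.array([cx, cy, z_bp]) + d * Lb
            nodes.append(end.tolist())
            parents.append(2)
            termini.append(end)
        skel = Skeleton(
            ids=np.arange(1, len(nodes) + 1),
            type_codes=np.full(len(nodes), SWC_DENDRITE),
            xyz=np.asarray(nodes),
            radius=np.full(len(nodes), spec.branch_radius),
            parent_ids=np.asarray(parents),
        )
        dt_prop = float(termini[0][2] / Lc) if termini else spec.fp
        mid_z = 0.5 * Lc
        if z_cc < mid_z <= z_bp:
            mid_n = 1
        elif z_bp < mid_z < max(t[2] for t in termini):
            mid_n = spec.n_branches
        else:
            mid_n = 0
        return SyntheticNeuron(
            neuron_id=neuron_id, orn_type=orn_type, category="branched",
            segments={"proximal": prox, "distal": distal}, skeleton=skel,
            landmarks=LandmarkSet(
                ciliary_constriction=np.array([cx, cy, z_cc]),
                primary_branch_point=np.array([cx, cy, z_bp]),
                dendritic_termini=termini,
            ),
            fp=None, bp=spec.fp, dt=dt_prop, n_branches=spec.n_branches,
            midpoint_components=mid_n,
            size=prox.surface_area + distal.surface_area,
        )

    # flattened-sheet archetypes (the CO2-sensing morphologies)
    category = _KIND_CATEGORIES[spec.kind]
    z_fp = spec.fp * Lc
    z_cc = z_fp - spec.proximal_length
    prox = _cylinder_segment("proximal", spec.radius, z_cc, z_fp, (cx, cy))
    if spec.kind == "sheet":
        distal = _sheet_segment(
            "distal", spec.width, spec.thickness, spec.curl_angle_deg,
            z_fp, z_dt, (cx, cy),
        )
    elif spec.kind == "curled_tube":
        distal = _curled_tube_segment(
            "distal", spec.r_outer, spec.r_inner, z_fp, z_dt, (cx, cy)
        )
    elif spec.kind == "split_sheets":
        distal = _split_segment(
            "distal", spec.width, spec.thickness, z_fp, z_dt, (cx, cy)
        )
    else:  # mixed
        distal = _mixed_segment(
            "distal", spec.width, spec.thickness, z_fp, z_dt, (cx, cy)
        )
    skel = Skeleton.from_points(
        [[cx, cy, z_cc], [cx, cy, z_fp], [cx, cy, z_dt]], radius=spec.radius
    )
    return SyntheticNeuron(
        neuron_id=neuron_id, orn_type=orn_type, category=category,
        segments={"proximal": prox, "distal": distal}, skeleton=skel,
        landmarks=LandmarkSet(
            ciliary_constriction=np.array([cx, cy, z_cc]),
            flattening_point=np.array([cx, cy, z_fp]),
            dendritic_termini=[np.array([cx, cy, z_dt])],
        ),
        fp=spec.fp, bp=None, dt=spec.dt,
        n_branches=2 if spec.kind == "split_sheets" else 1,
        midpoint_components=(
            (2 if spec.kind in ("split_sheets", "mixed") else 1)
            if z_fp < 0.5 * Lc < z_dt
            else int(z_cc < 0.5 * Lc < z_dt)
        ),
        size=prox.surface_area + distal.surface_area,
    )


def make_cuticle_shell(
    length: float = DEFAULT_CUTICLE_LENGTH,
    r_base: float = 1.45,
    r_tip: float = 1.05,
    thickness: float = 0.15,
) -> tuple[trimesh.Trimesh, trimesh.Trimesh, CuticleAxis, float, float]:
    """Tapered hollow cuticle shell.

    Returns ``(outer_mesh, lumen_mesh, axis, sa, v)`` where ``sa``/``v``
    are the analytic hollow-pair values of the shell wall.
    """

    def radius_at(z: float, r0: float, r1: float) -> float:
        return r0 + (r1 - r0) * z / length

    st_o = _stack(lambda z: _circle(radius_at(z, r_base, r_tip)), 0.0, length, "cuticle")
    st_i = _stack(
        lambda z: _circle(radius_at(z, r_base - thickness, r_tip - thickness)),
        0.0, length, "lumen",
    )
    outer = mesh_from_contours(st_o)
    lumen = mesh_from_contours(st_i)
    axis = CuticleAxis(np.array([[0.0, 0.0, 0.0], [0.0, 0.0, length]]))

    def frustum(r0, r1):
        slant = np.hypot(length, r0 - r1)
        lateral = np.pi * (r0 + r1) * slant
        caps = np.pi * (r0**2 + r1**2)
        vol = np.pi * length * (r0**2 + r0 * r1 + r1**2) / 3
        return lateral + caps, vol

    sa_o, v_o = frustum(r_base, r_tip)
    sa_i, v_i = frustum(r_base - thickness, r_tip - thickness)
    return outer, lumen, axis, sa_o + sa_i, v_o - v_i


# ---------------------------------------------------------------------------
# Scenes
# ---------------------------------------------------------------------------

_DEFAULT_SCENE = [
    # orn_type, spec kwargs, azimuth (deg), radial offset (µm), soma+ID SA
    ("ab1A", dict(kind="branched_tree", n_branches=6, fp=0.18, radius=0.17,
                  branch_radius=0.07, branch_length=6.5, proximal_length=5.0,
                  branch_tilt_deg=3.0, branch_fan_center_deg=0.0), 0, 0.5, 96.7),
    ("ab1B", dict(kind="branched_tree", n_branches=4, fp=0.25, radius=0.16,
                  branch_radius=0.07, branch_length=6.0, proximal_length=5.0,
                  branch_tilt_deg=3.0, branch_fan_center_deg=90.0), 90, 0.5, 87.6),
    ("ab1C", dict(kind="sheet", width=0.8, thickness=0.09, fp=0.40, dt=0.89,
                  radius=0.22, proximal_length=6.5, curl_angle_deg=100.0), 180, 0.5, 35.2),
    ("ab1D", dict(kind="branched_tree", n_branches=3, fp=0.21, radius=0.147,
                  branch_radius=0.056, branch_length=6.0, proximal_length=4.0,
                  branch_tilt_deg=3.0, branch_fan_center_deg=270.0), 270, 0.5, 12.8),
]


def make_sensillum(
    neuron_specs: list[tuple] | None = None, seed: int = 0, scene_id: str = "s0"
) -> SensillumScene:
    """Assemble a sensillum scene: cuticle shell plus 2-4 neurons.

    ``neuron_specs`` rows are ``(orn_type, spec_kwargs, azimuth_deg,
    radial_offset, soma_id_sa)``; the default scene holds the four-neuron
    complement at the published size rank (largest to smallest:
    A > B > C > D).  Neurons are placed at distinct azimuths inside the
    lumen; a cross-section overlap check rejects unpackable scenes.
    """
    specs = neuron_specs if neuron_specs is not None else _DEFAULT_SCENE
    if not 2 <= len(specs) <= 4:
        raise GeometryError("a sensillum houses 2-4 neurons")
    outer, lumen, axis, cut_sa, cut_v = make_cuticle_shell()
    neurons = []
    for orn_type, kwargs, az_deg, offset, soma_sa in specs:
        az = np.deg2rad(az_deg)
        center = (offset * np.cos(az), offset * np.sin(az))
        spec = ArchetypeSpec(center=center, seed=seed, **kwargs)
        n = make_archetype(spec, neuron_id=f"{scene_id}_{orn_type}", orn_type=orn_type)
        n.size += soma_sa
        neurons.append(n)
    _check_packing(neurons)
    return SensillumScene(
        scene_id=scene_id,
        cuticle_outer=outer, cuticle_lumen=lumen, cuticle_axis=axis,
        cuticle_sa=cut_sa, cuticle_v=cut_v,
        neurons=neurons,
        midpoint_count=sum(n.midpoint_components for n in neurons),
    )


def _check_packing(neurons: list[SyntheticNeuron]) -> None:
    """Reject scenes whose neurons' cross-sections overlap."""
    from .geometry import combined_section_polygons
    import shapely

    stations = np.linspace(1.0, 8.0, 4)
    geoms_per_neuron = []
    for n in neurons:
        meshes, pairs = n.all_meshes
        geoms = [
            shapely.union_all(
                combined_section_polygons(
                    meshes, pairs, np.array([0.0, 0.0, z]), np.array([0.0, 0.0, 1.0])
                )
            )
            for z in stations
        ]
        geoms_per_neuron.append(geoms)
    for i in range(len(neurons)):
        for j in range(i + 1, len(neurons)):
            for gi, gj in zip(geoms_per_neuron[i], geoms_per_neuron[j]):
                inter = gi.intersection(gj).area
                if inter > 1e-6:
                    raise GeometryError(
                        f"neurons {neurons[i].neuron_id} and "
                        f"{neurons[j].neuron_id} interpenetrate "
                        f"({inter:.2g} µm² overlap)"
                    )


def make_dendrite_within_dendrite(seed: int = 0) -> SensillumScene:
    """Scene with a fully curled sheet enclosing two neighboring branches.

    The enclosing tube's cross-section is a ring; the neighbors' thin
    branches run inside the ring's lumen, so at the midpoint the tube
    contributes one membrane-bounded component and each enclosed branch its
    own.
    """
    outer, lumen, axis, cut_sa, cut_v = make_cuticle_shell()
    tube = make_archetype(
        ArchetypeSpec(kind="curled_tube", r_outer=0.37, r_inner=0.30,
                      fp=0.35, dt=0.90, radius=0.28, proximal_length=6.0,
                      center=(0.0, 0.0), seed=seed),
        neuron_id="dwd_ab1C", orn_type="ab1C",
    )
    inner_neurons = []
    for k, dx in enumerate((-0.1, 0.1)):
        n = make_archetype(
            ArchetypeSpec(kind="cylinder", radius=0.05, length=9.0, dt=0.95,
                          center=(dx, 0.0), seed=seed),
            neuron_id=f"dwd_inner{k}", orn_type="ab1A",
        )
        inner_neurons.append(n)
    neurons = [tube, *inner_neurons]
    # ground truth at midpoint: ring + 2 enclosed branches
    return SensillumScene(
        scene_id="dwd",
        cuticle_outer=outer, cuticle_lumen=lumen, cuticle_axis=axis,
        cuticle_sa=cut_sa, cuticle_v=cut_v,
        neurons=neurons,
        midpoint_count=sum(n.midpoint_components for n in neurons),
    )


# ---------------------------------------------------------------------------
# Archetype populations (geometry-level)
# ---------------------------------------------------------------------------


def archetype_population(
    counts: dict[str, int] | None = None,
    seed: int = 0,
    orn_type: str = "ab1C",
) -> list[SyntheticNeuron]:
    """Population of sheet archetypes with per-neuron parameter variation.

    Category counts default to the published ab1C distribution
    (13 loosely curled / 5 fully curled / 4 split / 3 mixed).  Flattening
    points are drawn from the published range, termini likewise; sheet
    dimensions vary a few percent around their defaults.
    """
    counts = counts or ref.AB1C_CATEGORY_COUNTS
    neurons = []
    k = 0
    for category, n_cat in counts.items():
        for _ in range(n_cat):
            nid = f"{orn_type}_{k:02d}"
            rng = substream(seed, nid)
            fp = float(np.clip(rng.normal(0.40, 0.10), *ref.AB1C_FLATTENING["range"]))
            dt = float(np.clip(rng.normal(0.89, 0.08), *ref.AB1C_TERMINUS["range"]))
            dt = max(dt, fp + 0.15)  # keep a measurable flattened span
            spec = ArchetypeSpec(
                kind=_CATEGORY_KINDS[category],
                fp=fp, dt=dt,
                radius=float(rng.normal(0.28, 0.015)),
                width=float(rng.normal(2.0, 0.12)),
                thickness=float(rng.normal(0.09, 0.006)),
                r_outer=float(rng.normal(0.37, 0.02)),
                r_inner=float(rng.normal(0.28, 0.015)),
                proximal_length=float(rng.normal(10.7, 0.9)),
                curl_angle_deg=float(rng.uniform(60, 120)),
                seed=seed,
            )
            neurons.append(make_archetype(spec, neuron_id=nid, orn_type=orn_type))
            k += 1
    return neurons


def ab1d_population(
    counts: dict[str, int] | None = None, seed: int = 0
) -> list[SyntheticNeuron]:
    """Population of unbranched/branched tree archetypes (default 8/13)."""
    counts = counts or ref.AB1D_CATEGORY_COUNTS
    neurons = []
    k = 0
    for category, n_cat in counts.items():
        for _ in range(n_cat):
            nid = f"ab1D_{k:02d}"
            rng = substream(seed, nid)
            if category == "unbranched":
                spec = ArchetypeSpec(
                    kind="cylinder",
                    radius=float(rng.normal(0.113, 0.008)),
                    length=float(rng.normal(17.47, 1.85)),
                    dt=float(np.clip(rng.normal(0.91, 0.08), 0.63, 0.97)),
                    seed=seed,
                )
            else:
                spec = ArchetypeSpec(
                    kind="branched_tree",
                    n_branches=int(rng.integers(2, 8)),
                    fp=float(np.clip(rng.normal(0.21, 0.10), 0.08, 0.44)),
                    radius=float(rng.normal(0.147, 0.01)),
                    proximal_length=float(rng.normal(8.94, 1.1)),
                    branch_radius=float(rng.normal(0.056, 0.003)),
                    branch_length=float(rng.normal(6.0, 0.6)),
                    seed=seed,
                )
            neurons.append(make_archetype(spec, neuron_id=nid, orn_type="ab1D"))
            k += 1
    return neurons


# ---------------------------------------------------------------------------
# Metric-level population sampling
# ---------------------------------------------------------------------------


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal(mean, sd) truncated below at 0 (degenerate sd -> constant)."""
    if mean <= 0:
        raise GeometryError("truncated-normal mean must be positive")
    if sd == 0:
        return np.full(n, mean)
    a = (0.0 - mean) / sd
    return sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def sample_population(
    orn_type: str = "ab1C",
    counts: dict[str, int] | None = None,
    seed: int = 0,
    summary_spec: dict | None = None,
) -> pd.DataFrame:
    """Sample a per-neuron morphometric table from summary statistics.

    L, SA and V of the proximal and distal segments (or the total, where a
    category has no segment split) are drawn independently from truncated
    normals at the published per-category mean ± SD; totals and the derived
    V/L and SA/V columns are recomputed per row, so the within-row
    arithmetic identities hold exactly while column means match the
    generator specification.
    """
    if summary_spec is None:
        if orn_type == "ab1C":
            summary_spec = ref.AB1C_SEGMENTS
            counts = counts or ref.AB1C_CATEGORY_COUNTS
        elif orn_type == "ab1D":
            summary_spec = ref.AB1D_SEGMENTS
            counts = counts or ref.AB1D_CATEGORY_COUNTS
        else:
            raise ValueError(f"no built-in summary for {orn_type!r}")
    if counts is None:
        raise ValueError("category counts required with a custom summary_spec")
    rows = []
    k = 0
    for category, n_cat in counts.items():
        spec = summary_spec[category]
        for _ in range(n_cat):
            nid = f"{orn_type}_{k:02d}"
            rng = substream(seed, nid)
            row = {"neuron_id": nid, "orn_type": orn_type, "category": category}
            for segment in ("proximal", "distal"):
                if segment not in spec:
                    continue
                for metric in ("length", "surface_area", "volume"):
                    m, s = spec[segment][metric]
                    row[f"{segment}_{metric}"] = float(
                        _truncated_normal(rng, m, s, 1)[0]
                    )
            if "proximal" in spec and "distal" in spec:
                for metric in ("length", "surface_area", "volume"):
                    row[f"total_{metric}"] = (
                        row[f"proximal_{metric}"] + row[f"distal_{metric}"]
                    )
            else:
                for metric in ("length", "surface_area", "volume"):
                    m, s = spec["total"][metric]
                    row[f"total_{metric}"] = float(_truncated_normal(rng, m, s, 1)[0])
            for segment in ("proximal", "distal", "total"):
                if f"{segment}_length" in row:
                    row[f"{segment}_volume_per_length"] = (
                        row[f"{segment}_volume"] / row[f"{segment}_length"]
                    )
                    row[f"{segment}_sa_to_v"] = (
                        row[f"{segment}_surface_area"] / row[f"{segment}_volume"]
                    )
            rows.append(row)
            k += 1
    return pd.DataFrame(rows)
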