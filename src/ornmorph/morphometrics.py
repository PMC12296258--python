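"""Per-segment and population morphometrics.

Each dendritic segment is summarized by length L (µm), surface area SA
(µm²), volume V (µm³) and the derived quantities V/L (µm², the mean
cross-sectional area) and SA/V (µm⁻¹).  Branched segments sum L, SA and V
over branches before deriving the ratios.  Population columns are reduced to
mean, sample SD and the coefficient of variation CV = SD/mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import trimesh

from . import geometry
from .axis import CuticleAxis
from .errors import AmbiguousRankError, GeometryError, StatisticsError
from .skeleton import Skeleton, skeleton_length

__all__ = [
    "SegmentMorphometrics",
    "NeuronRecord",
    "PopulationSummary",
    "segment_morphometrics",
    "summed_morphometrics",
    "population_summary",
    "percent_change",
    "fold_range",
    "midpoint_branch_count",
    "assign_orn_identities",
    "round_half_away",
]


@dataclass(frozen=True)
class SegmentMorphometrics:
    """L, SA, V and derived V/L, SA/V for one dendritic segment."""

    length: float  # µm
    surface_area: float  # µm²
    volume: float  # µm³

    @property
    def volume_per_length(self) -> float:
        """Mean cross-sectional area, µm²."""
        return self.volume / self.length

    @property
    def sa_to_v(self) -> float:
        """Surface-area-to-volume ratio, µm⁻¹."""
        return self.surface_area / self.volume

    def __post_init__(self) -> None:
        if self.length <= 0 or self.surface_area <= 0 or self.volume <= 0:
            raise GeometryError("segment morphometrics must be strictly positive")


@dataclass
class NeuronRecord:
    """Per-neuron morphometrics row: segments, category, landmark positions."""

    neuron_id: str
    orn_type: str
    total: SegmentMorphometrics
    proximal: SegmentMorphometrics | None = None
    distal: SegmentMorphometrics | None = None
    category: str | None = None
    landmarks: dict | None = None  # landmark name -> cuticle proportion
    n_branches: int | None = None


@dataclass(frozen=True)
class PopulationSummary:
    mean: float
    sd: float
    cv: float
    n: int


def segment_morphometrics(
    meshes: list[trimesh.Trimesh],
    skeleton: Skeleton | float,
    hollow_pairs: list[tuple[int, int]] | None = None,
) -> SegmentMorphometrics:
    """Measure one dendritic segment from its meshes and skeleton.

    ``hollow_pairs`` lists ``(outer_index, inner_index)`` mesh pairs for
    tube-like objects whose enclosed lumen was segmented as a separate inner
    object: their volume is outer minus inner, their surface outer plus
    inner.  All remaining meshes contribute their plain SA and V.  Length
    comes from the segment skeleton (or is passed directly as a float).
    """
    hollow_pairs = hollow_pairs or []
    paired = {i for pair in hollow_pairs for i in pair}
    sa = v = 0.0
    for i_out, i_in in hollow_pairs:
        s, vol = geometry.hollow_morphometrics(meshes[i_out], meshes[i_in])
        sa += s
        v += vol
    for i, mesh in enumerate(meshes):
        if i in paired:
            continue
        sa += geometry.surface_area(mesh)
        v += geometry.volume(mesh)
    length = skeleton if isinstance(skeleton, (int, float)) else skeleton_length(skeleton)
    if length <= 0:
        raise GeometryError("segment has zero length")
    return SegmentMorphometrics(length=float(length), surface_area=sa, volume=v)


def summed_morphometrics(
    branches: list[SegmentMorphometrics],
) -> SegmentMorphometrics:
    """Combine branch segments: component-wise sums of L, SA, V.

    The derived ratios follow from the sums (V/L = ΣV/ΣL, SA/V = ΣSA/ΣV),
    matching the convention of summing branch values before deriving.
    """
    if not branches:
        raise GeometryError("cannot sum an empty branch list")
    return SegmentMorphometrics(
        length=sum(b.length for b in branches),
        surface_area=sum(b.surface_area for b in branches),
        volume=sum(b.volume for b in branches),
    )


def population_summary(values) -> PopulationSummary:
    """Mean, sample SD (n-1 denominator) and CV of a metric column.

    Raises
    ------
    StatisticsError
        For n < 2, where SD and CV are undefined.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if len(arr) < 2:
        raise StatisticsError("population SD/CV undefined for n < 2")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return PopulationSummary(mean=mean, sd=sd, cv=sd / mean, n=len(arr))


def percent_change(reference: float, value: float) -> float:
    """Signed percent change of ``value`` relative to ``reference``."""
    if reference <= 0:
        raise ValueError("percent_change requires a positive reference")
    return 100.0 * (value - reference) / reference


def fold_range(minimum: float, maximum: float) -> float:
    """max/min fold span of a metric across a population."""
    if minimum <= 0:
        raise ValueError("fold_range requires a positive minimum")
    return maximum / minimum


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero, the convention used for printed values."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def midpoint_branch_count(
    dendrite_objects: list[tuple[list[trimesh.Trimesh], list[tuple[int, int]]]],
    lumen_mesh: trimesh.Trimesh,
    axis: CuticleAxis,
    proportion: float = 0.5,
) -> tuple[int, float]:
    """Count dendritic branches at the cuticle midpoint.

    A plane is placed at the given cuticle proportion (default 0.5),
    perpendicular to the local axis tangent.  Each dendrite object is a
    ``(meshes, hollow_pairs)`` bundle; its branch count at the plane is the
    number of membrane-bounded cross-section components (outer loops), holes
    excluded — an enclosed lumen is sensillum lymph, not a dendrite.

    Returns
    -------
    (n_dendrites, lumen_area)
        Total branch count and the net cross-sectional area (µm²) of the
        sensillum lumen at the same plane.

    Raises
    ------
    GeometryError
        If the plane misses the sensillum lumen.
    """
    point = axis.point_at(proportion)
    normal = axis.tangent_at(proportion)
    lumen_sec = geometry.cross_section(lumen_mesh, point, normal)
    if lumen_sec.is_empty:
        raise GeometryError("midpoint plane misses the sensillum lumen")
    n = 0
    for meshes, hollow_pairs in dendrite_objects:
        polys = geometry.combined_section_polygons(meshes, hollow_pairs, point, normal)
        n += len(polys)
    return n, float(lumen_sec.net_area)


def assign_orn_identities(
    sizes: list[tuple[str, float]], tie_tolerance: float = 0.01
) -> dict[str, str]:
    """Assign A/B/C/D identities by descending neuron size.

    Within a sensillum the rank order of neuron sizes tracks relative
    extracellular spike amplitudes, so identities follow from sizes alone.

    Raises
    ------
    AmbiguousRankError
        When two sizes differ by less than ``tie_tolerance`` (relative).
    """
    if not 1 <= len(sizes) <= 4:
        raise ValueError("expected 1-4 neurons per sensillum")
    ordered = sorted(sizes, key=lambda kv: -kv[1])
    for (id1, s1), (id2, s2) in zip(ordered, ordered[1:]):
        if s1 <= 0 or (s1 - s2) / s1 < tie_tolerance:
            raise AmbiguousRankError(
                f"sizes of {id1} and {id2} within {tie_tolerance:.0%}: "
                f"{s1:.3g} vs {s2:.3g}"
            )
    return {nid: label for (nid, _), label in zip(ordered, "ABCD")}
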