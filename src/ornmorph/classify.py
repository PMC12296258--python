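"""Operational morphology categories for outer dendrites.

CO2-sensing (ab1C-like) dendrites flatten into sheets partway up the
sensillum; the sheets occur as four qualitative forms — loosely curled
(single gently curved sheet), fully curled (ring/tube enclosing neighboring
branches), split (two or more sheetlets) and mixed (both curl and split
features).  This module turns those visual categories into reproducible
rules over cross-section profiles sampled along the cuticle axis:

* a station is *flattened* when its largest component is elongated
  (principal-extent aspect ratio >= threshold), or shows self-enclosure
  (a ring profile — a sheet so fully curled it closed on itself), or is
  split into multiple components; rings and split sheetlets are flattened
  sheets by construction even though a closed ring has aspect ratio ~1;
* the flattening point FP is the first station whose flattening evidence is
  sustained over a persistence window of arc length;
* over the flattened span, *curl evidence* is the fraction of stations with
  self-enclosure and *split evidence* the fraction with >= 2 components;
  mixed takes precedence when both exceed the persistence fraction.

Odor-sensing (ab1D-like) dendrites are classified from skeleton topology
alone: branched iff the outer-dendrite skeleton has a branch point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh

from .axis import CuticleAxis
from .errors import GeometryError
from .geometry import combined_section_polygons
from .skeleton import Skeleton, branch_summary

__all__ = [
    "CrossSectionProfile",
    "profile_along_axis",
    "detect_flattening_point",
    "classify_ab1C",
    "classify_ab1D",
    "category_distribution",
    "AB1C_CATEGORIES",
]

AB1C_CATEGORIES = ("loosely_curled", "fully_curled", "split", "mixed")

DEFAULT_ASPECT_THRESHOLD = 2.0  # separates ~1:1 cylinders from sheets
DEFAULT_PERSISTENCE_UM = 0.5  # µm of arc a transition must be sustained
DEFAULT_EVIDENCE_FRACTION = 0.10  # of the flattened span


@dataclass(frozen=True)
class CrossSectionProfile:
    """Shape descriptors of one neuron's cross-section at one axis station."""

    station: float  # cuticle proportion
    n_components: int  # membrane-bounded components (outer loops)
    has_enclosure: bool  # any component encloses a lumen hole
    aspect_ratio: float  # max/min principal extent of the largest component
    area: float  # net µm²


def _aspect_ratio(poly) -> float:
    """Max/min principal-component extent of a section polygon's vertices."""
    pts = np.asarray(poly.exterior.coords)[:-1]
    pts = pts - pts.mean(axis=0)
    cov = pts.T @ pts / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    proj = pts @ evecs
    extents = proj.max(axis=0) - proj.min(axis=0)
    lo, hi = sorted(extents)
    return float(hi / max(lo, 1e-9))


def profile_along_axis(
    meshes: list[trimesh.Trimesh] | trimesh.Trimesh,
    axis: CuticleAxis,
    step: float = 0.02,
    hollow_pairs: list[tuple[int, int]] | None = None,
    start: float = 0.0,
) -> list[CrossSectionProfile]:
    """Cross-section profiles of one neuron from the cuticle base upward.

    Stations run from ``start`` (default the cuticle base, proportion 0) to
    the dendritic terminus: sampling stops after the sections run out.

    Raises
    ------
    GeometryError
        If the dendrite yields no section at any station (entirely below
        base) or ``step`` is outside (0, 0.1].
    """
    if not 0 < step <= 0.1:
        raise GeometryError("profile step must be in (0, 0.1]")
    if isinstance(meshes, trimesh.Trimesh):
        meshes = [meshes]
    hollow_pairs = hollow_pairs or []
    profiles: list[CrossSectionProfile] = []
    station = start
    misses = 0
    while station <= 1.0 + 1e-9 and misses < 2:
        point = axis.point_at(station)
        normal = axis.tangent_at(station)
        polys = combined_section_polygons(meshes, hollow_pairs, point, normal)
        if not polys:
            misses += 1 if profiles else 0
            station += step
            continue
        misses = 0
        largest = max(polys, key=lambda p: p.area)
        profiles.append(
            CrossSectionProfile(
                station=round(station, 9),
                n_components=len(polys),
                has_enclosure=any(len(p.interiors) > 0 for p in polys),
                aspect_ratio=_aspect_ratio(largest),
                area=float(sum(p.area for p in polys)),
            )
        )
        station += step
    if not profiles:
        raise GeometryError("dendrite produced no cross-section above the base")
    return profiles


def _is_flattened(
    p: CrossSectionProfile, aspect_threshold: float
) -> bool:
    return (
        p.aspect_ratio >= aspect_threshold
        or p.has_enclosure
        or p.n_components >= 2
    )


def detect_flattening_point(
    profiles: list[CrossSectionProfile],
    axis_length: float,
    aspect_threshold: float = DEFAULT_ASPECT_THRESHOLD,
    persistence_um: float = DEFAULT_PERSISTENCE_UM,
) -> float | None:
    """First station whose flattening evidence is sustained; None if never.

    The persistence window (µm of arc along the cuticle axis) suppresses
    single-station mesh artifacts; a cylinder that stays round throughout
    returns None.
    """
    if not profiles:
        return None
    if len(profiles) > 1:
        step = profiles[1].station - profiles[0].station
        window = max(1, int(np.ceil(persistence_um / (step * axis_length))))
    else:
        window = 1
    flags = [_is_flattened(p, aspect_threshold) for p in profiles]
    for i in range(len(flags)):
        span = flags[i : i + window]
        if len(span) == window and all(span):
            return profiles[i].station
    return None


def classify_ab1C(
    profiles: list[CrossSectionProfile],
    flattening_point: float | None = None,
    aspect_threshold: float = DEFAULT_ASPECT_THRESHOLD,
    persistence_um: float = DEFAULT_PERSISTENCE_UM,
    evidence_fraction: float = DEFAULT_EVIDENCE_FRACTION,
    axis_length: float | None = None,
) -> tuple[str, dict[str, float]]:
    """Assign one of the four sheet categories from profiles.

    Over the flattened span (stations at or above the flattening point),
    curl evidence is the fraction of stations with self-enclosure, split
    evidence the fraction with >= 2 components.  Both over the persistence
    fraction -> mixed; curl only -> fully_curled; split only -> split;
    neither -> loosely_curled.

    Returns
    -------
    (label, evidence)
        ``evidence`` holds the flattening point and the two fractions.

    Raises
    ------
    GeometryError
        When no flattened span exists (cylindrical throughout).
    """
    if flattening_point is None:
        if axis_length is None:
            raise ValueError("need axis_length to detect the flattening point")
        flattening_point = detect_flattening_point(
            profiles, axis_length, aspect_threshold, persistence_um
        )
    if flattening_point is None:
        raise GeometryError("no flattened span: dendrite is cylindrical throughout")
    span = [p for p in profiles if p.station >= flattening_point - 1e-9]
    if not span:
        raise GeometryError("no stations at or above the flattening point")
    curl = sum(p.has_enclosure for p in span) / len(span)
    split = sum(p.n_components >= 2 for p in span) / len(span)
    if curl >= evidence_fraction and split >= evidence_fraction:
        label = "mixed"
    elif curl >= evidence_fraction:
        label = "fully_curled"
    elif split >= evidence_fraction:
        label = "split"
    else:
        label = "loosely_curled"
    evidence = {
        "flattening_point": float(flattening_point),
        "curl_fraction": float(curl),
        "split_fraction": float(split),
    }
    return label, evidence


def classify_ab1D(skeleton: Skeleton) -> tuple[str, int]:
    """Branched/unbranched call plus branch count from the outer-dendrite
    skeleton (branches = terminal tips; 1 for an unbranched chain)."""
    bs = branch_summary(skeleton)
    label = "branched" if bs.branch_points else "unbranched"
    return label, bs.n_branches


def category_distribution(labels) -> pd.DataFrame:
    """Counts and proportions per category label."""
    s = pd.Series(list(labels))
    if s.empty:
        raise ValueError("no labels to summarize")
    counts = s.value_counts()
    return pd.DataFrame(
        {"n": counts, "fraction": counts / counts.sum()}
    ).rename_axis("category")
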