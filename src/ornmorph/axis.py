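"""Normalized cuticle-axis coordinates.

Positions of dendritic landmarks (ciliary constriction, flattening point,
primary branch point, dendritic terminus) are expressed as *cuticle
proportions*: each landmark is projected onto the nearest point of the
sensillum-cuticle centerline and reported as arc-length fraction, 0 at the
cuticle base and 1 at the tip.  Landmarks below the base project onto the
extrapolated basal segment and get negative proportions, with -1 meaning one
full cuticle length below the base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GeometryError, SkeletonError
from .skeleton import Skeleton, branch_summary

__all__ = ["CuticleAxis", "LandmarkSet", "build_axis", "cuticle_proportion",
           "landmark_proportions"]

_RESAMPLE_STEP = 0.05  # µm; sub-voxel-z resolution of the projection table


@dataclass
class CuticleAxis:
    """Arc-length parameterized cuticle centerline, base -> tip, in µm."""

    polyline: np.ndarray  # (n, 3) ordered base -> tip
    cumulative_arclength: np.ndarray = field(init=False)
    total_length: float = field(init=False)

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float).reshape(-1, 3)
        if len(self.polyline) < 2:
            raise GeometryError("axis polyline needs >=2 points")
        seg = np.linalg.norm(np.diff(self.polyline, axis=0), axis=1)
        if np.any(seg <= 0):
            raise GeometryError("axis polyline has repeated points")
        self.cumulative_arclength = np.concatenate([[0.0], np.cumsum(seg)])
        self.total_length = float(self.cumulative_arclength[-1])

    @property
    def base(self) -> np.ndarray:
        return self.polyline[0]

    @property
    def tip(self) -> np.ndarray:
        return self.polyline[-1]

    def point_at(self, proportion: float) -> np.ndarray:
        """3D point at a given cuticle proportion (clamped to [0, 1] on the
        polyline; negative values extrapolate the basal segment)."""
        s = proportion * self.total_length
        if s <= 0:
            u0 = self.polyline[1] - self.polyline[0]
            u0 = u0 / np.linalg.norm(u0)
            return self.base + s * u0
        s = min(s, self.total_length)
        k = int(np.searchsorted(self.cumulative_arclength, s, side="right") - 1)
        k = min(k, len(self.polyline) - 2)
        ds = s - self.cumulative_arclength[k]
        u = self.polyline[k + 1] - self.polyline[k]
        return self.polyline[k] + u * (ds / np.linalg.norm(u))

    def tangent_at(self, proportion: float) -> np.ndarray:
        s = np.clip(proportion, 0.0, 1.0) * self.total_length
        k = int(np.searchsorted(self.cumulative_arclength, s, side="right") - 1)
        k = int(np.clip(k, 0, len(self.polyline) - 2))
        u = self.polyline[k + 1] - self.polyline[k]
        return u / np.linalg.norm(u)

    def transformed(self, matrix: np.ndarray) -> "CuticleAxis":
        xyz1 = np.column_stack([self.polyline, np.ones(len(self.polyline))])
        return CuticleAxis((np.asarray(matrix) @ xyz1.T).T[:, :3])


def build_axis(cuticle_skeleton: Skeleton, resample_step: float = _RESAMPLE_STEP) -> CuticleAxis:
    """Build the cuticle axis from an unbranched base->tip skeleton.

    The root of the skeleton is taken as the cuticle base (the end nearer
    the antennal surface, designated by the caller at segmentation time).
    The polyline is resampled at ``resample_step`` µm for projection accuracy.

    Raises
    ------
    SkeletonError
        If the cuticle skeleton is branched or a forest.
    """
    bs = branch_summary(cuticle_skeleton)
    if bs.branch_points:
        raise SkeletonError("cuticle skeleton must be unbranched")
    # walk root -> tip
    cm = cuticle_skeleton.children_map()
    node = int(cuticle_skeleton.roots[0])
    pts = [cuticle_skeleton.node_xyz(node)]
    while cm[node]:
        node = cm[node][0]
        pts.append(cuticle_skeleton.node_xyz(node))
    pts = np.asarray(pts)
    if len(pts) < 2:
        raise SkeletonError("cuticle skeleton needs >=2 nodes")
    # resample by arc length, keeping the exact endpoints
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(2, int(np.ceil(cum[-1] / resample_step)) + 1)
    targets = np.linspace(0.0, cum[-1], n)
    idx = np.clip(np.searchsorted(cum, targets, side="right") - 1, 0, len(seg) - 1)
    frac = (targets - cum[idx]) / seg[idx]
    fine = pts[idx] + (pts[idx + 1] - pts[idx]) * frac[:, None]
    return CuticleAxis(fine)


def cuticle_proportion(point: np.ndarray, axis: CuticleAxis) -> float:
    """Arc-length fraction in (-inf, 1] of the nearest axis point.

    The point is projected onto every axis segment and onto the extrapolated
    basal ray; the globally nearest candidate wins (lower arc-length station
    on ties).  Projections onto the basal ray give
    ``-(distance below base) / total_length``.
    """
    p = np.asarray(point, dtype=float)
    a = axis.polyline[:-1]
    b = axis.polyline[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
    foot = a + ab * t[:, None]
    d2 = np.einsum("ij,ij->i", p - foot, p - foot)
    k = int(np.argmin(d2))  # first minimum = lowest arc length on ties
    best_d2 = float(d2[k])
    s = axis.cumulative_arclength[k] + t[k] * np.sqrt(denom[k])
    prop = s / axis.total_length

    # extrapolated basal ray, direction of the first segment reversed
    u0 = ab[0] / np.sqrt(denom[0])
    t_ray = float((p - axis.base) @ (-u0))
    if t_ray > 0:
        ray_foot = axis.base - u0 * t_ray
        ray_d2 = float((p - ray_foot) @ (p - ray_foot))
        # ray wins ties: its stations are below every on-axis station
        if ray_d2 <= best_d2 + 1e-12:
            return -t_ray / axis.total_length
    return float(prop)


@dataclass
class LandmarkSet:
    """Named 3D landmarks of one neuron, in the cuticle frame (µm)."""

    ciliary_constriction: np.ndarray | None = None
    flattening_point: np.ndarray | None = None
    primary_branch_point: np.ndarray | None = None
    dendritic_termini: list[np.ndarray] = field(default_factory=list)


def landmark_proportions(
    landmarks: LandmarkSet, axis: CuticleAxis, neuron_id: str = ""
) -> pd.DataFrame:
    """Cuticle proportions of all landmarks, one row per landmark.

    Termini are reported individually (``terminus_1`` ...) plus a
    ``dendritic_terminus`` row carrying the maximum proportion over termini,
    the convention for the neuron-level DT position.

    Raises
    ------
    GeometryError
        If the landmark set is empty.
    """
    rows = []

    def add(name: str, pt) -> None:
        pt = np.asarray(pt, dtype=float)
        rows.append(
            {
                "neuron_id": neuron_id,
                "landmark": name,
                "x": pt[0],
                "y": pt[1],
                "z": pt[2],
                "proportion": cuticle_proportion(pt, axis),
            }
        )

    if landmarks.ciliary_constriction is not None:
        add("ciliary_constriction", landmarks.ciliary_constriction)
    if landmarks.flattening_point is not None:
        add("flattening_point", landmarks.flattening_point)
    if landmarks.primary_branch_point is not None:
        add("primary_branch_point", landmarks.primary_branch_point)
    for k, t in enumerate(landmarks.dendritic_termini, start=1):
        add(f"terminus_{k}", t)
    if landmarks.dendritic_termini:
        term_rows = [r for r in rows if r["landmark"].startswith("terminus_")]
        best = max(term_rows, key=lambda r: r["proportion"])
        rows.append({**best, "landmark": "dendritic_terminus"})
    if not rows:
        raise GeometryError("empty landmark set")
    return pd.DataFrame(rows)
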