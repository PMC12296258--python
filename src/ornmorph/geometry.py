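"""Mesh construction from serial contours and surface-area/volume/cross-section
computation.

Reconstructions arrive as stacks of closed contours drawn on serial EM
sections (pixel units, anisotropic voxel calibration) or as watertight
triangle meshes in micrometres.  Contour stacks are lofted into watertight
meshes; surface area is the triangle-area sum and volume the
divergence-theorem signed volume.  Hollow (tube-like) objects segmented as an
outer/inner pair follow the convention used for EM morphometry of enclosed
membranes: volume is outer minus inner, surface area is outer plus inner.

The module is backed by :mod:`trimesh` (mesh container, plane sections) and
:mod:`shapely` (planar polygon operations).  Ray casting and end-cap
triangulation are implemented here because they must not depend on optional
compiled extensions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
import trimesh
from shapely.geometry import MultiPolygon, Polygon

from .errors import ContainmentError, GeometryError, WatertightError

__all__ = [
    "ContourStack",
    "PlanarSection",
    "SectionLoop",
    "mesh_from_contours",
    "surface_area",
    "volume",
    "hollow_morphometrics",
    "cross_section",
    "combined_section_polygons",
    "voxel_fill_volume",
    "points_in_mesh",
    "ray_intersections",
    "load_mesh",
    "save_mesh",
]

_MERGE_TOL = 1e-9  # µm; vertices are matched exactly, no fuzzy welding


# ---------------------------------------------------------------------------
# Contour stacks
# ---------------------------------------------------------------------------


@dataclass
class ContourStack:
    """Serial closed contours around one object, in pixel units.

    Parameters
    ----------
    contours
        List of ``(z_index, polygon)`` pairs where ``polygon`` is an
        ``(n, 2)`` array of planar vertices in pixels (unclosed; the last
        vertex connects back to the first).  ``z_index`` values need not be
        contiguous but must be sortable.
    voxel_size_nm
        ``(x, y, z)`` calibration in nanometres, strictly positive.
    object_id
        Label of the segmented object.
    """

    contours: list[tuple[int, np.ndarray]]
    voxel_size_nm: tuple[float, float, float]
    object_id: str = ""

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size_nm):
            raise GeometryError("voxel_size_nm must be strictly positive")
        cleaned = []
        for z, poly in self.contours:
            poly = np.asarray(poly, dtype=float)
            if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
                raise GeometryError(
                    f"contour at z={z} needs >=3 planar vertices"
                )
            if not Polygon(poly).is_valid:
                raise GeometryError(
                    f"contour at z={z} is self-intersecting or degenerate"
                )
            cleaned.append((int(z), poly))
        self.contours = sorted(cleaned, key=lambda c: c[0])

    # -- unit conversion ----------------------------------------------------

    def contours_um(self) -> list[np.ndarray]:
        """Contours as ``(n, 3)`` arrays in µm, sorted by z."""
        vx, vy, vz = (v / 1000.0 for v in self.voxel_size_nm)
        out = []
        for z, poly in self.contours:
            pts = np.column_stack(
                [poly[:, 0] * vx, poly[:, 1] * vy, np.full(len(poly), z * vz)]
            )
            out.append(pts)
        return out

    # -- JSON dialect -------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "object_id": self.object_id,
            "voxel_size_nm": list(self.voxel_size_nm),
            "contours": [
                {"z": int(z), "xy": np.asarray(p).tolist()}
                for z, p in self.contours
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ContourStack":
        payload = json.loads(Path(path).read_text())
        return cls(
            contours=[
                (c["z"], np.asarray(c["xy"], dtype=float))
                for c in payload["contours"]
            ],
            voxel_size_nm=tuple(payload["voxel_size_nm"]),
            object_id=payload.get("object_id", ""),
        )


# ---------------------------------------------------------------------------
# Polygon helpers
# ---------------------------------------------------------------------------


def _signed_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(
        np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    )


def _ensure_ccw(poly: np.ndarray) -> np.ndarray:
    return poly[::-1].copy() if _signed_area(poly) < 0 else poly


def resample_closed_polygon(poly: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polygon to ``n`` vertices by arc length.

    Original vertices are preserved (corners must survive resampling);
    additional points are inserted at the midpoints of the largest arc gaps
    until the target count is reached.  With ``n`` below the input count the
    polygon falls back to plain equal arc spacing.
    """
    closed = np.vstack([poly, poly[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise GeometryError("degenerate zero-perimeter polygon")
    if n >= len(poly):
        targets = sorted(cum[:-1].tolist())
        while len(targets) < n:
            ring = targets + [targets[0] + total]
            gaps = np.diff(ring)
            k = int(np.argmax(gaps))
            targets.insert(k + 1, (ring[k] + ring[k + 1]) / 2.0)
            targets = sorted(t % total for t in targets)
        targets = np.asarray(targets)
    else:
        targets = np.arange(n) * total / n
    idx = np.searchsorted(cum, targets, side="right") - 1
    idx = np.clip(idx, 0, len(seg) - 1)
    frac = (targets - cum[idx]) / np.where(seg[idx] > 0, seg[idx], 1.0)
    return closed[idx] + (closed[idx + 1] - closed[idx]) * frac[:, None]


def _best_cyclic_shift(a: np.ndarray, b: np.ndarray) -> int:
    """Cyclic offset of ``b`` minimizing summed squared distance to ``a``."""
    n = len(a)
    best, best_cost = 0, np.inf
    for s in range(n):
        cost = float(np.sum((a[:, :2] - np.roll(b[:, :2], -s, axis=0)) ** 2))
        if cost < best_cost:
            best, best_cost = s, cost
    return best


def triangulate_simple_polygon(poly: np.ndarray) -> np.ndarray:
    """Ear-clipping triangulation of a simple polygon (indices into ``poly``).

    Works on convex and non-convex simple polygons; used for planar end caps
    where the triangulation must reuse exactly the ring vertices so lofted
    meshes stay watertight.
    """
    poly = np.asarray(poly, dtype=float)[:, :2]
    n = len(poly)
    if n < 3:
        raise GeometryError("cannot triangulate polygon with <3 vertices")
    ccw = _signed_area(poly) >= 0
    order = list(range(n)) if ccw else list(range(n - 1, -1, -1))
    faces = []

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    def point_in_tri(p, a, b, c, eps=1e-12):
        d1 = cross(a, b, p)
        d2 = cross(b, c, p)
        d3 = cross(c, a, p)
        return d1 >= -eps and d2 >= -eps and d3 >= -eps

    guard = 0
    while len(order) > 3 and guard < 10 * n * n:
        guard += 1
        m = len(order)
        clipped = False
        for k in range(m):
            i0, i1, i2 = order[k - 1], order[k], order[(k + 1) % m]
            a, b, c = poly[i0], poly[i1], poly[i2]
            if cross(a, b, c) <= 1e-14:
                continue  # reflex or collinear vertex, not an ear
            if any(
                point_in_tri(poly[j], a, b, c)
                for j in order
                if j not in (i0, i1, i2)
            ):
                continue
            faces.append((i0, i1, i2))
            order.pop(k)
            clipped = True
            break
        if not clipped:
            # numerical fallback: clip the most convex vertex
            k = max(
                range(len(order)),
                key=lambda k: cross(
                    poly[order[k - 1]],
                    poly[order[k]],
                    poly[order[(k + 1) % len(order)]],
                ),
            )
            m = len(order)
            faces.append((order[k - 1], order[k], order[(k + 1) % m]))
            order.pop(k)
    faces.append(tuple(order))
    return np.asarray(faces, dtype=np.int64)


# ---------------------------------------------------------------------------
# Lofting
# ---------------------------------------------------------------------------


def mesh_from_contours(
    stack: ContourStack, resolution: int | None = None
) -> trimesh.Trimesh:
    """Loft a serial-contour stack into a watertight triangle mesh in µm.

    Adjacent contours are resampled by arc length to a common vertex count
    (the maximum over the stack, or ``resolution`` if larger), aligned by the
    cyclic shift minimizing vertex displacement, and connected by triangle
    strips.  The first and last contours are closed with planar ear-clipped
    end caps.

    Raises
    ------
    GeometryError
        For single-plane stacks or self-intersecting contours.
    WatertightError
        If the lofted mesh fails the watertightness check.
    """
    rings3 = stack.contours_um()
    if len(rings3) < 2:
        raise GeometryError("cannot loft a single-plane contour stack")
    n = max(len(r) for r in rings3)
    if resolution is not None:
        n = max(n, int(resolution))
    rings = []
    for r in rings3:
        z = r[0, 2]
        ring2 = _ensure_ccw(r[:, :2])
        ring2 = resample_closed_polygon(ring2, n)
        rings.append(np.column_stack([ring2, np.full(n, z)]))
    # cumulative alignment so twist does not accumulate arbitrarily
    for k in range(1, len(rings)):
        s = _best_cyclic_shift(rings[k - 1], rings[k])
        rings[k] = np.roll(rings[k], -s, axis=0)

    vertices = np.vstack(rings)
    faces = []
    for k in range(len(rings) - 1):
        a0 = k * n
        b0 = (k + 1) * n
        for j in range(n):
            j1 = (j + 1) % n
            faces.append((a0 + j, a0 + j1, b0 + j1))
            faces.append((a0 + j, b0 + j1, b0 + j))
    bottom = triangulate_simple_polygon(rings[0][:, :2])
    faces.extend(tuple(tri[::-1]) for tri in bottom)  # outward = -z
    top_off = (len(rings) - 1) * n
    top = triangulate_simple_polygon(rings[-1][:, :2])
    faces.extend(tuple(tri + top_off) for tri in top)

    mesh = trimesh.Trimesh(
        vertices=vertices, faces=np.asarray(faces, dtype=np.int64), process=False
    )
    mesh.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=9)
    mesh.update_faces(mesh.nondegenerate_faces())
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        raise WatertightError(
            f"lofted mesh for object '{stack.object_id}' is not watertight"
        )
    return mesh


# ---------------------------------------------------------------------------
# Morphometric primitives
# ---------------------------------------------------------------------------


def surface_area(mesh: trimesh.Trimesh) -> float:
    """Total surface area in µm² (sum of triangle areas, end caps included)."""
    if mesh is None or len(mesh.faces) == 0:
        raise GeometryError("empty mesh has no surface area")
    return float(mesh.area)


def is_watertight(mesh: trimesh.Trimesh) -> bool:
    return bool(mesh.is_watertight and mesh.is_winding_consistent)


def volume(mesh: trimesh.Trimesh) -> float:
    """Divergence-theorem volume in µm³ (requires a watertight mesh)."""
    if mesh is None or len(mesh.faces) == 0:
        raise GeometryError("empty mesh has no volume")
    if not is_watertight(mesh):
        raise WatertightError("volume is undefined for a non-watertight mesh")
    return float(abs(mesh.volume))


def hollow_morphometrics(
    outer: trimesh.Trimesh,
    inner: trimesh.Trimesh,
    check_containment: bool = True,
) -> tuple[float, float]:
    """Surface area and volume of a hollow (tube-like) object pair.

    Follows the EM-morphometry convention for enclosed membranes: the
    membrane-bound volume is ``V(outer) - V(inner)`` and the sensory surface
    is ``SA(outer) + SA(inner)`` (both membrane faces).

    Returns
    -------
    (sa, v) in (µm², µm³).
    """
    v_out, v_in = volume(outer), volume(inner)
    if check_containment:
        sample = np.asarray(inner.vertices)
        if len(sample) > 64:
            idx = np.linspace(0, len(sample) - 1, 64).astype(int)
            sample = sample[idx]
        # tolerate coincident boundary faces (e.g. shared end-cap planes)
        centroid = sample.mean(axis=0)
        sample = centroid + (sample - centroid) * (1.0 - 1e-6)
        if not points_in_mesh(outer, sample).all():
            raise ContainmentError("inner object is not contained in outer")
    v = v_out - v_in
    if v <= 0:
        raise ContainmentError(
            f"hollow pair has non-positive membrane volume ({v:.3g} µm³)"
        )
    return surface_area(outer) + surface_area(inner), v


# ---------------------------------------------------------------------------
# Plane sections
# ---------------------------------------------------------------------------


@dataclass
class SectionLoop:
    """One closed loop of a mesh-plane intersection, in plane coordinates."""

    points: np.ndarray  # (n, 2) in-plane coordinates, µm
    is_hole: bool
    area: float  # positive loop area, µm²


@dataclass
class PlanarSection:
    """Mesh-plane intersection: closed loops with even-odd hole flags.

    ``polygons`` are shapely polygons with holes attached (the even-odd
    nesting already resolved); ``loops`` flatten the same geometry into
    outer/hole rings.  ``to_world`` maps in-plane ``(u, v)`` coordinates back
    to 3D.
    """

    point: np.ndarray
    normal: np.ndarray
    polygons: list[Polygon] = field(default_factory=list)
    loops: list[SectionLoop] = field(default_factory=list)
    to_world: np.ndarray | None = None  # (4, 4)

    @property
    def is_empty(self) -> bool:
        return len(self.loops) == 0

    @property
    def n_outer(self) -> int:
        return sum(not lp.is_hole for lp in self.loops)

    @property
    def net_area(self) -> float:
        """Σ outer areas − Σ hole areas (µm²)."""
        return float(sum(p.area for p in self.polygons))

    def loop_centroids_3d(self) -> np.ndarray:
        """Area centroids of the outer loops, mapped back to 3D (k, 3)."""
        cents = []
        for poly in self.polygons:
            c = poly.centroid
            uv1 = np.array([c.x, c.y, 0.0, 1.0])
            cents.append((self.to_world @ uv1)[:3])
        return np.asarray(cents)


def _plane_transform(point: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """4x4 world→plane transform with the plane mapped to z=0."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    a = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(a, n)) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, a)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    rot = np.vstack([u, v, n])
    tf = np.eye(4)
    tf[:3, :3] = rot
    tf[:3, 3] = -rot @ np.asarray(point, dtype=float)
    return tf


def cross_section(
    mesh: trimesh.Trimesh,
    point: np.ndarray,
    normal: np.ndarray,
) -> PlanarSection:
    """Intersect a mesh with a plane.

    Returns an empty :class:`PlanarSection` when the plane misses the mesh.

    Raises
    ------
    GeometryError
        For a zero-length normal.
    """
    normal = np.asarray(normal, dtype=float)
    norm = np.linalg.norm(normal)
    if norm < 1e-12:
        raise GeometryError("degenerate (zero) section normal")
    normal = normal / norm
    point = np.asarray(point, dtype=float)
    section = PlanarSection(point=point, normal=normal)
    tf = _plane_transform(point, normal)
    section.to_world = np.linalg.inv(tf)
    try:
        path3 = mesh.section(plane_origin=point, plane_normal=normal)
    except ValueError:
        path3 = None
    if path3 is None or len(path3.entities) == 0:
        return section
    planar, _ = path3.to_2D(to_2D=tf, check=False)
    rings: list[np.ndarray] = []
    for disc in planar.discrete:
        pts = np.asarray(disc)
        if len(pts) < 3:
            continue
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) >= 3 and Polygon(pts).area > 1e-12:
            rings.append(pts)
    if not rings:
        return section
    ring_polys = [Polygon(r) for r in rings]
    # even-odd nesting: a ring contained in an odd number of other rings is a hole
    depth = np.zeros(len(rings), dtype=int)
    for i, pi in enumerate(ring_polys):
        rep = pi.representative_point()
        for j, pj in enumerate(ring_polys):
            if i != j and pj.contains(rep):
                depth[i] += 1
    for i, pi in enumerate(ring_polys):
        section.loops.append(
            SectionLoop(points=rings[i], is_hole=depth[i] % 2 == 1, area=pi.area)
        )
    # attach each hole to its smallest containing outer ring
    outers = [i for i in range(len(rings)) if depth[i] % 2 == 0]
    holes_of: dict[int, list[int]] = {i: [] for i in outers}
    for h in range(len(rings)):
        if depth[h] % 2 == 0:
            continue
        rep = ring_polys[h].representative_point()
        parents = [i for i in outers if ring_polys[i].contains(rep)]
        if parents:
            holes_of[min(parents, key=lambda i: ring_polys[i].area)].append(h)
    section.polygons = [
        Polygon(rings[i], [rings[h] for h in holes_of[i]]) for i in outers
    ]
    return section


def combined_section_polygons(
    meshes: list[trimesh.Trimesh],
    hollow_pairs: list[tuple[int, int]],
    point: np.ndarray,
    normal: np.ndarray,
) -> list[Polygon]:
    """Cross-section of a multi-object neuron as shapely polygons.

    All meshes are cut in a common plane frame; for hollow pairs the inner
    object's section is subtracted from the outer's (the membrane annulus),
    so a fully curled tube appears as a ring with a hole.
    """
    inner_idx = {i for _, i in hollow_pairs}
    outer_of = dict(hollow_pairs)
    sections = [cross_section(m, point, normal) for m in meshes]
    result: list[Polygon] = []
    for i, sec in enumerate(sections):
        if i in inner_idx or sec.is_empty:
            continue
        geom: Polygon | MultiPolygon = shapely.union_all(sec.polygons)
        if i in outer_of:
            inner_sec = sections[outer_of[i]]
            if not inner_sec.is_empty:
                geom = geom.difference(shapely.union_all(inner_sec.polygons))
        if geom.is_empty:
            continue
        if isinstance(geom, Polygon):
            result.append(geom)
        else:
            result.extend(g for g in geom.geoms if g.area > 0)
    return result


# ---------------------------------------------------------------------------
# Ray casting and containment (pure numpy; no optional engines)
# ---------------------------------------------------------------------------


def ray_intersections(
    mesh: trimesh.Trimesh, origin: np.ndarray, direction: np.ndarray
) -> np.ndarray:
    """Sorted positive ray parameters of all ray-triangle intersections.

    Vectorized Möller–Trumbore over all faces of the mesh.
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    tri = mesh.triangles  # (m, 3, 3)
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    h = np.cross(direction, e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > 1e-14
    f = np.zeros_like(a)
    f[ok] = 1.0 / a[ok]
    s = origin - v0
    u = f * np.einsum("ij,ij->i", s, h)
    q = np.cross(s, e1)
    v = f * (q @ direction)
    t = f * np.einsum("ij,ij->i", q, e2)
    hit = ok & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1 + 1e-12) & (t > 1e-9)
    return np.sort(t[hit])


def points_in_mesh(
    mesh: trimesh.Trimesh, points: np.ndarray, direction=None
) -> np.ndarray:
    """Boolean containment by ray-crossing parity.

    Uses a fixed slightly-irrational ray direction to avoid edge-grazing
    degeneracies on axis-aligned synthetic meshes.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if direction is None:
        direction = np.array([0.1234567, 0.2345678, 0.9456789])
    out = np.empty(len(points), dtype=bool)
    for i, p in enumerate(points):
        out[i] = len(ray_intersections(mesh, p, direction)) % 2 == 1
    return out


def voxel_fill_volume(mesh: trimesh.Trimesh, pitch: float = 0.02) -> float:
    """Volume estimate by counting voxel centres inside the mesh.

    Sections the mesh at each z-slab centre and tests an x-y grid of voxel
    centres against the section polygons — an estimator independent of the
    divergence-theorem volume, used as a cross-check oracle.
    """
    lo, hi = mesh.bounds
    zs = np.arange(lo[2] + pitch / 2, hi[2], pitch)
    xs = np.arange(lo[0] + pitch / 2, hi[0] + pitch, pitch)
    ys = np.arange(lo[1] + pitch / 2, hi[1] + pitch, pitch)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    gx, gy = gx.ravel(), gy.ravel()
    count = 0
    for z in zs:
        sec = cross_section(mesh, np.array([0.0, 0.0, z]), np.array([0.0, 0.0, 1.0]))
        if sec.is_empty:
            continue
        geom = shapely.union_all(sec.polygons)
        # plane frame for normal=z is a rotation of world x-y; test in-plane
        tf = _plane_transform(np.array([0.0, 0.0, z]), np.array([0.0, 0.0, 1.0]))
        pts = np.column_stack([gx, gy, np.full(gx.shape, z), np.ones_like(gx)])
        uv = (tf @ pts.T).T[:, :2]
        count += int(np.count_nonzero(shapely.contains_xy(geom, uv[:, 0], uv[:, 1])))
    return count * pitch**3


# ---------------------------------------------------------------------------
# Mesh I/O (ASCII OBJ / PLY, units µm)
# ---------------------------------------------------------------------------


def save_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    path = Path(path)
    kind = path.suffix.lstrip(".").lower()
    if kind not in ("obj", "ply"):
        raise GeometryError(f"unsupported mesh format '{kind}'")
    data = mesh.export(file_type=kind, encoding="ascii") if kind == "ply" else mesh.export(
        file_type="obj"
    )
    if isinstance(data, bytes):
        data = data.decode()
    path.write_text(data)


def load_mesh(path: str | Path) -> trimesh.Trimesh:
    loaded = trimesh.load(str(path), force="mesh", process=False)
    return loaded
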