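"""Mesh lofting, surface area, volume, hollow pairs and plane sections."""

import numpy as np
import pytest
import trimesh

from ornmorph.errors import ContainmentError, GeometryError, WatertightError
from ornmorph.geometry import (
    ContourStack,
    cross_section,
    hollow_morphometrics,
    load_mesh,
    mesh_from_contours,
    points_in_mesh,
    save_mesh,
    surface_area,
    volume,
    voxel_fill_volume,
)

from conftest import circle_contour, cylinder_stack


class TestLoft:
    def test_two_squares_make_unit_cube(self, unit_cube_mesh):
        assert volume(unit_cube_mesh) == pytest.approx(1.0, abs=1e-9)
        assert surface_area(unit_cube_mesh) == pytest.approx(6.0, abs=1e-9)
        assert unit_cube_mesh.is_watertight

    def test_cylinder_volume_and_area_within_1pct(self, cylinder_mesh):
        assert volume(cylinder_mesh) == pytest.approx(np.pi * 0.25 * 10, rel=0.01)
        expected_sa = 2 * np.pi * 0.5 * 10 + 2 * np.pi * 0.25
        assert surface_area(cylinder_mesh) == pytest.approx(expected_sa, rel=0.01)

    @pytest.mark.parametrize("ngon,tol", [(16, 0.05), (64, 0.01)])
    def test_volume_converges_with_contour_resolution(self, ngon, tol):
        mesh = mesh_from_contours(cylinder_stack(0.5, 10.0, n=ngon))
        assert volume(mesh) == pytest.approx(np.pi * 0.25 * 10, rel=tol)

    def test_square_to_octagon_loft_matches_voxel_oracle(self):
        sq = (np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float) - 0.5) * 2
        th = np.linspace(0, 2 * np.pi, 8, endpoint=False) + np.pi / 8
        octo = np.column_stack([np.cos(th), np.sin(th)]) * 0.7
        mesh = mesh_from_contours(
            ContourStack([(0, sq), (1, octo)], (1000, 1000, 1000)), resolution=32
        )
        assert mesh.is_watertight
        assert volume(mesh) == pytest.approx(voxel_fill_volume(mesh, 0.02), rel=0.02)

    def test_blob_volume_matches_voxel_oracle(self):
        blob = trimesh.creation.icosphere(subdivisions=3, radius=0.5)
        blob.apply_scale([1.0, 0.7, 1.3])
        assert volume(blob) == pytest.approx(voxel_fill_volume(blob, 0.02), rel=0.02)

    def test_single_plane_stack_rejected(self):
        stack = ContourStack([(0, circle_contour(0.5))], (5, 5, 40))
        with pytest.raises(GeometryError):
            mesh_from_contours(stack)

    def test_self_intersecting_contour_rejected(self):
        bowtie = np.array([[0, 0], [1, 1], [1, 0], [0, 1]], float)
        with pytest.raises(GeometryError):
            ContourStack([(0, bowtie), (1, bowtie)], (5, 5, 40))

    def test_stack_json_roundtrip(self, tmp_path):
        stack = cylinder_stack(0.5, 1.0)
        stack.to_json(tmp_path / "s.json")
        back = ContourStack.from_json(tmp_path / "s.json")
        assert back.object_id == stack.object_id
        assert back.voxel_size_nm == stack.voxel_size_nm
        for (z1, p1), (z2, p2) in zip(stack.contours, back.contours):
            assert z1 == z2
            np.testing.assert_allclose(p1, p2)


class TestMorphometricPrimitives:
    def test_empty_mesh_rejected(self):
        with pytest.raises(GeometryError):
            surface_area(trimesh.Trimesh())
        with pytest.raises(GeometryError):
            volume(trimesh.Trimesh())

    def test_open_mesh_area_defined_but_volume_rejected(self, unit_cube_mesh):
        broken = trimesh.Trimesh(
            vertices=unit_cube_mesh.vertices.copy(),
            faces=unit_cube_mesh.faces[:-1].copy(),
        )
        assert surface_area(broken) > 0
        assert not broken.is_watertight
        with pytest.raises(WatertightError):
            volume(broken)

    def test_rigid_motion_invariance(self, cylinder_mesh):
        moved = cylinder_mesh.copy()
        moved.apply_transform(
            trimesh.transformations.rotation_matrix(0.73, [1, 2, 3], [0.2, -0.1, 0.4])
        )
        moved.apply_translation([5.0, -3.0, 2.0])
        assert volume(moved) == pytest.approx(volume(cylinder_mesh), rel=1e-9)
        assert surface_area(moved) == pytest.approx(
            surface_area(cylinder_mesh), rel=1e-9
        )

    def test_sheet_volume(self):
        rect = np.array([[0, 0], [2.0, 0], [2.0, 0.1], [0, 0.1]]) / 0.005
        zs = range(0, 251, 5)
        mesh = mesh_from_contours(ContourStack([(z, rect) for z in zs], (5, 5, 40)))
        assert volume(mesh) == pytest.approx(2.0, rel=0.01)


class TestHollowPairs:
    def test_annulus_volume_is_difference(self, annulus_pair):
        outer, inner = annulus_pair
        sa, v = hollow_morphometrics(outer, inner)
        assert v == pytest.approx(np.pi * (0.25 - 0.09) * 5, rel=0.01)
        # surface area sums both membrane faces, caps included
        expected_sa = (2 * np.pi * 0.5 * 5 + 2 * np.pi * 0.25) + (
            2 * np.pi * 0.3 * 5 + 2 * np.pi * 0.09
        )
        assert sa == pytest.approx(expected_sa, rel=0.01)

    def test_hollow_volume_additivity_exact(self, annulus_pair):
        outer, inner = annulus_pair
        _, v = hollow_morphometrics(outer, inner)
        assert v + volume(inner) == pytest.approx(volume(outer), rel=1e-9)

    def test_identical_pair_rejected(self, annulus_pair):
        outer, _ = annulus_pair
        with pytest.raises(ContainmentError):
            hollow_morphometrics(outer, outer.copy())

    def test_disjoint_inner_rejected(self, annulus_pair):
        outer, inner = annulus_pair
        shifted = inner.copy()
        shifted.apply_translation([10.0, 0, 0])
        with pytest.raises(ContainmentError):
            hollow_morphometrics(outer, shifted)


class TestCrossSection:
    def test_cylinder_section_is_one_disc(self, cylinder_mesh):
        sec = cross_section(cylinder_mesh, [0, 0, 5.0], [0, 0, 1.0])
        assert sec.n_outer == 1
        assert sec.net_area == pytest.approx(np.pi * 0.25, rel=0.01)

    def test_annulus_section_has_hole(self, annulus_pair):
        # section of the membrane annulus: subtract the inner solid's disc
        from ornmorph.geometry import combined_section_polygons

        outer, inner = annulus_pair
        polys = combined_section_polygons(
            [outer, inner], [(0, 1)], np.array([0, 0, 2.5]), np.array([0, 0, 1.0])
        )
        assert len(polys) == 1
        assert len(polys[0].interiors) == 1
        assert sum(p.area for p in polys) == pytest.approx(
            np.pi * (0.25 - 0.09), rel=0.01
        )

    def test_plane_beyond_mesh_is_empty(self, cylinder_mesh):
        sec = cross_section(cylinder_mesh, [0, 0, 50.0], [0, 0, 1.0])
        assert sec.is_empty
        assert sec.net_area == 0.0

    def test_zero_normal_rejected(self, cylinder_mesh):
        with pytest.raises(GeometryError):
            cross_section(cylinder_mesh, [0, 0, 5.0], [0, 0, 0])

    def test_convex_section_area_continuous_along_axis(self, cylinder_mesh):
        areas = [
            cross_section(cylinder_mesh, [0, 0, z], [0, 0, 1.0]).net_area
            for z in np.linspace(0.5, 9.5, 19)
        ]
        jumps = np.abs(np.diff(areas))
        assert jumps.max() < 0.01 * np.pi * 0.25


class TestContainmentAndIO:
    def test_points_in_mesh_parity(self, unit_cube_mesh):
        inside = [[0.5, 0.5, 0.5], [0.1, 0.9, 0.2]]
        outside = [[2, 2, 2], [-0.1, 0.5, 0.5]]
        assert points_in_mesh(unit_cube_mesh, inside).all()
        assert not points_in_mesh(unit_cube_mesh, outside).any()

    @pytest.mark.parametrize("ext", ["ply", "obj"])
    def test_mesh_file_roundtrip(self, cylinder_mesh, tmp_path, ext):
        path = tmp_path / f"m.{ext}"
        save_mesh(cylinder_mesh, path)
        back = load_mesh(path)
        assert volume(back) == pytest.approx(volume(cylinder_mesh), rel=1e-6)
        assert surface_area(back) == pytest.approx(
            surface_area(cylinder_mesh), rel=1e-6
        )
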