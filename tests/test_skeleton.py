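"""SWC handling, branch topology, centerline extraction and planar layout."""

import math

import numpy as np
import pytest
import trimesh

from ornmorph.errors import SkeletonError
from ornmorph.skeleton import (
    Skeleton,
    branch_summary,
    centerline_from_mesh,
    planar_layout,
    prune_short_branches,
    read_swc,
    skeleton_length,
    write_swc,
)


def y_tree() -> Skeleton:
    return Skeleton(
        ids=[1, 2, 3, 4],
        type_codes=[3] * 4,
        xyz=[[0, 0, 0], [0, 0, 1], [1, 0, 2], [-1, 0, 2]],
        radius=[0.1] * 4,
        parent_ids=[-1, 1, 2, 2],
    )


def multi_leaf_tree(n_leaves: int) -> Skeleton:
    nodes = [[0.0, 0.0, 0.0], [0.0, 0.0, 2.0]]
    parents = [-1, 1]
    for k in range(n_leaves):
        ang = 2 * np.pi * k / n_leaves
        nodes.append([np.cos(ang), np.sin(ang), 3.0])
        parents.append(2)
    n = len(nodes)
    return Skeleton(
        ids=np.arange(1, n + 1), type_codes=[3] * n, xyz=nodes,
        radius=[0.05] * n, parent_ids=parents,
    )


class TestSwcIO:
    def test_three_node_chain(self, tmp_path):
        path = tmp_path / "chain.swc"
        path.write_text(
            "# comment\n1 1 0 0 0 0.5 -1\n2 3 0 0 1 0.2 1\n3 3 0 0 2 0.2 2\n"
        )
        sk = read_swc(path)
        assert len(sk.roots) == 1
        bs = branch_summary(sk)
        assert bs.termini == [3]
        assert bs.n_branches == 1

    def test_roundtrip_preserves_node_table(self, tmp_path):
        sk = y_tree()
        write_swc(sk, tmp_path / "y.swc")
        back = read_swc(tmp_path / "y.swc")
        np.testing.assert_array_equal(back.ids, sk.ids)
        np.testing.assert_allclose(back.xyz, sk.xyz)
        np.testing.assert_allclose(back.radius, sk.radius)
        np.testing.assert_array_equal(back.parent_ids, sk.parent_ids)

    def test_self_parent_rejected(self, tmp_path):
        path = tmp_path / "bad.swc"
        path.write_text("1 1 0 0 0 0.5 1\n")
        with pytest.raises(SkeletonError):
            read_swc(path)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(SkeletonError):
            Skeleton(ids=[1, 1], type_codes=[3, 3], xyz=[[0, 0, 0], [0, 0, 1]],
                     radius=[0.1, 0.1], parent_ids=[-1, 1])

    def test_cycles_rejected(self):
        with pytest.raises(SkeletonError):
            Skeleton(ids=[1, 2], type_codes=[3, 3], xyz=[[0, 0, 0], [0, 0, 1]],
                     radius=[0.1, 0.1], parent_ids=[2, 1])

    def test_forward_parent_reference_allowed(self, tmp_path):
        path = tmp_path / "fwd.swc"
        path.write_text("2 3 0 0 1 0.2 1\n1 1 0 0 0 0.5 -1\n")
        sk = read_swc(path)
        assert skeleton_length(sk) == pytest.approx(1.0)


class TestLengthsAndTopology:
    def test_pythagorean_chain(self):
        sk = Skeleton.from_points([[0, 0, 0], [0, 4, 0], [3, 0, 0]])
        assert skeleton_length(sk) == pytest.approx(9.0)

    def test_single_node_has_zero_length(self):
        sk = Skeleton.from_points([[1.0, 2.0, 3.0]])
        assert skeleton_length(sk) == 0.0

    def test_y_tree_with_unit_edges(self):
        sk = Skeleton(
            ids=[1, 2, 3, 4], type_codes=[3] * 4,
            xyz=[[0, 0, 0], [0, 0, 1], [0, 1, 1], [0, -1, 1]],
            radius=[0.1] * 4, parent_ids=[-1, 1, 2, 2],
        )
        assert skeleton_length(sk) == pytest.approx(3.0)

    def test_subset_length(self):
        sk = Skeleton.from_points([[0, 0, 0], [0, 0, 1], [0, 0, 3]])
        assert skeleton_length(sk, {2, 3}) == pytest.approx(2.0)

    def test_unbranched_chain_summary(self):
        sk = Skeleton.from_points([[0, 0, 0], [0, 0, 1], [0, 0, 2]])
        bs = branch_summary(sk)
        assert bs.branch_points == []
        assert bs.primary_branch_point is None
        assert bs.n_branches == 1

    def test_binary_y_summary(self):
        bs = branch_summary(y_tree())
        assert bs.branch_points == [2]
        assert bs.primary_branch_point == 2
        assert bs.n_branches == 2

    @pytest.mark.parametrize("n_leaves", range(1, 8))
    def test_leaf_count_matches_generator(self, n_leaves):
        if n_leaves == 1:
            sk = Skeleton.from_points([[0, 0, 0], [0, 0, 1]])
        else:
            sk = multi_leaf_tree(n_leaves)
        assert branch_summary(sk).n_branches == n_leaves

    def test_invariance_under_rigid_motion_and_reindexing(self):
        sk = y_tree()
        ref_len = skeleton_length(sk)
        M = trimesh.transformations.rotation_matrix(0.9, [1, 1, 0], [2, -1, 3])
        assert skeleton_length(sk.transformed(M)) == pytest.approx(ref_len, rel=1e-9)
        relabeled = Skeleton(
            ids=[10, 20, 30, 40], type_codes=sk.type_codes, xyz=sk.xyz,
            radius=sk.radius, parent_ids=[-1, 10, 20, 20],
        )
        assert skeleton_length(relabeled) == pytest.approx(ref_len)

    def test_multi_root_forest_rejected_for_single_neuron(self):
        sk = Skeleton(
            ids=[1, 2], type_codes=[3, 3], xyz=[[0, 0, 0], [5, 0, 0]],
            radius=[0.1] * 2, parent_ids=[-1, -1],
        )
        with pytest.raises(SkeletonError):
            branch_summary(sk)

    def test_prune_short_branches(self):
        sk = Skeleton(
            ids=[1, 2, 3, 4], type_codes=[3] * 4,
            xyz=[[0, 0, 0], [0, 0, 5], [0, 0, 10], [0.2, 0, 5.1]],
            radius=[0.1] * 4, parent_ids=[-1, 1, 2, 2],
        )
        pruned = prune_short_branches(sk, min_length=1.0)
        assert branch_summary(pruned).n_branches == 1
        assert skeleton_length(pruned) == pytest.approx(10.0)


def _capped_cylinder(r, L, sections=48):
    c = trimesh.creation.cylinder(radius=r, height=L, sections=sections)
    c.apply_translation([0, 0, L / 2])
    return c


class TestCenterline:
    @pytest.mark.parametrize("r", [0.05, 0.1, 0.25])
    @pytest.mark.parametrize("L", [5.0, 10.0, 20.0])
    def test_cylinder_length_recovered_within_2pct(self, r, L):
        cl = centerline_from_mesh(_capped_cylinder(r, L), [0, 0, 1.0])
        assert skeleton_length(cl) == pytest.approx(L, rel=0.02)

    def test_quarter_torus_length_within_5pct(self):
        R, r = 5.0, 0.25
        phi = np.linspace(0, np.pi / 2, 120)
        theta = np.linspace(0, 2 * np.pi, 32, endpoint=False)
        rings = []
        for p in phi:
            c = np.array([R * np.cos(p), 0, R * np.sin(p)])
            n1 = np.array([np.cos(p), 0, np.sin(p)])
            n2 = np.array([0.0, 1.0, 0.0])
            rings.append(
                c + r * np.outer(np.cos(theta), n1) + r * np.outer(np.sin(theta), n2)
            )
        nth = len(theta)
        faces = []
        for k in range(len(phi) - 1):
            a0, b0 = k * nth, (k + 1) * nth
            for j in range(nth):
                j1 = (j + 1) % nth
                faces += [(a0 + j, a0 + j1, b0 + j1), (a0 + j, b0 + j1, b0 + j)]
        V = np.vstack(rings)
        c0 = len(V)
        V = np.vstack([V, rings[0].mean(axis=0)])
        faces += [(c0, (j + 1) % nth, j) for j in range(nth)]
        c1 = len(V)
        V = np.vstack([V, rings[-1].mean(axis=0)])
        off = (len(phi) - 1) * nth
        faces += [(c1, off + j, off + (j + 1) % nth) for j in range(nth)]
        tor = trimesh.Trimesh(V, faces, process=True)
        if tor.volume < 0:
            tor.invert()
        assert tor.is_watertight
        cl = centerline_from_mesh(tor, [0, 0, 1.0])
        assert skeleton_length(cl) == pytest.approx(np.pi * R / 2, rel=0.05)

    def test_y_tube_has_one_branch_point(self):
        def tube(p0, p1, r):
            p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
            L = np.linalg.norm(p1 - p0)
            c = _capped_cylinder(r, L)
            d = (p1 - p0) / L
            z = np.array([0.0, 0.0, 1.0])
            if not np.allclose(d, z):
                ax = np.cross(z, d)
                ang = np.arccos(np.clip(d @ z, -1, 1))
                c.apply_transform(trimesh.transformations.rotation_matrix(ang, ax))
            c.apply_translation(p0)
            return c

        Y = trimesh.util.concatenate(
            [
                tube([0, 0, 0], [0, 0, 5], 0.2),
                tube([0, 0, 4.8], [2.5, 0, 9], 0.15),
                tube([0, 0, 4.8], [-2.5, 0, 9], 0.15),
            ]
        )
        bs = branch_summary(centerline_from_mesh(Y, [0, 0, 1.0]))
        assert len(bs.branch_points) == 1
        assert bs.n_branches == 2

    def test_flat_mesh_rejected(self):
        from ornmorph.errors import GeometryError

        with pytest.raises(GeometryError):
            centerline_from_mesh(_capped_cylinder(0.5, 0.05), [0, 0, 1.0])


class TestPlanarLayout:
    def test_chain_layout_is_vertical(self):
        sk = Skeleton.from_points([[0, 0, 0], [1, 1, 1], [2, 2, 2]])
        coords = planar_layout(sk)
        xs = {round(x, 9) for x, _ in coords.values()}
        assert xs == {0.0}
        ys = sorted(y for _, y in coords.values())
        assert ys[-1] == pytest.approx(skeleton_length(sk))

    def test_seven_leaves_get_distinct_x(self):
        coords = planar_layout(multi_leaf_tree(7))
        sk = multi_leaf_tree(7)
        leaf_ids = branch_summary(sk).termini
        xs = [round(coords[i][0], 6) for i in leaf_ids]
        assert len(set(xs)) == 7

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_edge_lengths_preserved(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        parents = [-1] + [int(rng.integers(1, k + 1)) for k in range(1, n)]
        sk = Skeleton(
            ids=np.arange(1, n + 1), type_codes=[3] * n,
            xyz=rng.normal(size=(n, 3)) * 3, radius=[0.1] * n,
            parent_ids=parents,
        )
        coords = planar_layout(sk)
        for i, p in zip(sk.ids, sk.parent_ids):
            if p == -1:
                continue
            l3 = float(np.linalg.norm(sk.node_xyz(i) - sk.node_xyz(p)))
            l2 = math.dist(coords[int(i)], coords[int(p)])
            assert l2 == pytest.approx(l3, rel=0.01)
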