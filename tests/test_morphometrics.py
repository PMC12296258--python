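"""Segment metrics, population summaries, derived ratios, midpoint counts."""

import numpy as np
import pytest

from ornmorph import reference as ref
from ornmorph.errors import AmbiguousRankError, GeometryError, StatisticsError
from ornmorph.morphometrics import (
    SegmentMorphometrics,
    assign_orn_identities,
    fold_range,
    midpoint_branch_count,
    percent_change,
    population_summary,
    round_half_away,
    segment_morphometrics,
    summed_morphometrics,
)
from ornmorph.synthetic import (
    ArchetypeSpec,
    make_archetype,
    make_dendrite_within_dendrite,
    make_sensillum,
)

from conftest import cylinder_stack
from ornmorph.geometry import mesh_from_contours


class TestSegmentMorphometrics:
    def test_capped_cylinder_sa_to_v(self):
        mesh = mesh_from_contours(cylinder_stack(0.25, 10.0))
        m = segment_morphometrics([mesh], 10.0)
        assert m.length == 10.0
        assert m.volume == pytest.approx(np.pi * 0.0625 * 10, rel=0.01)
        assert m.sa_to_v == pytest.approx(2 / 0.25 + 2 / 10, rel=0.02)

    def test_sheet_sa_to_v(self):
        w, t, L = 2.0, 0.1, 5.0
        rect = np.array([[0, 0], [w, 0], [w, t], [0, t]]) / 0.005
        stack_zs = range(0, int(L / 0.04) + 1, 5)
        from ornmorph.geometry import ContourStack

        mesh = mesh_from_contours(
            ContourStack([(z, rect) for z in stack_zs], (5, 5, 40))
        )
        m = segment_morphometrics([mesh], L)
        expected = 2 * (w * L + t * L + w * t) / (w * t * L)
        assert m.sa_to_v == pytest.approx(expected, rel=0.02)

    def test_annular_tube_uses_subtraction_rule(self, annulus_pair):
        outer, inner = annulus_pair
        m = segment_morphometrics([outer, inner], 5.0, hollow_pairs=[(0, 1)])
        assert m.volume_per_length == pytest.approx(np.pi * (0.25 - 0.09), rel=0.02)

    def test_zero_length_rejected(self, unit_cube_mesh):
        with pytest.raises(GeometryError):
            segment_morphometrics([unit_cube_mesh], 0.0)

    def test_derived_ratio_identities(self):
        m = SegmentMorphometrics(length=7.0, surface_area=23.0, volume=2.0)
        assert m.volume_per_length * m.length == pytest.approx(m.volume, rel=1e-12)
        assert m.sa_to_v * m.volume == pytest.approx(m.surface_area, rel=1e-12)


class TestSummedMorphometrics:
    def test_two_identical_branches_double_extensives(self):
        b = SegmentMorphometrics(length=6.0, surface_area=2.22, volume=0.06)
        total = summed_morphometrics([b, b])
        assert total.length == pytest.approx(12.0)
        assert total.surface_area == pytest.approx(4.44)
        assert total.volume == pytest.approx(0.12)
        assert total.sa_to_v == pytest.approx(b.sa_to_v)

    def test_single_branch_is_identity(self):
        b = SegmentMorphometrics(length=6.0, surface_area=2.22, volume=0.06)
        total = summed_morphometrics([b])
        assert (total.length, total.surface_area, total.volume) == (
            b.length, b.surface_area, b.volume,
        )

    def test_seven_branches_sum_length(self):
        b = SegmentMorphometrics(length=6.0, surface_area=2.22, volume=0.06)
        assert summed_morphometrics([b] * 7).length == pytest.approx(42.0)

    def test_empty_rejected(self):
        with pytest.raises(GeometryError):
            summed_morphometrics([])

    def test_additivity_total_equals_proximal_plus_distal(self):
        prox = SegmentMorphometrics(8.94, 8.97, 0.60)
        dist = SegmentMorphometrics(29.09, 10.77, 0.30)
        total = summed_morphometrics([prox, dist])
        assert total.length == pytest.approx(prox.length + dist.length, rel=1e-6)
        assert total.surface_area == pytest.approx(
            prox.surface_area + dist.surface_area, rel=1e-6
        )
        assert total.volume == pytest.approx(prox.volume + dist.volume, rel=1e-6)


class TestPopulationSummary:
    def test_printed_cuticle_cv(self):
        # the printed cuticle length 9.50 ± 0.98 reproduces CV 0.10
        mean, sd = ref.CUTICLE["length"]
        assert round_half_away(sd / mean, 2) == pytest.approx(0.10)

    def test_constant_column_cv_zero(self):
        s = population_summary([4.2] * 10)
        assert s.sd == pytest.approx(0.0, abs=1e-12)
        assert s.cv == pytest.approx(0.0, abs=1e-12)

    def test_small_sample(self):
        s = population_summary([1.0, 2.0, 3.0])
        assert s.mean == pytest.approx(2.0)
        assert s.sd == pytest.approx(1.0)
        assert s.cv == pytest.approx(0.5)
        assert s.n == 3

    def test_n_below_two_rejected(self):
        with pytest.raises(StatisticsError):
            population_summary([1.0])


class TestDerivedRatios:
    def test_flattened_vs_cylindrical_surface_gain(self):
        # +21.6%, printed as "about 22% larger"
        pc = percent_change(19.90, 24.19)
        assert pc == pytest.approx(21.56, abs=0.01)
        assert round_half_away(pc) == 22

    def test_volume_per_length_reduction(self):
        assert percent_change(0.25, 0.18) == pytest.approx(-28.0)

    def test_degenerate_fold(self):
        assert fold_range(10, 10) == 1.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)
        with pytest.raises(ValueError):
            fold_range(0.0, 1.0)

    def test_sa_to_v_monotonicity_in_shape_parameters(self):
        def cyl_sav(r, L=10.0):
            return 2 / r + 2 / L

        def sheet_sav(w, t, L=10.0):
            return 2 * (w * L + t * L + w * t) / (w * t * L)

        radii = [0.1, 0.2, 0.3, 0.5]
        assert all(
            cyl_sav(a) > cyl_sav(b) for a, b in zip(radii, radii[1:])
        )
        thicknesses = [0.05, 0.1, 0.2]
        assert all(
            sheet_sav(2.0, a) > sheet_sav(2.0, b)
            for a, b in zip(thicknesses, thicknesses[1:])
        )

    def test_flattening_raises_sa_to_v_at_equal_volume(self):
        # sheet and cylinder of identical volume and length
        w, t, L = 2.0, 0.1, 10.0
        v = w * t * L
        r = np.sqrt(v / (np.pi * L))
        sheet = 2 * (w * L + t * L + w * t) / v
        cyl = (2 * np.pi * r * L + 2 * np.pi * r**2) / v
        assert sheet > 2.5 * cyl


class TestMidpointCount:
    def test_default_scene_count_matches_ground_truth(self):
        scene = make_sensillum(seed=3)
        n, lumen_area = midpoint_branch_count(
            [nr.all_meshes for nr in scene.neurons],
            scene.cuticle_lumen,
            scene.cuticle_axis,
        )
        assert n == scene.midpoint_count
        assert lumen_area > 0

    def test_unbranched_trio(self):
        neurons = [
            make_archetype(
                ArchetypeSpec(kind="cylinder", radius=0.1, length=9.0, dt=0.9,
                              center=(0.4 * np.cos(a), 0.4 * np.sin(a))),
                f"c{k}", "x",
            )
            for k, a in enumerate(np.linspace(0, 2 * np.pi, 3, endpoint=False))
        ]
        from ornmorph.synthetic import make_cuticle_shell

        _, lumen, axis, _, _ = make_cuticle_shell()
        n, _ = midpoint_branch_count([n.all_meshes for n in neurons], lumen, axis)
        assert n == 3

    def test_fully_curled_sheet_counts_once_and_enclosed_separately(self):
        scene = make_dendrite_within_dendrite(seed=0)
        n, _ = midpoint_branch_count(
            [nr.all_meshes for nr in scene.neurons],
            scene.cuticle_lumen,
            scene.cuticle_axis,
        )
        # the enclosing ring is 1 dendrite; its lumen hole is not counted,
        # each enclosed neighbor branch is
        assert n == scene.midpoint_count == 3


class TestIdentityAssignment:
    def test_published_size_ratio_recovers_rank(self):
        sizes = [("n1", 5.2), ("n2", 4.5), ("n3", 2.3), ("n4", 1.0)]
        assert assign_orn_identities(sizes) == {
            "n1": "A", "n2": "B", "n3": "C", "n4": "D",
        }

    def test_tie_rejected(self):
        with pytest.raises(AmbiguousRankError):
            assign_orn_identities([("a", 3.0), ("b", 3.0)])

    def test_single_neuron_gets_a(self):
        assert assign_orn_identities([("solo", 2.0)]) == {"solo": "A"}

    def test_scene_sizes_recover_identities(self):
        scene = make_sensillum(seed=5)
        labels = assign_orn_identities(
            [(n.neuron_id, n.size) for n in scene.neurons]
        )
        for n in scene.neurons:
            assert labels[n.neuron_id] == n.orn_type[-1]
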