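"""Generator ground truth, pipeline-vs-ground-truth recovery, determinism."""

import numpy as np
import pandas as pd
import pytest

from ornmorph import reference as ref
from ornmorph.errors import GeometryError
from ornmorph.morphometrics import segment_morphometrics
from ornmorph.skeleton import branch_summary
from ornmorph.synthetic import (
    ArchetypeSpec,
    ab1d_population,
    make_archetype,
    make_cuticle_shell,
    make_sensillum,
    sample_population,
    substream,
)

ALL_KINDS = ("cylinder", "sheet", "curled_tube", "split_sheets", "mixed",
             "branched_tree")


class TestGroundTruth:
    def test_cylinder_closed_form(self):
        n = make_archetype(ArchetypeSpec(kind="cylinder", radius=0.5, length=10.0))
        seg = n.segments["total"]
        assert seg.volume == pytest.approx(np.pi * 0.25 * 10, rel=1e-12)
        assert seg.surface_area == pytest.approx(
            2 * np.pi * 0.5 * 10 + 2 * np.pi * 0.25, rel=1e-12
        )

    def test_sheet_closed_form(self):
        n = make_archetype(
            ArchetypeSpec(kind="sheet", width=2.0, thickness=0.1, fp=0.4, dt=0.926)
        )
        seg = n.segments["distal"]
        w, t, L = 2.0, 0.1, seg.length
        assert seg.surface_area / seg.volume == pytest.approx(
            2 * (w * L + t * L + w * t) / (w * t * L), rel=1e-12
        )

    def test_curled_tube_volume_is_annular(self):
        n = make_archetype(ArchetypeSpec(kind="curled_tube", r_outer=0.4, r_inner=0.3))
        seg = n.segments["distal"]
        assert seg.volume == pytest.approx(
            np.pi * (0.16 - 0.09) * seg.length, rel=1e-12
        )

    def test_branched_tree_has_requested_leaves(self):
        n = make_archetype(ArchetypeSpec(kind="branched_tree", n_branches=7))
        assert branch_summary(n.skeleton).n_branches == 7

    def test_invalid_spec_rejected(self):
        with pytest.raises(GeometryError):
            ArchetypeSpec(kind="banana")
        with pytest.raises(GeometryError):
            ArchetypeSpec(kind="sheet", thickness=-1)
        with pytest.raises(GeometryError):
            ArchetypeSpec(kind="sheet", fp=1.5)
        with pytest.raises(GeometryError):
            ArchetypeSpec(kind="branched_tree", n_branches=11)


class TestPipelineVsGroundTruth:
    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_measured_morphometrics_within_2pct(self, kind):
        n = make_archetype(ArchetypeSpec(kind=kind), neuron_id=f"gt_{kind}")
        for seg in n.segments.values():
            m = segment_morphometrics(seg.meshes, seg.length, seg.hollow_pairs)
            assert m.surface_area == pytest.approx(seg.surface_area, rel=0.02)
            assert m.volume == pytest.approx(seg.volume, rel=0.02)

    def test_cuticle_shell_hollow_morphometrics(self):
        from ornmorph.geometry import hollow_morphometrics

        outer, lumen, axis, sa_true, v_true = make_cuticle_shell()
        sa, v = hollow_morphometrics(outer, lumen)
        assert sa == pytest.approx(sa_true, rel=0.02)
        assert v == pytest.approx(v_true, rel=0.02)
        assert axis.total_length == pytest.approx(9.5)


class TestScenes:
    def test_default_scene_packs_and_ranks(self):
        scene = make_sensillum(seed=2)
        assert len(scene.neurons) == 4
        sizes = sorted((n.size for n in scene.neurons), reverse=True)
        base = sizes[-1]
        np.testing.assert_allclose(
            [s / base for s in sizes], [5.2, 4.5, 2.3, 1.0], rtol=0.05
        )

    def test_unpackable_scene_rejected(self):
        # two wide sheets at the same location cannot coexist
        spec = dict(kind="sheet", width=2.0, thickness=0.1)
        scene_spec = [
            ("n1", spec, 0, 0.0, 10.0),
            ("n2", spec, 10, 0.05, 10.0),
        ]
        with pytest.raises(GeometryError):
            make_sensillum(scene_spec, seed=0)

    def test_wrong_neuron_count_rejected(self):
        with pytest.raises(GeometryError):
            make_sensillum([], seed=0)


class TestDeterminism:
    def test_same_seed_reproduces_population_table(self):
        a = sample_population("ab1C", seed=9)
        b = sample_population("ab1C", seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = sample_population("ab1C", seed=9)
        b = sample_population("ab1C", seed=10)
        assert not a.drop(columns=["neuron_id", "orn_type", "category"]).equals(
            b.drop(columns=["neuron_id", "orn_type", "category"])
        )

    def test_same_seed_reproduces_meshes(self):
        n1 = make_archetype(ArchetypeSpec(kind="branched_tree", seed=4), "d")
        n2 = make_archetype(ArchetypeSpec(kind="branched_tree", seed=4), "d")
        for s1, s2 in zip(n1.segments.values(), n2.segments.values()):
            for m1, m2 in zip(s1.meshes, s2.meshes):
                np.testing.assert_array_equal(m1.vertices, m2.vertices)

    def test_substream_is_insertion_order_independent(self):
        r1 = substream(7, "neuron_a").normal()
        _ = substream(7, "neuron_b").normal()
        r1_again = substream(7, "neuron_a").normal()
        assert r1 == r1_again


class TestSampledPopulations:
    def test_category_counts_exact(self):
        df = sample_population("ab1C", seed=1)
        assert df["category"].value_counts().to_dict() == ref.AB1C_CATEGORY_COUNTS
        df_d = sample_population("ab1D", seed=1)
        assert df_d["category"].value_counts().to_dict() == ref.AB1D_CATEGORY_COUNTS

    def test_rows_internally_consistent(self):
        df = sample_population("ab1C", seed=3)
        np.testing.assert_allclose(
            df.total_length, df.proximal_length + df.distal_length
        )
        np.testing.assert_allclose(
            df.total_sa_to_v, df.total_surface_area / df.total_volume
        )
        assert (df.filter(like="_").select_dtypes(float) > 0).all().all()

    def test_sd_zero_spec_gives_identical_rows(self):
        spec = {
            "only": {
                "total": {
                    "length": (10.0, 0.0),
                    "surface_area": (20.0, 0.0),
                    "volume": (2.0, 0.0),
                }
            }
        }
        df = sample_population("x", counts={"only": 5}, seed=0, summary_spec=spec)
        assert df.total_length.nunique() == 1

    def test_infeasible_truncation_rejected(self):
        spec = {
            "bad": {
                "total": {
                    "length": (-1.0, 1.0),
                    "surface_area": (1.0, 1.0),
                    "volume": (1.0, 1.0),
                }
            }
        }
        with pytest.raises(GeometryError):
            sample_population("x", counts={"bad": 2}, seed=0, summary_spec=spec)

    def test_means_recovered_within_sampling_error(self):
        df = sample_population("ab1C", seed=5)
        n = len(df)
        for metric in ("length", "surface_area", "volume"):
            for segment in ("proximal", "distal"):
                mean, sd = ref.AB1C_TOTAL_ROW[segment][metric]
                # per-category means differ slightly from the pooled row;
                # the pooled draw must still sit within sampling error
                assert df[f"{segment}_{metric}"].mean() == pytest.approx(
                    mean, abs=max(3 * sd / np.sqrt(n), 0.05 * mean)
                )

    def test_flattening_contrast_direction(self):
        # the flattened segment's SA/V exceeds the cylindrical segment's
        # by >2.5-fold in nearly all sampled populations
        hits = 0
        for seed in range(50):
            df = sample_population("ab1C", seed=seed)
            ratio = df.distal_sa_to_v.mean() / df.proximal_sa_to_v.mean()
            hits += ratio > 2.5
        assert hits >= 48
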