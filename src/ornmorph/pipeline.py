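"""Pipeline stages binding generation, measurement, classification and
statistics, plus run configuration.

Stages mirror the order of an EM-morphometry workflow — segmentation
(here: synthetic generation), skeletonization, morphometrics, statistics —
and are deterministic under a fixed seed.  Every stage logs a structured
record (stage, object count, elapsed seconds) and the full configuration
(with its hash) is embedded in every output bundle, so each threshold that
enters a result is auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cls
from . import stats as st
from . import synthetic as syn
from .axis import landmark_proportions
from .errors import OrnmorphError
from .geometry import save_mesh
from .morphometrics import population_summary, segment_morphometrics
from .skeleton import skeleton_length, write_swc

log = logging.getLogger("ornmorph")

__all__ = [
    "RunConfig",
    "generate",
    "measure",
    "classify",
    "summarize",
    "compare",
    "measure_neuron",
]

METRICS = ("length", "surface_area", "volume", "volume_per_length", "sa_to_v")
SEGMENTS = ("proximal", "distal", "total")


@dataclass
class RunConfig:
    """All knobs of a pipeline run; serialized into every output bundle."""

    seed: int = 0
    out_dir: str = "scratch/run"
    # classification thresholds
    aspect_threshold: float = cls.DEFAULT_ASPECT_THRESHOLD
    persistence_um: float = cls.DEFAULT_PERSISTENCE_UM
    evidence_fraction: float = cls.DEFAULT_EVIDENCE_FRACTION
    profile_step: float = 0.02  # cuticle-proportion step between stations
    midpoint_proportion: float = 0.5
    alpha: float = st.ALPHA
    # population design (category -> n)
    ab1c_counts: dict = field(default_factory=lambda: dict(syn.ref.AB1C_CATEGORY_COUNTS))
    ab1d_counts: dict = field(default_factory=lambda: dict(syn.ref.AB1D_CATEGORY_COUNTS))

    def __post_init__(self) -> None:
        if not 0 < self.profile_step <= 0.1:
            raise OrnmorphError("profile_step must be in (0, 0.1]")
        if not 1.0 <= self.aspect_threshold:
            raise OrnmorphError("aspect_threshold must be >= 1")
        if not 0 < self.alpha < 1:
            raise OrnmorphError("alpha must be in (0, 1)")
        if not 0 <= self.midpoint_proportion <= 1:
            raise OrnmorphError("midpoint_proportion must be in [0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls_, path: str | Path) -> "RunConfig":
        return cls_(**yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = yaml.safe_dump(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.time()
            out = fn(*args, **kwargs)
            n = len(out) if hasattr(out, "__len__") else 1
            log.info("stage=%s n_objects=%s elapsed=%.2fs", name, n, time.time() - t0)
            return out

        wrapper.__name__ = fn.__name__
        wrapper.__doc__ = fn.__doc__
        return wrapper

    return deco


# ---------------------------------------------------------------------------
# generate
# ---------------------------------------------------------------------------


@_stage("generate")
def generate(config: RunConfig, write: bool = False):
    """Generate the synthetic study populations (and optionally a bundle).

    Returns ``(ab1c_neurons, ab1d_neurons, axis)``.  With ``write=True`` the
    scene bundle (ASCII PLY meshes, SWC skeletons, contour-stack JSON,
    ground-truth JSON, config YAML) lands under ``config.out_dir``.
    """
    neurons_c = syn.archetype_population(config.ab1c_counts, seed=config.seed)
    neurons_d = syn.ab1d_population(config.ab1d_counts, seed=config.seed)
    _, _, axis, _, _ = syn.make_cuticle_shell()
    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        truth = []
        for n in neurons_c + neurons_d:
            ndir = out / n.neuron_id
            ndir.mkdir(exist_ok=True)
            for seg in n.segments.values():
                for i, mesh in enumerate(seg.meshes):
                    save_mesh(mesh, ndir / f"{seg.name}_{i}.ply")
                for i, stack in enumerate(seg.stacks):
                    stack.to_json(ndir / f"{seg.name}_{i}.json")
            write_swc(n.skeleton, ndir / "skeleton.swc", comment=n.neuron_id)
            truth.append(
                {
                    "neuron_id": n.neuron_id,
                    "orn_type": n.orn_type,
                    "category": n.category,
                    "fp": n.fp,
                    "bp": n.bp,
                    "dt": n.dt,
                    "n_branches": n.n_branches,
                    "segments": {
                        s.name: {
                            "length": s.length,
                            "surface_area": s.surface_area,
                            "volume": s.volume,
                        }
                        for s in n.segments.values()
                    },
                }
            )
        (out / "ground_truth.json").write_text(
            json.dumps({"config_hash": config.config_hash, "neurons": truth}, indent=1)
        )
    return neurons_c, neurons_d, axis


# ---------------------------------------------------------------------------
# measure
# ---------------------------------------------------------------------------


def _split_node(neuron: syn.SyntheticNeuron):
    """Skeleton node id nearest the flattening/branch landmark (or None)."""
    lm = neuron.landmarks
    anchor = (
        lm.flattening_point
        if lm.flattening_point is not None
        else lm.primary_branch_point
    )
    if anchor is None:
        return None
    d = np.linalg.norm(neuron.skeleton.xyz - np.asarray(anchor), axis=1)
    return int(neuron.skeleton.ids[int(np.argmin(d))])


def measure_neuron(neuron: syn.SyntheticNeuron, axis, config: RunConfig) -> dict:
    """One population-table row: segment morphometrics plus landmarks."""
    row: dict = {
        "neuron_id": neuron.neuron_id,
        "orn_type": neuron.orn_type,
        "true_category": neuron.category,
        "n_branches": neuron.n_branches,
    }
    skel = neuron.skeleton
    split = _split_node(neuron)
    seg_lengths: dict[str, float] = {}
    if split is not None and len(neuron.segments) > 1:
        distal_ids = set(skel.subtree_ids(split))
        prox_ids = set(int(i) for i in skel.ids) - distal_ids | {split}
        seg_lengths["proximal"] = skeleton_length(skel, prox_ids)
        seg_lengths["distal"] = skeleton_length(skel, distal_ids)
    else:
        seg_lengths["total"] = skeleton_length(skel)
    morph = {}
    for name, seg in neuron.segments.items():
        morph[name] = segment_morphometrics(
            seg.meshes, seg_lengths.get(name, seg.length), seg.hollow_pairs
        )
    if "proximal" in morph and "distal" in morph:
        from .morphometrics import summed_morphometrics

        morph["total"] = summed_morphometrics([morph["proximal"], morph["distal"]])
    for seg_name, m in morph.items():
        row[f"{seg_name}_length"] = m.length
        row[f"{seg_name}_surface_area"] = m.surface_area
        row[f"{seg_name}_volume"] = m.volume
        row[f"{seg_name}_volume_per_length"] = m.volume_per_length
        row[f"{seg_name}_sa_to_v"] = m.sa_to_v
    props = landmark_proportions(neuron.landmarks, axis, neuron.neuron_id)
    for _, lrow in props.iterrows():
        if lrow.landmark in (
            "ciliary_constriction",
            "flattening_point",
            "primary_branch_point",
            "dendritic_terminus",
        ):
            row[lrow.landmark] = lrow.proportion
    return row


@_stage("measure")
def measure(neurons, axis, config: RunConfig) -> pd.DataFrame:
    """Population table: one morphometrics row per neuron."""
    return pd.DataFrame([measure_neuron(n, axis, config) for n in neurons])


# ---------------------------------------------------------------------------
# classify
# ---------------------------------------------------------------------------


@_stage("classify")
def classify(neurons, axis, config: RunConfig) -> pd.DataFrame:
    """Morphology category calls with evidence, one row per neuron."""
    rows = []
    for n in neurons:
        row = {
            "neuron_id": n.neuron_id,
            "orn_type": n.orn_type,
            "true_category": n.category,
        }
        if n.orn_type == "ab1D" or n.fp is None and n.bp is None and n.category in (
            "unbranched", "branched",
        ):
            label, n_branches = cls.classify_ab1D(n.skeleton)
            row.update(category=label, n_branches=n_branches)
        else:
            meshes, pairs = n.all_meshes
            profiles = cls.profile_along_axis(
                meshes, axis, step=config.profile_step, hollow_pairs=pairs
            )
            fp = cls.detect_flattening_point(
                profiles,
                axis.total_length,
                aspect_threshold=config.aspect_threshold,
                persistence_um=config.persistence_um,
            )
            if fp is None:
                row.update(category="cylindrical", flattening_point=np.nan)
            else:
                label, evidence = cls.classify_ab1C(
                    profiles,
                    fp,
                    evidence_fraction=config.evidence_fraction,
                )
                row.update(
                    category=label,
                    flattening_point=fp,
                    curl_fraction=evidence["curl_fraction"],
                    split_fraction=evidence["split_fraction"],
                )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# summarize
# ---------------------------------------------------------------------------


@_stage("summarize")
def summarize(table: pd.DataFrame, by: str = "true_category") -> pd.DataFrame:
    """Per-category mean ± SD ± CV summary of every segment metric."""
    rows = []
    groups = [("all", table)] + list(table.groupby(by))
    for cat, sub in groups:
        for seg in SEGMENTS:
            for metric in METRICS:
                col = f"{seg}_{metric}"
                if col not in sub or sub[col].dropna().shape[0] < 2:
                    continue
                s = population_summary(sub[col])
                rows.append(
                    {
                        "category": cat,
                        "segment": seg,
                        "metric": metric,
                        "mean": s.mean,
                        "sd": s.sd,
                        "cv": s.cv,
                        "n": s.n,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# compare
# ---------------------------------------------------------------------------


def _result_dict(r: st.TestResult) -> dict:
    return {
        "test": r.test_name,
        "statistic": r.statistic,
        "p_value": r.p_value,
        "n": list(r.n),
        "significant": r.significant,
        **({"detail": r.detail} if r.detail else {}),
    }


@_stage("compare")
def compare(
    ab1c: pd.DataFrame | None = None,
    ab1d: pd.DataFrame | None = None,
    alpha: float = st.ALPHA,
) -> dict:
    """The statistical battery over population tables.

    For flattened-sheet neurons: paired comparisons of the proximal
    (cylindrical) vs distal (flattened) segment, and Kruskal-Wallis with a
    letter display across morphological categories.  For branched/unbranched
    neurons: rank-sum comparisons of whole-dendrite metrics between the two
    branching categories, paired proximal/distal comparisons within branched
    neurons, and linear fits of distal metrics against branch number.
    """
    out: dict = {}
    if ab1c is not None and len(ab1c) >= 3:
        section: dict = {}
        for metric in ("volume_per_length", "sa_to_v", "surface_area"):
            x = ab1c[f"proximal_{metric}"].to_numpy()
            y = ab1c[f"distal_{metric}"].to_numpy()
            section[f"paired_proximal_vs_distal_{metric}"] = _result_dict(
                st.paired_t(x, y)
            )
        letters: dict = {}
        cats = ab1c.groupby("true_category")
        if cats.ngroups >= 3 and cats.size().min() >= 2:
            for metric in ("total_length", "total_surface_area", "total_volume"):
                groups = {
                    str(cat): sub[metric].to_numpy() for cat, sub in cats
                }
                res, ld = st.kruskal_letters(groups, alpha=alpha)
                letters[metric] = {
                    "omnibus": _result_dict(res),
                    "letters": ld.letters,
                }
        section["kruskal_by_category"] = letters
        out["ab1c"] = section
    if ab1d is not None and len(ab1d) >= 3:
        section = {}
        unb = ab1d[ab1d.true_category == "unbranched"]
        bra = ab1d[ab1d.true_category == "branched"]
        if len(unb) >= 3 and len(bra) >= 3:
            for metric in ("length", "surface_area", "volume", "sa_to_v"):
                section[f"unbranched_vs_branched_total_{metric}"] = _result_dict(
                    st.mann_whitney(
                        unb[f"total_{metric}"].to_numpy(),
                        bra[f"total_{metric}"].to_numpy(),
                    )
                )
            for metric in ("length", "surface_area", "volume", "sa_to_v"):
                pcol, dcol = f"proximal_{metric}", f"distal_{metric}"
                sub = bra.dropna(subset=[pcol, dcol])
                if len(sub) >= 2:
                    section[f"branched_paired_proximal_vs_distal_{metric}"] = (
                        _result_dict(st.paired_t(sub[pcol], sub[dcol]))
                    )
            fits = {}
            if "n_branches" in bra:
                for seg in ("proximal", "distal"):
                    for metric in ("length", "surface_area", "volume", "sa_to_v"):
                        col = f"{seg}_{metric}"
                        sub = bra.dropna(subset=[col])
                        if sub["n_branches"].nunique() >= 2 and len(sub) >= 3:
                            slope, intercept, r2 = st.linear_fit(
                                sub["n_branches"], sub[col]
                            )
                            fits[col] = {
                                "slope": slope,
                                "intercept": intercept,
                                "r_squared": r2,
                            }
            section["fits_vs_branch_count"] = fits
        out["ab1d"] = section
    return out
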