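"""Derived ratios from the published population summary statistics.

Reads nothing but the packaged reference table; reproduces the headline
contrasts of the flattening/branching analysis by exact arithmetic:
cuticle CVs, the flattened-vs-cylindrical segment contrasts, the
branched-vs-unbranched contrasts, and the surface-area fold spans.

Writes results/published_contrasts.json.
"""

import json
from pathlib import Path

from ornmorph import reference as ref
from ornmorph.morphometrics import fold_range, percent_change, round_half_away

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    c = ref.AB1C_TOTAL_ROW
    b = ref.AB1D_SEGMENTS["branched"]
    rows = {
        "cv_cuticle_length": round_half_away(
            ref.CUTICLE["length"][1] / ref.CUTICLE["length"][0], 2
        ),
        "cv_cuticle_surface_area": round_half_away(
            ref.CUTICLE["surface_area"][1] / ref.CUTICLE["surface_area"][0], 2
        ),
        "cv_cuticle_volume": round_half_away(
            ref.CUTICLE["volume"][1] / ref.CUTICLE["volume"][0], 2
        ),
        "ab1c_flattened_sa_increase_pct": percent_change(
            c["proximal"]["surface_area"][0], c["distal"]["surface_area"][0]
        ),
        "ab1c_flattened_vl_change_pct": percent_change(
            c["proximal"]["volume_per_length"][0], c["distal"]["volume_per_length"][0]
        ),
        "ab1c_flattened_sav_ratio_pct": 100
        * c["distal"]["sa_to_v"][0]
        / c["proximal"]["sa_to_v"][0],
        "ab1d_branched_sav_increase_pct": percent_change(
            ref.AB1D_SEGMENTS["unbranched"]["total"]["sa_to_v"][0],
            b["total"]["sa_to_v"][0],
        ),
        "ab1d_distal_sa_increase_pct": percent_change(
            b["proximal"]["surface_area"][0], b["distal"]["surface_area"][0]
        ),
        "ab1d_distal_length_increase_pct": percent_change(
            b["proximal"]["length"][0], b["distal"]["length"][0]
        ),
        "ab1d_distal_volume_ratio_pct": 100
        * b["distal"]["volume"][0]
        / b["proximal"]["volume"][0],
        "ab1d_distal_sav_ratio_pct": 100
        * b["distal"]["sa_to_v"][0]
        / b["proximal"]["sa_to_v"][0],
        "ab1c_sa_fold_range": fold_range(*ref.AB1C_SA_RANGE),
        "ab1d_sa_fold_range": fold_range(*ref.AB1D_SA_RANGE),
    }
    OUT.mkdir(exist_ok=True)
    (OUT / "published_contrasts.json").write_text(json.dumps(rows, indent=1))
    print("Flattening: the sheet segment carries "
          f"{rows['ab1c_flattened_sa_increase_pct']:+.1f}% surface area at "
          f"{rows['ab1c_flattened_vl_change_pct']:+.1f}% cross-sectional area, "
          f"so its SA/V is {rows['ab1c_flattened_sav_ratio_pct']:.0f}% of the "
          "cylindrical segment's.")
    print("Branching: branched dendrites gain surface "
          f"({rows['ab1d_distal_sa_increase_pct']:+.1f}% distal vs proximal) "
          "but only modestly raise whole-dendrite SA/V "
          f"({rows['ab1d_branched_sav_increase_pct']:+.1f}%).")
    print(f"wrote {OUT / 'published_contrasts.json'}")


if __name__ == "__main__":
    main()
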