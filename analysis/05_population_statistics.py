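"""Statistical battery over the measured synthetic populations.

Paired comparisons of cylindrical vs flattened segments, Kruskal-Wallis
with compact letters across sheet categories, rank-sum comparisons of
branched vs unbranched dendrites, and linear fits of distal morphometrics
against branch count.

Writes results/statistics.json.
"""

import json
import logging
from pathlib import Path

from ornmorph import pipeline as pl

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    cfg = pl.RunConfig(seed=SEED)
    neurons_c, neurons_d, axis = pl.generate(cfg)
    table_c = pl.measure(neurons_c, axis, cfg)
    table_d = pl.measure(neurons_d, axis, cfg)
    results = pl.compare(table_c, table_d, alpha=cfg.alpha)
    results["config_hash"] = cfg.config_hash
    OUT.mkdir(exist_ok=True)
    (OUT / "statistics.json").write_text(json.dumps(results, indent=1))

    sav = results["ab1c"]["paired_proximal_vs_distal_sa_to_v"]
    print(f"flattened vs cylindrical SA/V: paired t = {sav['statistic']:.1f}, "
          f"p = {sav['p_value']:.2g} (n = {sav['n'][0]})")
    for metric, entry in results["ab1c"]["kruskal_by_category"].items():
        print(f"{metric}: KW p = {entry['omnibus']['p_value']:.2f}, "
              f"letters {entry['letters']}")
    mw = results["ab1d"]["unbranched_vs_branched_total_surface_area"]
    print(f"branched vs unbranched total surface: rank-sum p = "
          f"{mw['p_value']:.3g}")
    fits = results["ab1d"]["fits_vs_branch_count"]
    scaling = {k: round(v["r_squared"], 2) for k, v in fits.items()
               if k.startswith("distal")}
    print(f"distal metrics vs branch count, R²: {scaling}")
    print(f"wrote {OUT / 'statistics.json'}")


if __name__ == "__main__":
    main()
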