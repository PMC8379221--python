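#!/usr/bin/env python
"""Confounder-balanced group comparisons.

Runs the distance-quartet analysis (greedy packing under min-max cutoffs
with indistinguishability verification, vs the exhaustive oracle on small
instances) and writes the per-group residual fold changes and the balance
report.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from rbpmt import workflows as W
from rbpmt.io import setup_logging, write_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--log-level", default="INFO")
    args = ap.parse_args()
    setup_logging(args.log_level)

    r = W.quartet_fidelity(seed=args.seed)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    write_table(pd.DataFrame({
        "group": [1, 2, 3, 4],
        "mean_residual_log2fc": r["group_mean_residuals"],
    }), args.out_dir / "quartet_groups.tsv")
    (args.out_dir / "quartet_summary.json").write_text(json.dumps({
        k: v for k, v in r.items() if k != "group_mean_residuals"}, indent=2))
    print(f"{r['n_quartets']} quartets; oracle match "
          f"{r['oracle_match_fraction']:.0%}; monotone trend: "
          f"{r['monotone_trend']}; g1-vs-g4 p = {r['p_group1_vs_group4']:.2g}")


if __name__ == "__main__":
    main()
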