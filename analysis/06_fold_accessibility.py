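#!/usr/bin/env python
"""Constrained-folding accessibility model on a simulated cohort.

For each target transcript, folds the fragment around the site under four
constraint sets (free; RBS unpaired; site unpaired + seed duplex; both) and
writes the ΔG quartet with the two accessibility costs
(ddG_nomodel = dG_miR - dG0, ddG_model = dG_RBP+miR - dG_RBP). A negative
difference ddG_model - ddG_nomodel means the bound RBP pre-opens the site.
"""

import argparse
from pathlib import Path

import pandas as pd

from rbpmt.io import setup_logging, write_table
from rbpmt.simulate import (
    DistanceDistribution,
    SimulationConfig,
    generate_transcriptome,
    implant_rbs,
)
from rbpmt.annotate import RbsInterval, SiteMatch
from rbpmt.structure import site_accessibility_energies


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-transcripts", type=int, default=40)
    ap.add_argument("--fragment", type=int, default=120,
                    help="fragment width centred on the site (nt)")
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--log-level", default="INFO")
    args = ap.parse_args()
    setup_logging(args.log_level)

    # close binding so the RBS falls inside the folded fragment
    cfg = SimulationConfig(
        seed=args.seed, n_transcripts=args.n_transcripts, p_overlap=0.2,
        distance_distribution=DistanceDistribution(kind="uniform", d_max=30))
    transcripts, truth = generate_transcriptome(cfg)
    rbs = implant_rbs(transcripts, truth, cfg)
    rbs_by_tx: dict[str, list[RbsInterval]] = {}
    for iv in rbs:
        rbs_by_tx.setdefault(iv.transcript_id, []).append(iv)
    rows = []
    half = args.fragment // 2
    for tx in transcripts:
        site = truth.sites.get(tx.id)
        if site is None:
            continue
        mid = (site.start + site.end) // 2
        lo = max(0, mid - half)
        hi = min(len(tx), mid + half)
        frag = tx.utr_seq[lo:hi]
        local_site = SiteMatch(tx.id, site.start - lo, site.end - lo,
                               site.site_type, site.mirna_id)
        local_rbs = [
            RbsInterval(iv.rbp_id, tx.id, max(0, iv.start - lo),
                        min(len(frag), iv.end - lo), iv.stringency)
            for iv in rbs_by_tx.get(tx.id, ())
            if iv.start < hi and iv.end > lo
        ]
        fe = site_accessibility_energies(frag, local_site, local_rbs,
                                         truth.mirna)
        rows.append({
            "transcript": tx.id, "d": truth.d_true[tx.id],
            "dG0": fe.dG0, "dG_miR": fe.dG_miR, "dG_RBP": fe.dG_RBP,
            "dG_RBP_miR": fe.dG_RBP_miR,
            "ddG_nomodel": fe.ddG_nomodel, "ddG_model": fe.ddG_model,
        })
    df = pd.DataFrame(rows)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    write_table(df, args.out_dir / "energies.tsv")
    eased = (df["ddG_model"] < df["ddG_nomodel"]).mean()
    print(f"{len(df)} fragments; RBP binding lowers the accessibility cost "
          f"in {eased:.0%} of them "
          f"(mean ddG_nomodel {df['ddG_nomodel'].mean():.2f}, "
          f"mean ddG_model {df['ddG_model'].mean():.2f} kcal/mol)")


if __name__ == "__main__":
    main()
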