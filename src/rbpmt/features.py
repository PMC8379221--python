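"""Confounding features of miRNA targeting efficacy.

Four sequence/context features are known to confound any association between
binding distance and repression: local AU content around the site, target-site
abundance (TA) of the miRNA across the transcriptome, seed-pairing stability
(SPS) of the miRNA seed duplex, and 3'UTR length. They are computed here in
their simplest defensible forms and carried on every feature row so the
regression and matched-sampling corrections can remove them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import (
    MicroRNA,
    RbsInterval,
    SiteMatch,
    count_rbps_near,
    distance_mts_rbs,
    scan_mts,
)
from .io import Transcript

#: Per-pair duplex energies (kcal/mol) used for SPS and the seed-duplex bonus.
DEFAULT_PAIR_ENERGY: dict[str, float] = {"GC": -3.0, "AU": -2.0, "GU": -1.0}

FEATURE_COLUMNS = ["transcript", "mirna", "d", "overlapped", "n_rbp",
                   "local_au", "ta", "sps", "log10_len", "log2fc"]

CONFOUNDERS = ["local_au", "ta", "sps", "log10_len"]


def local_au_content(
    utr_seq: str, site: SiteMatch, window: int = 30,
    distance_weighted: bool = False,
) -> float:
    """Fraction of A/U in the flanks of a site.

    Counts up to ``window`` nt upstream plus up to ``window`` nt downstream
    (site excluded), truncating at UTR ends; the denominator is the number of
    bases actually available. With ``distance_weighted`` each flank base gets
    weight 1/(distance from the site edge), the weighting used in the
    context-score literature (off by default).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if site.start < 0 or site.end > len(utr_seq):
        raise ValueError("site outside UTR")
    up = utr_seq[max(0, site.start - window) : site.start]
    down = utr_seq[site.end : site.end + window]
    if not distance_weighted:
        flanks = up + down
        if not flanks:
            return 0.0
        return sum(b in "AU" for b in flanks) / len(flanks)
    num = den = 0.0
    for i, b in enumerate(reversed(up)):
        w = 1.0 / (i + 1)
        den += w
        num += w * (b in "AU")
    for i, b in enumerate(down):
        w = 1.0 / (i + 1)
        den += w
        num += w * (b in "AU")
    return num / den if den else 0.0


def target_abundance(mirna: MicroRNA, transcriptome: Sequence[Transcript]) -> float:
    """log10(1 + total canonical site count) across the supplied 3'UTRs.

    Computed on the supplied transcriptome only, never a built-in reference;
    monotone nondecreasing as transcripts are added.
    """
    if not transcriptome:
        raise ValueError("empty transcriptome")
    total = sum(len(scan_mts(t.utr_seq, mirna)) for t in transcriptome)
    return float(np.log10(1 + total))


def seed_pairing_stability(
    mirna: MicroRNA, pair_energy: Mapping[str, float] | None = None
) -> float:
    """Additive seed:target duplex energy over the 7 seed positions (kcal/mol).

    Each seed base pairs its perfect Watson-Crick complement, so the pair
    class is determined by the seed letter alone (G/C -> GC, A/U -> AU).
    """
    table = dict(DEFAULT_PAIR_ENERGY if pair_energy is None else pair_energy)
    total = 0.0
    for base in mirna.seed7:
        if base in "GC":
            total += table["GC"]
        elif base in "AU":
            total += table["AU"]
        else:
            raise ValueError(f"non-pairable seed letter {base!r}")
    return total


def duplex_energy(seed7: str, pair_energy: Mapping[str, float] | None = None) -> float:
    """Seed-duplex energy for an arbitrary 7-nt seed string (same table as SPS)."""
    table = dict(DEFAULT_PAIR_ENERGY if pair_energy is None else pair_energy)
    total = 0.0
    for base in seed7:
        if base in "GC":
            total += table["GC"]
        elif base in "AU":
            total += table["AU"]
        else:
            raise ValueError(f"non-pairable seed letter {base!r}")
    return total


@dataclass
class FeatureRow:
    """Per (transcript, miRNA) record feeding the association analyses."""

    transcript_id: str
    mirna_id: str
    d: int | None            # None = no RBS on the transcript
    overlapped: bool
    n_rbp: int
    local_au: float
    ta: float
    sps: float
    log10_len: float
    log2fc: float


def build_feature_table(
    transcripts: Sequence[Transcript],
    mirna: MicroRNA,
    rbs: Sequence[RbsInterval],
    fold_changes: Mapping[str, float],
    flank: int = 50,
    local_au_window: int = 30,
) -> pd.DataFrame:
    """One complete feature row per single-site transcript.

    ``transcripts`` must already be restricted to single-site 3'UTRs. Rows
    lacking a fold change are dropped (count logged). Transcripts with no RBS
    keep a null d and are excluded from distance analyses downstream but
    retained as no-site baselines.
    """
    from .io import logger

    rbs_by_tx: dict[str, list[RbsInterval]] = {}
    for iv in rbs:
        rbs_by_tx.setdefault(iv.transcript_id, []).append(iv)
    ta = target_abundance(mirna, transcripts)
    sps = seed_pairing_stability(mirna)
    rows = []
    seen: set[str] = set()
    n_dropped = 0
    for tx in transcripts:
        if tx.id in seen:
            raise ValueError(f"duplicate (transcript, miRNA): {tx.id}, {mirna.id}")
        seen.add(tx.id)
        sites = scan_mts(tx.utr_seq, mirna)
        if len(sites) != 1:
            raise ValueError(f"{tx.id}: expected exactly one site, found {len(sites)}")
        site = sites[0]
        site.transcript_id = tx.id
        if tx.id not in fold_changes or pd.isna(fold_changes[tx.id]):
            n_dropped += 1
            continue
        tx_rbs = rbs_by_tx.get(tx.id, [])
        dist = distance_mts_rbs(site, tx_rbs)
        by_rbp: dict[str, list[RbsInterval]] = {}
        for iv in tx_rbs:
            by_rbp.setdefault(iv.rbp_id, []).append(iv)
        rows.append({
            "transcript": tx.id,
            "mirna": mirna.id,
            "d": dist.d if dist.has_rbs else np.nan,
            "overlapped": dist.overlapped,
            "n_rbp": count_rbps_near(site, by_rbp, flank),
            "local_au": local_au_content(tx.utr_seq, site, local_au_window),
            "ta": ta,
            "sps": sps,
            "log10_len": float(np.log10(len(tx))),
            "log2fc": float(fold_changes[tx.id]),
        })
    if n_dropped:
        logger.info("build_feature_table: dropped %d rows without fold change",
                    n_dropped)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
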