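"""Canonical miRNA target-site detection and RBP-binding-site processing.

Detects the three canonical seed-match site types (8mer, 7mer-m8, 7mer-A1)
in 3'UTRs, merges replicate eCLIP-style binding intervals, applies the RBP
retention filters, and computes the central distance statistic d (the gap
between a target site and the nearest binding site on the same 3'UTR).

Conventions
-----------
* Coordinates are 0-based half-open on the UTR.
* A site and an interval are *overlapped* only when they share at least one
  base; intervals that merely touch (end == start) have gap 0 but are not
  overlapped. This is the strictest reading of the "overlapped" category.
* An 8mer locus is reported once, as 8mer only; its contained 7mers are not
  double-reported (site types are exclusive categories).
* N bases never match a seed pattern.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import Transcript

_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}


def revcomp_rna(seq: str) -> str:
    """Reverse complement of an RNA string (no ambiguity codes)."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"cannot complement base {exc.args[0]!r}") from exc


@dataclass
class MicroRNA:
    """A mature miRNA, 5'->3'. The seed is positions 2-8 (1-based)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 19:
            raise ValueError(f"miRNA {self.id}: length {len(self.sequence)} < 19")

    @property
    def seed7(self) -> str:
        """miRNA positions 2-8, the 7-nt seed."""
        return self.sequence[1:8]

    @property
    def site_7mer_m8(self) -> str:
        """Perfect target complement of positions 2-8."""
        return revcomp_rna(self.sequence[1:8])

    @property
    def site_7mer_a1(self) -> str:
        """Complement of positions 2-7 followed by an A opposite position 1."""
        return revcomp_rna(self.sequence[1:7]) + "A"

    @property
    def site_8mer(self) -> str:
        """7mer-m8 match followed by an A (the union of both 7mer features)."""
        return self.site_7mer_m8 + "A"


@dataclass
class SiteMatch:
    """One canonical miRNA target site (MTS) on a 3'UTR."""

    transcript_id: str
    start: int
    end: int
    site_type: str  # {"8mer", "7mer-m8", "7mer-A1"}
    mirna_id: str
    phylop: float | None = None


@dataclass
class RbsInterval:
    """One (possibly replicate-merged) RBP-binding interval."""

    rbp_id: str
    transcript_id: str
    start: int
    end: int
    stringency: str = "lenient"  # {"stringent", "lenient"}
    support: int = 1             # number of supporting replicates

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"RBS {self.rbp_id}: start >= end")


@dataclass
class DistanceResult:
    """d statistic for one MTS: gap to the nearest RBS on its 3'UTR.

    ``has_rbs`` distinguishes "no RBS on this transcript" from any numeric
    distance; d is never reported as infinity.
    """

    has_rbs: bool
    d: int | None = None
    overlapped: bool = False
    nearest_rbp_id: str | None = None


def scan_mts(utr_seq: str, mirna: MicroRNA) -> list[SiteMatch]:
    """Find all canonical seed-match sites of ``mirna`` in a 3'UTR.

    An 8mer is a 7mer-m8 match followed by A; at a locus matching the 8mer
    pattern only the 8mer is reported (neither contained 7mer is emitted).
    """
    if len(mirna.sequence) < 8:
        raise ValueError("miRNA shorter than 8 nt")
    s8, s7m8, s7a1 = mirna.site_8mer, mirna.site_7mer_m8, mirna.site_7mer_a1
    n = len(utr_seq)
    out: list[SiteMatch] = []
    for i in range(n - 6):
        window8 = utr_seq[i : i + 8]
        window7 = utr_seq[i : i + 7]
        if window8 == s8:
            out.append(SiteMatch(transcript_id="", start=i, end=i + 8,
                                 site_type="8mer", mirna_id=mirna.id))
        elif window7 == s7m8:
            # not followed by A (else the 8mer branch above fired)
            out.append(SiteMatch(transcript_id="", start=i, end=i + 7,
                                 site_type="7mer-m8", mirna_id=mirna.id))
        elif window7 == s7a1 and not (i >= 1 and utr_seq[i - 1 : i + 7] == s8):
            # skip the A1-anchored tail of an 8mer already reported at i-1
            out.append(SiteMatch(transcript_id="", start=i, end=i + 7,
                                 site_type="7mer-A1", mirna_id=mirna.id))
    return out


def scan_transcript(tx: Transcript, mirna: MicroRNA) -> list[SiteMatch]:
    sites = scan_mts(tx.utr_seq, mirna)
    for s in sites:
        s.transcript_id = tx.id
    return sites


def select_single_site_utrs(
    transcripts: Sequence[Transcript], mirna: MicroRNA
) -> list[Transcript]:
    """Transcripts whose 3'UTR carries exactly one canonical site of any type."""
    return [t for t in transcripts if len(scan_mts(t.utr_seq, mirna)) == 1]


def merge_replicate_rbs(
    rep_intervals: Iterable[tuple[str, str, int, int, int]],
) -> list[RbsInterval]:
    """Merge per-replicate intervals into a union track per (RBP, transcript).

    ``rep_intervals`` yields (rbp_id, transcript_id, start, end, replicate).
    Intervals detected in only one replicate are retained. Overlapping or
    touching intervals coalesce; support is the number of distinct replicates
    contributing to the merged span. Idempotent: merging merged output is a
    no-op.
    """
    by_key: dict[tuple[str, str], list[tuple[int, int, int]]] = defaultdict(list)
    for rbp, tx, start, end, rep in rep_intervals:
        if start >= end:
            raise ValueError(f"interval start >= end for {rbp} on {tx}")
        by_key[(rbp, tx)].append((start, end, rep))
    out: list[RbsInterval] = []
    for (rbp, tx), ivs in sorted(by_key.items()):
        ivs.sort()
        cur_start, cur_end, reps = ivs[0][0], ivs[0][1], {ivs[0][2]}
        for start, end, rep in ivs[1:]:
            if start <= cur_end:  # overlap or touch -> coalesce
                cur_end = max(cur_end, end)
                reps.add(rep)
            else:
                out.append(RbsInterval(rbp, tx, cur_start, cur_end, support=len(reps)))
                cur_start, cur_end, reps = start, end, {rep}
        out.append(RbsInterval(rbp, tx, cur_start, cur_end, support=len(reps)))
    return out


def assign_stringency(
    intervals: Sequence[RbsInterval],
    scores: Mapping[tuple[str, str, int], float] | None = None,
    tiers: Mapping[tuple[str, str, int], str] | None = None,
    score_quantile: float = 0.5,
) -> list[RbsInterval]:
    """Set the stringent/lenient tier on each interval.

    An explicit tier (from the BED name suffix) wins. Otherwise the BED score
    is thresholded at ``score_quantile`` per RBP: top fraction = stringent.
    Keys are (rbp_id, transcript_id, start).
    """
    if tiers:
        for iv in intervals:
            t = tiers.get((iv.rbp_id, iv.transcript_id, iv.start))
            if t is not None:
                iv.stringency = t
    if scores:
        by_rbp: dict[str, list[float]] = defaultdict(list)
        for key, sc in scores.items():
            by_rbp[key[0]].append(sc)
        cut = {rbp: float(np.quantile(v, score_quantile)) for rbp, v in by_rbp.items()}
        for iv in intervals:
            key = (iv.rbp_id, iv.transcript_id, iv.start)
            if tiers and key in tiers:
                continue
            sc = scores.get(key)
            if sc is not None:
                iv.stringency = "stringent" if sc > cut[iv.rbp_id] else "lenient"
    return list(intervals)


def filter_rbps(
    rbs_by_rbp: Mapping[str, Sequence[RbsInterval]],
    expression_by_rbp: Mapping[str, float] | None = None,
    min_utr_sites: int = 300,
    expression_quantile: float = 0.5,
) -> set[str]:
    """Retain RBPs with enough 3'UTR sites and (optionally) high expression.

    RBPs with fewer than ``min_utr_sites`` intervals are dropped; when an
    expression table is supplied, RBPs below ``expression_quantile`` of the
    RBP expression distribution are additionally dropped.
    """
    kept = {rbp for rbp, ivs in rbs_by_rbp.items() if len(ivs) >= min_utr_sites}
    if expression_by_rbp:
        vals = np.array([expression_by_rbp[r] for r in sorted(expression_by_rbp)])
        cut = float(np.quantile(vals, expression_quantile))
        kept = {r for r in kept
                if expression_by_rbp.get(r, -np.inf) >= cut}
    return kept


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Edge-to-edge gap of two half-open intervals; <= 0 when they touch/overlap."""
    if a_start < b_start:
        return b_start - a_end
    return a_start - b_end


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def distance_mts_rbs(mts: SiteMatch, rbs_list: Sequence[RbsInterval]) -> DistanceResult:
    """d statistic: gap between an MTS and the nearest RBS.

    Overlap (>= 1 shared base) gives d = 0 with ``overlapped=True``; touching
    intervals give d = 0 but are not overlapped. Ties between RBPs at the
    minimum gap break lexicographically on rbp_id.
    """
    if not rbs_list:
        return DistanceResult(has_rbs=False)
    best_d: int | None = None
    best_rbp: str | None = None
    overlapped = False
    for rbs in sorted(rbs_list, key=lambda r: r.rbp_id):
        d = max(0, _gap(mts.start, mts.end, rbs.start, rbs.end))
        if best_d is None or d < best_d:
            best_d = d
            best_rbp = rbs.rbp_id
            overlapped = _overlaps(mts.start, mts.end, rbs.start, rbs.end)
        elif d == best_d and d == 0 and not overlapped:
            # a tie at d=0 that actually shares bases upgrades the category
            if _overlaps(mts.start, mts.end, rbs.start, rbs.end):
                overlapped = True
                best_rbp = min(best_rbp, rbs.rbp_id)  # type: ignore[type-var]
    return DistanceResult(has_rbs=True, d=best_d, overlapped=overlapped,
                          nearest_rbp_id=best_rbp)


def count_rbps_near(
    mts: SiteMatch,
    rbs_by_rbp: Mapping[str, Sequence[RbsInterval]],
    flank: int = 50,
) -> int:
    """Number of distinct RBPs with >= 1 interval within ``flank`` nt of the MTS.

    The gap is measured edge-to-edge (consistent with d); overlap counts.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    n = 0
    for rbp, ivs in rbs_by_rbp.items():
        for iv in ivs:
            if max(0, _gap(mts.start, mts.end, iv.start, iv.end)) <= flank:
                n += 1
                break
    return n


def preserved_rbs(
    rbs_cell_a: Sequence[RbsInterval], rbs_cell_b: Sequence[RbsInterval]
) -> list[RbsInterval]:
    """Intervals of cell line A overlapping (>= 1 bp) a same-RBP interval in B."""
    by_key: dict[tuple[str, str], list[RbsInterval]] = defaultdict(list)
    for iv in rbs_cell_b:
        by_key[(iv.rbp_id, iv.transcript_id)].append(iv)
    out = []
    for iv in rbs_cell_a:
        for other in by_key.get((iv.rbp_id, iv.transcript_id), ()):
            if _overlaps(iv.start, iv.end, other.start, other.end):
                out.append(iv)
                break
    return out
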