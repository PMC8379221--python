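"""DMS-seq structure scoring and the constrained-folding accessibility model.

DMS chemistry methylates unpaired adenines and cytosines, so read counts at
A/C positions report single-strandedness. Scores are log2 ratios of
library-normalized (RPM) count levels against a denatured control; the
in vivo minus in vitro difference (the ΔDMS score) measures in-cell
structural opening, the signature expected where protein binding melts local
structure.

The folding engine is a self-contained Nussinov-style dynamic program over
additive base-pair energies with a minimum hairpin loop, supporting
positional unpaired constraints. RBP binding is modeled as forcing its
footprint single-stranded; miRNA binding as the target site forced unpaired
intramolecularly plus a seed-duplex energy bonus. The engine is deliberately
simple enough to verify against exhaustive enumeration; an external
thermodynamic folder can be substituted through the ``fold_fn`` hooks for
realistic energies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import MicroRNA, RbsInterval, SiteMatch
from .features import duplex_energy
from .io import Transcript

#: Pair energies (kcal/mol) for the simple engine; GU wobble allowed.
PAIR_ENERGY: dict[frozenset[str], float] = {
    frozenset("GC"): -3.0,
    frozenset("AU"): -2.0,
    frozenset("GU"): -1.0,
}

MIN_HAIRPIN_LOOP = 3  # unpaired bases strictly inside a hairpin
AC = frozenset("AC")


# ---------------------------------------------------------------------------
# DMS scoring (library normalization, levels, scores)
# ---------------------------------------------------------------------------

def rpm_normalize(counts: Sequence[float], library_size: float) -> np.ndarray:
    """Reads-per-million scaling of a per-position count vector."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return np.asarray(counts, dtype=float) * 1e6 / library_size


def dms_level(replicate_rpm_vectors: Sequence[Sequence[float]]) -> np.ndarray:
    """Position-wise mean of replicate RPM vectors."""
    vecs = [np.asarray(v, dtype=float) for v in replicate_rpm_vectors]
    if not vecs:
        raise ValueError("need >= 1 replicate")
    n = vecs[0].size
    if any(v.size != n for v in vecs):
        raise ValueError("replicate length mismatch")
    return np.mean(vecs, axis=0)


def dms_score(
    level_sample: Sequence[float],
    level_denatured: Sequence[float],
    pseudocount: float = 1.0,
) -> np.ndarray:
    """Per-position log2 ratio of sample DMS level to the denatured control.

    The denatured control removes the sequence-intrinsic reactivity baseline;
    the pseudocount (RPM units) guards zero coverage.
    """
    s = np.asarray(level_sample, dtype=float)
    d = np.asarray(level_denatured, dtype=float)
    if s.size != d.size:
        raise ValueError("length mismatch")
    if (s < 0).any() or (d < 0).any():
        raise ValueError("negative levels")
    return np.log2((s + pseudocount) / (d + pseudocount))


def fragment_score(score_vector: Sequence[float], seq: str,
                   start: int, end: int) -> float:
    """Fragment-level DMS score: mean over the A/C positions in [start, end)."""
    sv = np.asarray(score_vector, dtype=float)
    idx = [i for i in range(start, end) if seq[i] in AC]
    if not idx:
        return float("nan")
    return float(sv[idx].mean())


def delta_dms(score_invivo: float, score_invitro: float) -> float:
    """ΔDMS = in vivo score minus in vitro score (antisymmetric)."""
    return score_invivo - score_invitro


def make_fragments(utr_len: int, window: int = 100, step: int = 10
                   ) -> list[tuple[int, int]]:
    """Sliding windows [i*step, i*step + window) fully inside the UTR."""
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    return [(s, s + window) for s in range(0, utr_len - window + 1, step)]


def expression_filter(transcripts: Sequence[Transcript], quantile: float = 0.5
                      ) -> list[Transcript]:
    """Keep transcripts at or above the expression quantile (linear
    interpolation; "top 50%" keeps values strictly above the median when n is
    even)."""
    expr = np.array([t.expression for t in transcripts], dtype=float)
    if np.isnan(expr).any():
        raise ValueError("expression missing on some transcripts")
    cut = float(np.quantile(expr, quantile))
    return [t for t in transcripts if t.expression >= cut]


def normalize_delta_by_expression(delta: float, expression: float) -> float:
    """ΔDMS scaled by log10(1 + expression), damping coverage-driven inflation."""
    if expression <= 0:
        raise ValueError("expression must be > 0")
    return delta / float(np.log10(1 + expression))


def dms_reactivity(
    counts_plus: Sequence[float],
    counts_minus: Sequence[float],
    seq: str,
    library_size_plus: float = 1e6,
    library_size_minus: float = 1e6,
    pseudocount: float = 1.0,
) -> dict[int, float]:
    """Per-nucleotide reactivity at A/C positions from RT-stop counts.

    log2((RPM_treated + pc) / (RPM_untreated + pc)); G/U positions are
    excluded from the output.
    """
    plus = np.asarray(counts_plus, dtype=float)
    minus = np.asarray(counts_minus, dtype=float)
    if plus.size != minus.size or plus.size != len(seq):
        raise ValueError("length mismatch")
    rp = rpm_normalize(plus, library_size_plus)
    rm = rpm_normalize(minus, library_size_minus)
    return {
        i: float(np.log2((rp[i] + pseudocount) / (rm[i] + pseudocount)))
        for i in range(len(seq)) if seq[i] in AC
    }


# ---------------------------------------------------------------------------
# Constrained folding
# ---------------------------------------------------------------------------

def _pair_energy(a: str, b: str) -> float | None:
    return PAIR_ENERGY.get(frozenset((a, b)))


def fold_mfe(
    seq: str,
    forbidden_pair_positions: Iterable[int] = (),
    length_cap: int = 300,
) -> tuple[float, str]:
    """Constrained minimum-free-energy fold of one sequence.

    Nussinov-style dynamic program minimizing summed pair energies
    (GC/AU/GU = -3/-2/-1 kcal/mol), minimum hairpin loop of 3, with every
    position in ``forbidden_pair_positions`` forced unpaired. Returns the MFE
    and one optimal dot-bracket structure with deterministic traceback: on
    ties, pairing the left end wins over leaving it unpaired, and the
    smallest partner index wins.
    """
    n = len(seq)
    if n > length_cap:
        raise ValueError(f"sequence length {n} exceeds cap {length_cap}")
    bad = set(seq) - set("ACGUN")
    if bad:
        raise ValueError(f"invalid alphabet: {sorted(bad)}")
    forbidden = set(forbidden_pair_positions)
    if any(p < 0 or p >= n for p in forbidden):
        raise ValueError("forbidden position out of range")
    if n == 0:
        return 0.0, ""
    # pair-energy matrix; +inf marks unpairable or forbidden
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    emat = np.full((n, n), np.inf)
    for (a, b), e in [(tuple(k), v) for k, v in PAIR_ENERGY.items()]:
        ca, cb = ord(a), ord(b)
        emat[np.ix_(codes == ca, codes == cb)] = e
        emat[np.ix_(codes == cb, codes == ca)] = e
    if forbidden:
        idx = sorted(forbidden)
        emat[idx, :] = np.inf
        emat[:, idx] = np.inf
    # E padded one row/col so E[k+1, j] with k = j reads a zero
    E = np.zeros((n + 1, n + 1))
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        i_arr = np.arange(0, n - span)
        j_arr = i_arr + span
        for i, j in zip(i_arr, j_arr):
            ks = np.arange(i + MIN_HAIRPIN_LOOP + 1, j + 1)
            cand = emat[i, ks] + E[i + 1, ks - 1] + E[ks + 1, j]
            best = min(E[i + 1, j], cand.min()) if ks.size else E[i + 1, j]
            E[i, j] = best
    # deterministic traceback
    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < MIN_HAIRPIN_LOOP + 1:
            continue
        target = E[i, j]
        paired = False
        for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
            e = emat[i, k]
            if not np.isfinite(e):
                continue
            if np.isclose(e + E[i + 1, k - 1] + E[k + 1, j], target):
                structure[i], structure[k] = "(", ")"
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    return float(E[0, n - 1]), "".join(structure)


def enumerate_fold(
    seq: str, forbidden_pair_positions: Iterable[int] = ()
) -> float:
    """Exhaustive-enumeration MFE over all valid nested structures.

    Reference routine for validating :func:`fold_mfe`; exponential, intended
    for sequences of ~14 nt or less.
    """
    n = len(seq)
    forbidden = set(forbidden_pair_positions)
    candidates = [
        (i, j)
        for i in range(n)
        for j in range(i + MIN_HAIRPIN_LOOP + 1, n)
        if i not in forbidden and j not in forbidden
        and _pair_energy(seq[i], seq[j]) is not None
    ]
    best = [0.0]

    def compatible(p: tuple[int, int], chosen: list[tuple[int, int]]) -> bool:
        i, j = p
        for a, b in chosen:
            if len({i, j, a, b}) < 4:
                return False
            if a < i < b < j or i < a < j < b:  # crossing
                return False
        return True

    def recurse(idx: int, chosen: list[tuple[int, int]], energy: float) -> None:
        if energy < best[0]:
            best[0] = energy
        for t in range(idx, len(candidates)):
            p = candidates[t]
            if compatible(p, chosen):
                chosen.append(p)
                recurse(t + 1, chosen,
                        energy + _pair_energy(seq[p[0]], seq[p[1]]))
                chosen.pop()

    recurse(0, [], 0.0)
    return best[0]


@dataclass
class FoldEnergies:
    """The four constrained MFEs of the accessibility model (kcal/mol).

    dG0: unconstrained fold. dG_RBP: RBS footprints forced unpaired.
    dG_miR / dG_RBP_miR: additionally the MTS forced unpaired, plus the
    seed-duplex bonus. The model's accessibility cost of miRNA binding is
    ddG_model = dG_RBP_miR - dG_RBP; the RBP-blind cost is
    ddG_nomodel = dG_miR - dG0.
    """

    dG0: float
    dG_miR: float
    dG_RBP: float
    dG_RBP_miR: float

    @property
    def ddG_nomodel(self) -> float:
        return self.dG_miR - self.dG0

    @property
    def ddG_model(self) -> float:
        return self.dG_RBP_miR - self.dG_RBP


def site_accessibility_energies(
    fragment_seq: str,
    mts: SiteMatch,
    rbs: Sequence[RbsInterval],
    mirna: MicroRNA,
    fold_fn: Callable[..., tuple[float, str]] = fold_mfe,
) -> FoldEnergies:
    """Constrained-MFE quartet for one fragment (coordinates fragment-local).

    Overlapping MTS/RBS footprints are handled by position-set union, so no
    base is double counted.
    """
    n = len(fragment_seq)
    mts_pos = set(range(mts.start, mts.end))
    rbs_pos: set[int] = set()
    for iv in rbs:
        rbs_pos.update(range(iv.start, iv.end))
    if not mts_pos <= set(range(n)) or not rbs_pos <= set(range(n)):
        raise ValueError("MTS or RBS outside fragment")
    bonus = duplex_energy(mirna.seed7)
    dG0, _ = fold_fn(fragment_seq)
    dG_rbp, _ = fold_fn(fragment_seq, rbs_pos)
    dG_mir, _ = fold_fn(fragment_seq, mts_pos)
    dG_both, _ = fold_fn(fragment_seq, rbs_pos | mts_pos)
    return FoldEnergies(dG0=dG0, dG_miR=dG_mir + bonus, dG_RBP=dG_rbp,
                        dG_RBP_miR=dG_both + bonus)


# ---------------------------------------------------------------------------
# Fragment grouping by RBS tier, with MFE/expression balancing
# ---------------------------------------------------------------------------

def label_fragment(start: int, end: int, rbs: Sequence[RbsInterval]) -> str:
    """Stringent > Lenient > NoRBS precedence over overlapping RBSs."""
    label = "NoRBS"
    for iv in rbs:
        if iv.start < end and start < iv.end:
            if iv.stringency == "stringent":
                return "Stringent"
            label = "Lenient"
    return label


def group_fragments(
    fragments: pd.DataFrame,
    alpha: float = 0.05,
    max_retries: int = 10,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Balance fragment groups on in vitro MFE and expression.

    ``fragments`` needs columns ``group`` (NoRBS/Lenient/Stringent),
    ``invitro_mfe`` and ``expression``. The two larger classes are greedily
    matched to the smallest on standardized (MFE, expression) distance, and
    the matched size shrinks until the classes are indistinguishable
    (pairwise Wilcoxon, all p > alpha). Errors if a class is empty.
    """
    from .matching import verify_indistinguishable

    df = fragments.reset_index(drop=True)
    sizes = df.groupby("group").size()
    for cls in ("NoRBS", "Lenient", "Stringent"):
        if cls not in sizes.index or sizes[cls] == 0:
            raise ValueError(f"empty fragment class; sizes: {sizes.to_dict()}")
    feats = df[["invitro_mfe", "expression"]].to_numpy(float)
    mu, sd = feats.mean(0), feats.std(0)
    sd[sd == 0] = 1.0
    z = (feats - mu) / sd
    ref = str(sizes.idxmin())
    target = int(sizes.min())
    rng = np.random.default_rng(rng_seed)
    for _ in range(max_retries + 1):
        ref_idx = df.index[df["group"] == ref].to_numpy()
        if target < len(ref_idx):
            ref_idx = rng.permutation(ref_idx)[:target]
        retained = list(ref_idx)
        for cls in ("NoRBS", "Lenient", "Stringent"):
            if cls == ref:
                continue
            pool = list(df.index[df["group"] == cls])
            for r in ref_idx:
                if not pool:
                    break
                dists = np.linalg.norm(z[pool] - z[r], axis=1)
                retained.append(pool.pop(int(np.argmin(dists))))
        sub = df.loc[retained]
        ok, _ = verify_indistinguishable(
            {g: gdf for g, gdf in sub.groupby("group")},
            confounders=("invitro_mfe", "expression"), alpha=alpha)
        if ok:
            return sub.reset_index(drop=True)
        target = max(3, int(target * 0.8))
    return sub.reset_index(drop=True)


def pair_energy_profile(seq: str, chunk: int = 100) -> np.ndarray:
    """Per-position MFE attribution from a chunked fold of one sequence.

    The sequence is folded in non-overlapping ``chunk``-nt blocks and each
    base pair's energy is split half onto each partner, giving a positional
    energy density whose window sums estimate fragment MFEs without folding
    every overlapping window.
    """
    contrib = np.zeros(len(seq))
    for s in range(0, len(seq), chunk):
        sub = seq[s : s + chunk]
        _, struct = fold_mfe(sub, length_cap=chunk)
        stack: list[int] = []
        for i, ch in enumerate(struct):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                a = stack.pop()
                e = _pair_energy(sub[a], sub[i])
                contrib[s + a] += e / 2
                contrib[s + i] += e / 2
    return contrib


def score_fragments(
    transcripts: Sequence[Transcript],
    levels: Mapping[tuple[str, str], np.ndarray],
    rbs_by_tx: Mapping[str, Sequence[RbsInterval]],
    window: int = 100,
    step: int = 10,
    pseudocount: float = 1.0,
    mfe_chunk: int = 100,
) -> pd.DataFrame:
    """End-to-end fragment table: DMS scores, ΔDMS, tier label, in vitro MFE.

    ``levels`` maps (transcript_id, condition) to per-position DMS-level
    vectors for conditions in_vivo / in_vitro / denatured. Fragment MFE is
    the window sum of a per-transcript pair-energy profile (see
    :func:`pair_energy_profile`).
    """
    rows = []
    for tx in transcripts:
        key_vivo = (tx.id, "in_vivo")
        if key_vivo not in levels:
            continue
        s_vivo = dms_score(levels[(tx.id, "in_vivo")],
                           levels[(tx.id, "denatured")], pseudocount)
        s_vitro = dms_score(levels[(tx.id, "in_vitro")],
                            levels[(tx.id, "denatured")], pseudocount)
        tx_rbs = list(rbs_by_tx.get(tx.id, ()))
        energy_profile = pair_energy_profile(tx.utr_seq, mfe_chunk)
        for start, end in make_fragments(len(tx), window, step):
            fv = fragment_score(s_vivo, tx.utr_seq, start, end)
            ft = fragment_score(s_vitro, tx.utr_seq, start, end)
            if np.isnan(fv) or np.isnan(ft):
                continue
            frag_rbs = [iv for iv in tx_rbs if iv.start < end and start < iv.end]
            mfe = float(energy_profile[start:end].sum())
            rows.append({
                "transcript": tx.id, "start": start, "end": end,
                "dms_score_invivo": fv, "dms_score_invitro": ft,
                "delta_dms": delta_dms(fv, ft),
                "group": label_fragment(start, end, tx_rbs),
                "n_rbp": len({iv.rbp_id for iv in frag_rbs}),
                "invitro_mfe": mfe,
                "expression": tx.expression,
            })
    return pd.DataFrame(rows)
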