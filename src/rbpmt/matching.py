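"""Covariate-balanced group sampling.

The association between MTS-RBS distance and repression could be driven by
the four confounders if they co-vary with distance. Beyond regression
adjustment, this module removes confounding non-parametrically: transcripts
are packed into quartets that differ in d but have nearly identical
confounder values (min-max spread within per-feature cutoffs), with the
cutoffs chosen to maximize the number of transcripts consumed, and the
resulting groups verified to be statistically indistinguishable on every
confounder. The same machinery balances RBP-count quintiles and the
composition split.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import CONFOUNDERS
from .stats import chi2_contingency_nc, wilcoxon_rank_sum


@dataclass
class QuartetAssignment:
    """One selection round: four same-site-type transcripts ordered by d.

    Group 1 is the member whose MTS overlaps an RBS (d = 0); groups 2-4 have
    strictly positive d in ascending order. Every confounder's min-max spread
    across the four members is within its cutoff.
    """

    round_id: int
    members: list[str]
    d_values: list[float]
    groups: list[int]
    site_type: str


def _spread_ok(values: np.ndarray, cutoff: float) -> bool:
    return float(values.max() - values.min()) <= cutoff


def sample_quartets(
    candidates: pd.DataFrame,
    cutoffs: Mapping[str, float],
    rng_seed: int = 0,
    confounders: Sequence[str] = tuple(CONFOUNDERS),
) -> list[QuartetAssignment]:
    """Greedy quartet packing under per-confounder spread cutoffs.

    ``candidates`` needs columns transcript, site_type, d, overlapped, and
    the confounders. Candidates are shuffled under the seed; for each unused
    overlapped candidate, the first three unused d > 0 candidates of the same
    site type that jointly keep every confounder spread within its cutoff are
    consumed with it. Deterministic under the seed; no transcript is reused
    across rounds.
    """
    for c in confounders:
        if cutoffs[c] <= 0:
            raise ValueError(f"cutoff for {c} must be positive")
    from .io import logger

    df = candidates.reset_index(drop=True)
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(df))
    used = np.zeros(len(df), dtype=bool)
    feats = {c: df[c].to_numpy(float) for c in confounders}
    overlapped = df["overlapped"].to_numpy(bool)
    d_arr = df["d"].to_numpy(float)
    site_type = df["site_type"].to_numpy()
    quartets: list[QuartetAssignment] = []
    anchor_idx = [i for i in order if overlapped[i]]
    if not anchor_idx:
        logger.warning("sample_quartets: no overlapped candidates; empty result")
        return []
    for a in anchor_idx:
        if used[a]:
            continue
        chosen = [a]
        for j in order:
            if used[j] or j == a or j in chosen:
                continue
            if overlapped[j] or d_arr[j] <= 0 or site_type[j] != site_type[a]:
                continue
            trial = chosen + [j]
            if all(_spread_ok(feats[c][trial], cutoffs[c]) for c in confounders):
                chosen.append(j)
                if len(chosen) == 4:
                    break
        if len(chosen) == 4:
            used[chosen] = True
            ordered = sorted(chosen, key=lambda i: (d_arr[i], df.loc[i, "transcript"]))
            quartets.append(QuartetAssignment(
                round_id=len(quartets),
                members=[df.loc[i, "transcript"] for i in ordered],
                d_values=[float(d_arr[i]) for i in ordered],
                groups=[1, 2, 3, 4],
                site_type=str(site_type[a]),
            ))
    logger.info("sample_quartets: %d quartets from %d candidates",
                len(quartets), len(df))
    return quartets


def quartet_groups(
    quartets: Sequence[QuartetAssignment], features: pd.DataFrame
) -> dict[int, pd.DataFrame]:
    """Per-group feature frames (group 1..4) for verification and analysis."""
    feat = features.set_index("transcript")
    out: dict[int, pd.DataFrame] = {}
    for g in (1, 2, 3, 4):
        members = [q.members[g - 1] for q in quartets]
        out[g] = feat.loc[members].reset_index()
    return out


def verify_indistinguishable(
    groups: Mapping[object, pd.DataFrame],
    confounders: Sequence[str] = tuple(CONFOUNDERS),
    alpha: float = 0.05,
) -> tuple[bool, pd.DataFrame]:
    """All-pairs Wilcoxon tests of every confounder across groups.

    Pass iff the minimum p exceeds alpha. Comparisons where either group has
    fewer than 3 members are skipped (logged). Returns (pass, long-format
    p-value table with columns confounder, group_a, group_b, p).
    """
    from .io import logger

    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    keys = sorted(groups, key=str)
    rows = []
    for c in confounders:
        for a, b in itertools.combinations(keys, 2):
            ga, gb = groups[a], groups[b]
            if len(ga) < 3 or len(gb) < 3:
                logger.info("verify_indistinguishable: skipping %s %s-%s (n < 3)",
                            c, a, b)
                continue
            _, p = wilcoxon_rank_sum(ga[c].to_numpy(float), gb[c].to_numpy(float))
            rows.append({"confounder": c, "group_a": a, "group_b": b, "p": p})
    p_matrix = pd.DataFrame(rows, columns=["confounder", "group_a", "group_b", "p"])
    ok = bool(p_matrix.empty or p_matrix["p"].min() > alpha)
    return ok, p_matrix


def sample_quartets_verified(
    candidates: pd.DataFrame,
    cutoffs: Mapping[str, float],
    rng_seed: int = 0,
    alpha: float = 0.05,
    shrink: float = 0.8,
    max_retries: int = 10,
    confounders: Sequence[str] = tuple(CONFOUNDERS),
) -> tuple[list[QuartetAssignment], pd.DataFrame]:
    """Quartet sampling with post-hoc balance verification.

    If any confounder differs significantly across the four groups, every
    cutoff is shrunk multiplicatively and sampling is retried, up to
    ``max_retries`` times. Returns the last (possibly empty) quartet set and
    its p-value table.
    """
    cur = dict(cutoffs)
    quartets: list[QuartetAssignment] = []
    p_matrix = pd.DataFrame()
    for _ in range(max_retries + 1):
        quartets = sample_quartets(candidates, cur, rng_seed, confounders)
        if not quartets:
            return [], pd.DataFrame()
        groups = quartet_groups(quartets, candidates)
        ok, p_matrix = verify_indistinguishable(groups, confounders, alpha)
        if ok:
            return quartets, p_matrix
        cur = {k: v * shrink for k, v in cur.items()}
    return quartets, p_matrix


def _grid_axes(
    candidates: pd.DataFrame,
    confounders: Sequence[str],
    n_points: int,
) -> dict[str, np.ndarray]:
    axes = {}
    for c in confounders:
        v = candidates[c].to_numpy(float)
        span = float(v.max() - v.min())
        if span <= 0:
            span = max(abs(float(v.mean())), 1.0)
        # log-spaced: tight cutoffs matter most for balance
        axes[c] = np.geomspace(span / 100, span, n_points)
    return axes


def optimize_cutoffs(
    candidates: pd.DataFrame,
    optimizer: str = "grid",
    n_grid: int = 5,
    budget: int = 40,
    rng_seed: int = 0,
    alpha: float = 0.05,
    confounders: Sequence[str] = tuple(CONFOUNDERS),
) -> dict[str, float]:
    """Choose per-confounder spread cutoffs maximizing transcripts consumed.

    Objective: number of transcripts packed by :func:`sample_quartets`, with
    cutoff vectors whose groups fail the indistinguishability check scored
    zero. ``optimizer="grid"`` (default) evaluates a deterministic full
    factorial with ``n_grid`` points per axis; ``optimizer="gp"`` runs a
    Gaussian-process surrogate search (expected improvement over a random
    candidate pool) within ``budget`` evaluations, reproducible under the
    seed. Returns the best evaluated cutoff vector.
    """

    def objective(cut: dict[str, float]) -> int:
        qs = sample_quartets(candidates, cut, rng_seed, confounders)
        if not qs:
            return 0
        ok, _ = verify_indistinguishable(
            quartet_groups(qs, candidates), confounders, alpha)
        return 4 * len(qs) if ok else 0

    axes = _grid_axes(candidates, confounders, n_grid)
    if optimizer == "grid":
        best_cut, best_val = None, -1
        for combo in itertools.product(*(axes[c] for c in confounders)):
            cut = {c: float(v) for c, v in zip(confounders, combo)}
            val = objective(cut)
            if val > best_val:
                best_cut, best_val = cut, val
    elif optimizer == "gp":
        best_cut, best_val = _gp_maximize(objective, axes, confounders,
                                          budget, rng_seed)
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}")
    if best_val <= 0:
        raise ValueError(
            "all evaluated cutoffs yield 0 selections; widen the cutoff bounds")
    return best_cut  # type: ignore[return-value]


def _gp_maximize(objective, axes, confounders, budget, rng_seed):
    """Expected-improvement search with a Gaussian-process surrogate."""
    from scipy.stats import norm
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern

    rng = np.random.default_rng(rng_seed)
    lo = np.array([axes[c][0] for c in confounders])
    hi = np.array([axes[c][-1] for c in confounders])

    def sample_points(m):
        return lo + rng.random((m, len(confounders))) * (hi - lo)

    n_init = min(max(10, budget // 3), budget)
    X = sample_points(n_init)
    y = np.array([objective(dict(zip(confounders, x))) for x in X], dtype=float)
    gp = GaussianProcessRegressor(kernel=Matern(nu=2.5), normalize_y=True,
                                  random_state=rng_seed)
    while len(y) < budget:
        gp.fit(X, y)
        pool = sample_points(256)
        mu, sd = gp.predict(pool, return_std=True)
        best = y.max()
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (mu - best) / sd
            ei = np.where(sd > 0, (mu - best) * norm.cdf(z) + sd * norm.pdf(z), 0.0)
        x_next = pool[int(np.argmax(ei))]
        X = np.vstack([X, x_next])
        y = np.append(y, objective(dict(zip(confounders, x_next))))
    i = int(np.argmax(y))
    return dict(zip(confounders, map(float, X[i]))), float(y[i])


def balance_groups_by_trimming(
    df: pd.DataFrame,
    group_col: str,
    confounders: Sequence[str],
    alpha: float = 0.05,
    min_group_size: int = 5,
    max_iter: int = 500,
) -> pd.DataFrame:
    """Trim group extremes until all groups are confounder-indistinguishable.

    Repeatedly finds the worst-failing (confounder, group pair) comparison
    and drops the most extreme member from each side of the difference: the
    largest value from the higher group and the smallest from the lower.
    This removes the between-group shift from both directions rather than
    starving the test of sample size. Errors when a group would fall below
    ``min_group_size``, reporting the worst feature.
    """
    sub = df.copy()
    worst = ("", 1.0)
    for _ in range(max_iter):
        groups = {g: gdf for g, gdf in sub.groupby(group_col)}
        ok, pm = verify_indistinguishable(groups, confounders, alpha)
        if ok:
            return sub.reset_index(drop=True)
        row = pm.loc[pm["p"].idxmin()]
        c = str(row["confounder"])
        worst = (c, float(row["p"]))
        ga, gb = groups[row["group_a"]], groups[row["group_b"]]
        hi, lo = (ga, gb) if ga[c].mean() > gb[c].mean() else (gb, ga)
        if len(hi) <= min_group_size or len(lo) <= min_group_size:
            break
        sub = sub.drop(index=[hi[c].idxmax(), lo[c].idxmin()])
    raise ValueError(
        f"could not balance groups; worst feature: {worst[0]} "
        f"(p={worst[1]:.2g})")


def sample_count_groups(
    mts_rows: pd.DataFrame,
    k: int = 5,
    alpha: float = 0.05,
    min_group_size: int = 5,
    max_abs_corr: float | None = 0.1,
    rng_seed: int = 0,
    confounders: Sequence[str] = tuple(CONFOUNDERS),
) -> pd.DataFrame:
    """Split MTSs into k RBP-count strata with balanced confounders.

    Strata are quantile bands of the ``n_rbp`` column; the strata are then
    trimmed (see :func:`balance_groups_by_trimming`) until every confounder
    is statistically indistinguishable across them. When ``max_abs_corr`` is
    set, rows contributing most to any residual pooled count-confounder
    correlation are additionally dropped until |r| falls below the bound
    (between-group balancing alone cannot remove within-stratum
    confounding). Returns the retained rows with a ``count_group`` label
    column (0..k-1, ascending count).
    """
    from .stats import partition_by_binding_signal

    df = mts_rows.reset_index(drop=True).copy()
    if k == 1:
        df["count_group"] = 0
        return df
    df["count_group"] = partition_by_binding_signal(df["n_rbp"].to_numpy(float), k)
    sizes = df.groupby("count_group").size()
    if (sizes < 3).any():
        raise ValueError("a count stratum has fewer than 3 members")
    sub = balance_groups_by_trimming(df, "count_group", confounders, alpha,
                                     min_group_size)
    if max_abs_corr is None:
        return sub
    for _ in range(len(sub)):
        x = sub["n_rbp"].to_numpy(float)
        worst_c, worst_r = "", 0.0
        for c in confounders:
            y = sub[c].to_numpy(float)
            if x.std() == 0 or y.std() == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            if abs(r) > abs(worst_r):
                worst_c, worst_r = c, r
        if abs(worst_r) <= max_abs_corr:
            break
        y = sub[worst_c].to_numpy(float)
        contrib = np.sign(worst_r) * (x - x.mean()) * (y - y.mean())
        sizes = sub.groupby("count_group").size()
        droppable = sub["count_group"].map(sizes) > min_group_size
        if not droppable.any():
            break
        order = np.argsort(-contrib)
        drop_pos = next(p for p in order if droppable.iloc[p])
        sub = sub.drop(index=sub.index[drop_pos])
    return balance_groups_by_trimming(sub, "count_group", confounders, alpha,
                                      min_group_size)


@dataclass
class CompositionSplit:
    """Two MTS subgroups with similar bound-RBP counts but disjoint-leaning
    RBP compositions, plus the per-RBP fraction-of-MTS table per side."""

    side_a: pd.DataFrame
    side_b: pd.DataFrame
    composition: pd.DataFrame  # columns: rbp, frac_a, frac_b
    count_histogram_p: float


def composition_split(
    mts_rows: pd.DataFrame,
    count_range: tuple[int, int] = (1, 10),
    alpha: float = 0.05,
    rng_seed: int = 0,
) -> CompositionSplit:
    """Separate MTSs into two sides of different RBP composition.

    ``mts_rows`` needs columns ``n_rbp`` and ``rbp_set`` (iterable of RBP ids
    bound within the flank). RBPs are ordered by how many MTSs they touch and
    alternately assigned to sides A/B; each MTS goes to the side contributing
    the majority of its bound RBPs (ties to the currently smaller side). If
    the two sides' count histograms differ (chi-square p <= alpha), the
    larger side is stratified-downsampled by count until they agree.
    """
    lo, hi = count_range
    df = mts_rows[(mts_rows["n_rbp"] >= lo) & (mts_rows["n_rbp"] <= hi)]
    df = df.reset_index(drop=True)
    freq: dict[str, int] = {}
    for s in df["rbp_set"]:
        for r in s:
            freq[r] = freq.get(r, 0) + 1
    ordered = sorted(freq, key=lambda r: (-freq[r], r))
    side_of = {r: ("A" if i % 2 == 0 else "B") for i, r in enumerate(ordered)}
    labels = []
    n_a = n_b = 0
    for s in df["rbp_set"]:
        a = sum(1 for r in s if side_of.get(r) == "A")
        b = sum(1 for r in s if side_of.get(r) == "B")
        if a > b:
            lab = "A"
        elif b > a:
            lab = "B"
        else:
            lab = "A" if n_a <= n_b else "B"
        labels.append(lab)
        n_a += lab == "A"
        n_b += lab == "B"
    df = df.assign(side=labels)
    rng = np.random.default_rng(rng_seed)

    def hist_p(d: pd.DataFrame) -> float:
        counts = pd.crosstab(d["n_rbp"], d["side"])
        if counts.shape[1] < 2 or (counts.sum(0) == 0).any():
            return 0.0
        counts = counts.loc[counts.sum(1) > 0]
        _, p = chi2_contingency_nc(counts.to_numpy())
        return p

    p = hist_p(df)
    for _ in range(20):
        if p > alpha:
            break
        # stratified downsample: per count, trim both sides to the min
        parts = []
        for _, grp in df.groupby("n_rbp"):
            na, nb = (grp["side"] == "A").sum(), (grp["side"] == "B").sum()
            m = min(na, nb)
            for side in "AB":
                sub = grp[grp["side"] == side]
                if len(sub) > m:
                    sub = sub.loc[rng.permutation(sub.index)[:m]]
                parts.append(sub)
        df = pd.concat(parts).reset_index(drop=True)
        p = hist_p(df)
    side_a = df[df["side"] == "A"].reset_index(drop=True)
    side_b = df[df["side"] == "B"].reset_index(drop=True)
    if len(side_a) < 10 or len(side_b) < 10:
        raise ValueError(
            f"fewer than 10 MTSs per side after balancing "
            f"(A={len(side_a)}, B={len(side_b)})")
    all_rbps = sorted(freq)
    comp_rows = []
    for r in all_rbps:
        fa = float(np.mean([r in s for s in side_a["rbp_set"]])) if len(side_a) else 0.0
        fb = float(np.mean([r in s for s in side_b["rbp_set"]])) if len(side_b) else 0.0
        comp_rows.append({"rbp": r, "frac_a": fa, "frac_b": fb})
    return CompositionSplit(side_a, side_b, pd.DataFrame(comp_rows), p)
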