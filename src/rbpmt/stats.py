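"""Statistical core: regression, residualization, per-RBP association with
FDR, rank/KS/chi-square tests, binding-signal tertiles, saturation-curve
extrapolation, and the MTS/RBS co-occurrence test.

Sign convention: log2 fold changes are repression-negative (a well-targeted
mRNA goes down on miRNA transfection). Repression weakening as the
MTS-to-RBS distance d grows therefore shows up as a *positive* coefficient
on raw d — such an RBP is an enhancer of miRNA targeting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .features import CONFOUNDERS


@dataclass
class RegressionFit:
    """Ordinary least-squares fit; intercept first in every vector."""

    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    residuals: np.ndarray
    r2: float
    names: list[str]


@dataclass
class RbpAssociation:
    """Association of one RBP's binding distance with targeting efficacy."""

    rbp_id: str
    beta_d: float
    p: float
    q: float
    direction: str  # {"enhancer", "suppressor"}
    n_used: int


def fit_ols(y: np.ndarray, X: np.ndarray, names: Sequence[str] | None = None
            ) -> RegressionFit:
    """Closed-form OLS with two-sided t p-values on n - p degrees of freedom.

    An intercept column is auto-prepended. Rank-deficient designs are an
    error naming the collinear columns; so is n <= p.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    names = list(names) if names is not None else [f"x{i}" for i in range(k)]
    design = np.column_stack([np.ones(n), X])
    all_names = ["intercept"] + names
    if n <= design.shape[1]:
        raise ValueError(f"n={n} <= p={design.shape[1]}: cannot fit")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        cols = design[:, :1]
        for j in range(1, design.shape[1]):
            trial = np.column_stack([cols, design[:, j]])
            if np.linalg.matrix_rank(trial) == cols.shape[1]:
                bad.append(all_names[j])
            else:
                cols = trial
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    res = sm.OLS(y, design).fit()
    r2 = float(res.rsquared)
    if not np.isfinite(r2):  # constant response: define r2 = 0
        r2 = 0.0
    return RegressionFit(
        beta=np.asarray(res.params),
        se=np.asarray(res.bse),
        t=np.asarray(res.tvalues),
        p=np.asarray(res.pvalues),
        residuals=np.asarray(res.resid),
        r2=r2,
        names=all_names,
    )


def residualize(log2fc: np.ndarray, confounders: pd.DataFrame) -> np.ndarray:
    """Residuals of log2fc after regressing out the four confounders.

    The residual is the targeting-efficacy signal remaining once local AU
    content, TA, SPS, and UTR length are accounted for; mean zero by
    construction.
    """
    cols = [c for c in CONFOUNDERS if c in confounders.columns]
    fit = fit_ols(np.asarray(log2fc, dtype=float),
                  confounders[cols].to_numpy(float), names=cols)
    return fit.residuals


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def per_rbp_association(
    feature_tables_by_rbp: Mapping[str, pd.DataFrame],
    distance_transform: Callable[[np.ndarray], np.ndarray] | None = None,
) -> list[RbpAssociation]:
    """Per-RBP regression of log2fc on distance plus the four confounders.

    Each table holds rows where the RBP has >= 1 binding site on the
    transcript (column ``d`` defined). ``distance_transform`` optionally maps
    raw d to the regressor actually fitted (e.g. the saturating proximity
    ``exp(-d/tau)``, a decreasing function of d); the enhancer/suppressor
    call is adjusted so that "enhancer" always means repression is stronger
    at small d. q-values are BH across RBPs.
    """
    from .io import logger

    results: list[tuple[str, float, float, int]] = []
    decreasing_regressor = False
    if distance_transform is not None:
        probe = distance_transform(np.array([0.0, 100.0]))
        decreasing_regressor = probe[0] > probe[1]
    for rbp_id in sorted(feature_tables_by_rbp):
        df = feature_tables_by_rbp[rbp_id].dropna(subset=["d", "log2fc"])
        n = len(df)
        if n < len(CONFOUNDERS) + 3:  # p + 2 with p = confounders + d
            logger.info("per_rbp_association: skipping %s (n=%d too small)", rbp_id, n)
            continue
        d = df["d"].to_numpy(float)
        x = distance_transform(d) if distance_transform is not None else d
        X = np.column_stack([x] + [df[c].to_numpy(float) for c in CONFOUNDERS])
        fit = fit_ols(df["log2fc"].to_numpy(float), X, names=["d"] + CONFOUNDERS)
        results.append((rbp_id, float(fit.beta[1]), float(fit.p[1]), n))
    if not results:
        return []
    q = bh_fdr([r[2] for r in results])
    out = []
    for (rbp_id, beta, p, n), qv in zip(results, q):
        # enhancer: repression weakens with d (beta>0 on raw d, <0 on a
        # decreasing transform of d)
        enh = beta < 0 if decreasing_regressor else beta > 0
        out.append(RbpAssociation(rbp_id, beta, p, float(qv),
                                  "enhancer" if enh else "suppressor", n))
    return out


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when n_a + n_b <= 12 with no ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= 12 and no_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    res = scipy.stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def chi2_contingency_nc(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction."""
    chi2, p, _, _ = scipy.stats.chi2_contingency(np.asarray(table), correction=False)
    return float(chi2), float(p)


def chi2_select_mirnas(
    fold_changes: pd.Series,
    mts_presence_by_mirna: Mapping[str, Sequence[str]],
    derepression_quantile: float = 0.75,
    k: int = 5,
) -> list[str]:
    """Rank miRNAs by how specifically their targets are de-repressed.

    ``fold_changes`` is indexed by transcript (a miRNA-depletion condition,
    so de-repression is a *high* log2fc). For each miRNA a 2x2 table of
    (has MTS) x (highly de-repressed, above ``derepression_quantile``) is
    tested by chi-square without continuity correction; the top ``k`` most
    significant miRNAs are returned. miRNAs with any expected cell < 1 are
    skipped.
    """
    from .io import logger

    cut = float(fold_changes.quantile(derepression_quantile))
    high = fold_changes > cut
    scored: list[tuple[float, float, str]] = []
    for mirna_id, targets in mts_presence_by_mirna.items():
        has = fold_changes.index.isin(set(targets))
        table = np.array([
            [int((has & high).sum()), int((has & ~high).sum())],
            [int((~has & high).sum()), int((~has & ~high).sum())],
        ])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        if (expected < 1).any():
            logger.info("chi2_select_mirnas: skipping %s (expected cell < 1)",
                        mirna_id)
            continue
        chi2, p = chi2_contingency_nc(table)
        scored.append((p, -chi2, mirna_id))
    scored.sort()
    return [m for _, _, m in scored[:k]]


def partition_by_binding_signal(signal: Sequence[float], k: int = 3) -> np.ndarray:
    """Quantile groups (default tertiles) of a binding-signal vector.

    Returns integer labels 0..k-1 (ascending signal). Values tied at a
    quantile edge go to the lower group; all-equal input collapses into
    group 0.
    """
    signal = np.asarray(signal, dtype=float)
    if k > signal.size:
        raise ValueError(f"k={k} > n={signal.size}")
    edges = np.quantile(signal, [i / k for i in range(1, k)])
    labels = np.zeros(signal.size, dtype=int)
    for e in edges:
        labels += signal > e
    return labels


@dataclass
class SaturationFit:
    """Independence-model coverage curve f(n) = 1 - (1-p)^n."""

    p: float

    def extrapolate(self, n: float) -> float:
        return 1.0 - (1.0 - self.p) ** n


def fit_saturation_curve(
    points: Sequence[tuple[float, float]]
) -> SaturationFit:
    """Fit the coverage fraction vs number-of-RBPs curve f(n) = 1 - (1-p)^n.

    Least squares on log(1 - f) = n log(1 - p), linear through the origin in
    n. Points with f exactly 1 carry no information on that scale and are
    excluded with a warning.
    """
    from .io import logger

    pts = [(float(n), float(f)) for n, f in points]
    if len(pts) < 3:
        raise ValueError("need >= 3 points")
    if any(not 0 <= f <= 1 for _, f in pts):
        raise ValueError("fractions must be in [0, 1]")
    usable = [(n, f) for n, f in pts if f < 1.0]
    if len(usable) < len(pts):
        logger.warning("fit_saturation_curve: excluded %d point(s) with f = 1",
                       len(pts) - len(usable))
    ns = np.array([n for n, _ in usable])
    ys = np.array([np.log1p(-f) for _, f in usable])
    slope = float(ns @ ys / (ns @ ns))
    return SaturationFit(p=float(1.0 - np.exp(slope)))


@dataclass
class CooccurrenceResult:
    direction: str  # {"co-occurrence", "mutual-exclusion"}
    p: float
    q: float


def cooccurrence_test(
    binding_signal_near_mts: Sequence[float],
    binding_signal_near_control_mts: Sequence[float],
) -> CooccurrenceResult:
    """Are binding signals larger near real MTSs than near control MTSs?

    Two-sided Wilcoxon on the two signal distributions (confounder matching
    is the caller's job, via the matched-sampling module). Direction is
    co-occurrence when the MTS median exceeds the control median. q defaults
    to p (BH with one test); use :func:`cooccurrence_panel` across tissues.
    """
    a = np.asarray(binding_signal_near_mts, dtype=float)
    b = np.asarray(binding_signal_near_control_mts, dtype=float)
    if b.size == 0:
        raise ValueError("control set empty")
    _, p = wilcoxon_rank_sum(a, b)
    direction = ("co-occurrence" if np.median(a) > np.median(b)
                 else "mutual-exclusion")
    return CooccurrenceResult(direction, p, p)


def cooccurrence_panel(
    pairs: Mapping[str, tuple[Sequence[float], Sequence[float]]]
) -> dict[str, CooccurrenceResult]:
    """Run the co-occurrence test per tissue and BH-correct across tissues."""
    keys = sorted(pairs)
    singles = {k: cooccurrence_test(*pairs[k]) for k in keys}
    qs = bh_fdr([singles[k].p for k in keys])
    return {k: CooccurrenceResult(singles[k].direction, singles[k].p, float(q))
            for k, q in zip(keys, qs)}


@dataclass
class KoStratumResult:
    stratum: str
    n: int
    mean_shift: float
    shifts: np.ndarray


def compare_ko_response(
    fc_parental: Mapping[str, float],
    fc_ko: Mapping[str, float],
    d_values: Mapping[str, float | None],
    cutoff: float = 100,
) -> tuple[dict[str, KoStratumResult], dict[tuple[str, str], tuple[float, float]]]:
    """De-repression on RBP knockout, stratified by MTS-RBS distance.

    Transcripts present in both conditions are stratified into d < cutoff
    ("short"), d >= cutoff ("long"), and no-site/no-RBS ("no-site"); the per-
    transcript shift is log2fc_ko - log2fc_parental. Returns per-stratum
    summaries and pairwise KS tests between strata (strata with < 3 members
    are skipped with a warning).
    """
    from .io import logger

    strata: dict[str, list[float]] = {"short": [], "long": [], "no-site": []}
    for tx, fc_p in fc_parental.items():
        if tx not in fc_ko:
            continue
        shift = fc_ko[tx] - fc_p
        d = d_values.get(tx)
        if d is None or (isinstance(d, float) and np.isnan(d)):
            strata["no-site"].append(shift)
        elif d < cutoff:
            strata["short"].append(shift)
        else:
            strata["long"].append(shift)
    results = {
        name: KoStratumResult(name, len(v), float(np.mean(v)) if v else np.nan,
                              np.asarray(v))
        for name, v in strata.items()
    }
    ks: dict[tuple[str, str], tuple[float, float]] = {}
    names = ["short", "long", "no-site"]
    for i, s1 in enumerate(names):
        for s2 in names[i + 1:]:
            if results[s1].n < 3 or results[s2].n < 3:
                logger.warning("compare_ko_response: skipping %s vs %s (stratum < 3)",
                               s1, s2)
                continue
            ks[(s1, s2)] = ks_two_sample(results[s1].shifts, results[s2].shifts)
    return results, ks
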