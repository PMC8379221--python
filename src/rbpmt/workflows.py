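"""End-to-end experiment drivers over the library.

Each function runs one desk-scale analysis on synthetic data — the analogue
of one headline result of the underlying study — and returns a plain dict of
the quantities it measures. The numbered scripts under ``analysis/`` and the
acceptance script are thin wrappers over these.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from . import matching, stats
from .features import CONFOUNDERS
from .simulate import (
    EffectSizes,
    SimulationConfig,
    dms_levels_from_counts,
    generate_transcriptome,
    implant_rbs,
    sample_feature_rows,
    simulate_dms_counts,
    simulate_fold_changes,
)
from .structure import group_fragments, score_fragments

#: Published scale of the problem: the ~150 profiled RBPs average ~22,000
#: 3'UTR binding sites each, and >1,500 human RBPs are known.
SITES_PER_RBP = 22_000
N_HUMAN_RBPS = 1_500


def interaction_extrapolation(
    sites_per_rbp: int = SITES_PER_RBP, n_rbps: int = N_HUMAN_RBPS
) -> dict:
    """Extrapolated number of possible RBP-3'UTR interactions."""
    total = sites_per_rbp * n_rbps
    return {"sites_per_rbp": sites_per_rbp, "n_rbps": n_rbps,
            "total_interactions": total,
            "total_interactions_millions": total / 1e6}


def parameter_recovery(
    seeds: Sequence[int] = (1, 2, 3),
    n_transcripts: int = 2000,
    beta_d: float = -1.0,
    tau: float = 50.0,
    noise_sigma: float = 1.0,
) -> dict:
    """Per-RBP regression recovery of the injected distance effect.

    For each seed, a cohort of single-site transcripts is simulated with the
    stated effect size and the distance coefficient re-estimated by the
    per-RBP MLR (confounders included, saturating-proximity regressor on the
    generative scale). Returns the per-seed estimates and direction calls.
    """
    betas, directions, qs = [], [], []
    for seed in seeds:
        cfg = SimulationConfig(seed=seed, n_transcripts=n_transcripts,
                               noise_sigma=noise_sigma,
                               distance_decay_scale=tau)
        rows = sample_feature_rows(n_transcripts, cfg)
        fc = simulate_fold_changes(rows, EffectSizes(beta_d=beta_d), tau,
                                   noise_sigma, seed=seed + 10_000)
        (assoc,) = stats.per_rbp_association(
            {"RBP000": fc}, distance_transform=lambda d: np.exp(-d / tau))
        betas.append(assoc.beta_d)
        directions.append(assoc.direction)
        qs.append(assoc.q)
    return {
        "seeds": list(seeds),
        "beta_d_true": beta_d,
        "beta_d_hat": betas,
        "beta_d_hat_mean": float(np.mean(betas)),
        "max_abs_error": float(max(abs(b - beta_d) for b in betas)),
        "all_enhancer": all(d == "enhancer" for d in directions),
        "all_significant": all(q < 0.05 for q in qs),
    }


def null_calibration(
    n_rbps: int = 100,
    n_per_rbp: int = 300,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """False-positive control with no distance effect.

    Simulates ``n_rbps`` independent RBP cohorts with beta_d = 0, runs the
    per-RBP association with BH correction, and tests whether the fraction
    called significant is consistent with <= alpha (one-sided exact binomial
    test at level 0.01).
    """
    tables = {}
    for r in range(n_rbps):
        cfg = SimulationConfig(seed=seed + 131 * r, n_transcripts=n_per_rbp)
        rows = sample_feature_rows(n_per_rbp, cfg, rbp_id=f"RBP{r:03d}")
        tables[f"RBP{r:03d}"] = simulate_fold_changes(
            rows, EffectSizes(beta_d=0.0), 50.0, 1.0, seed=seed + 7000 + r)
    assoc = stats.per_rbp_association(tables)
    n_sig = sum(a.q < alpha for a in assoc)
    binom_p = float(scipy.stats.binomtest(
        n_sig, len(assoc), alpha, alternative="greater").pvalue)
    return {
        "n_rbps": len(assoc),
        "n_significant": n_sig,
        "significant_fraction": n_sig / len(assoc),
        "binomial_p": binom_p,
        "calibrated": binom_p > 0.01,
    }


def _greedy_friendly_instance(n_clusters: int = 4) -> pd.DataFrame:
    """A 20-candidate instance whose optimal quartet packing is known:
    well-separated confounder clusters, one overlapped anchor each."""
    rows = []
    for c in range(n_clusters):
        base = 10.0 * c
        rows.append(dict(transcript=f"o{c}", d=0.0, overlapped=True,
                         site_type="8mer", local_au=base, ta=base,
                         sps=base, log10_len=base))
        for j in range(4):
            eps = 0.01 * j
            rows.append(dict(transcript=f"c{c}{j}", d=10.0 + 10 * j,
                             overlapped=False, site_type="8mer",
                             local_au=base + eps, ta=base + eps,
                             sps=base + eps, log10_len=base + eps))
    return pd.DataFrame(rows)


def exhaustive_max_packing(df: pd.DataFrame, cutoffs: dict) -> int:
    """Reference maximum number of disjoint valid quartets, by exhaustive
    search over all quartet packings (exponential; small instances only)."""
    idx = list(df.index)

    def valid(quad):
        sub = df.loc[list(quad)]
        if sub["overlapped"].sum() != 1:
            return False
        if (sub.loc[~sub["overlapped"], "d"] <= 0).any():
            return False
        if sub["site_type"].nunique() != 1:
            return False
        return all(sub[c].max() - sub[c].min() <= cutoffs[c]
                   for c in CONFOUNDERS)

    quads = [q for q in itertools.combinations(idx, 4) if valid(q)]

    def best(remaining, pool):
        top = 0
        for i, q in enumerate(pool):
            if set(q) <= remaining:
                top = max(top, 1 + best(remaining - set(q), pool[i + 1:]))
        return top

    return best(set(idx), quads)


def quartet_fidelity(seed: int = 0, n_instances: int = 3) -> dict:
    """Greedy quartet sampler vs the exhaustive packing oracle, plus the
    desk-scale distance-quartet analysis with an injected effect.

    On constructed 20-candidate instances the greedy packing count must
    match the exhaustive optimum; on a simulated cohort with beta_d = -1 and
    confounders deliberately correlated with distance, the verified quartet
    groups must be confounder-balanced and show a monotone residual
    fold-change trend from the overlapped group to the most distal group.
    """
    cut = {c: 1.0 for c in CONFOUNDERS}
    oracle_matches = 0
    for t in range(n_instances):
        df = _greedy_friendly_instance()
        greedy = len(matching.sample_quartets(df, cut, rng_seed=seed + t))
        oracle = exhaustive_max_packing(df, cut)
        oracle_matches += greedy == oracle
    cfg = SimulationConfig(seed=seed + 31, p_overlap=0.25, noise_sigma=0.5,
                           distance_decay_scale=150.0)
    rows = sample_feature_rows(1500, cfg, confounder_d_corr=0.5)
    fc = simulate_fold_changes(rows, EffectSizes(beta_d=-1.0),
                               cfg.distance_decay_scale, cfg.noise_sigma,
                               seed=seed + 32)
    fc["resid"] = stats.residualize(fc["log2fc"].to_numpy(), fc)
    quartets, pm = matching.sample_quartets_verified(
        fc, {"local_au": 0.3, "ta": 0.5, "sps": 2.5, "log10_len": 0.3},
        rng_seed=seed, max_retries=15)
    groups = matching.quartet_groups(quartets, fc)
    means = [float(groups[g]["resid"].mean()) for g in (1, 2, 3, 4)]
    _, p_g1_g4 = stats.wilcoxon_rank_sum(groups[1]["resid"], groups[4]["resid"])
    criteria_ok = all(
        q.site_type and len(set(q.members)) == 4
        and q.d_values == sorted(q.d_values) and q.d_values[0] == 0
        for q in quartets)
    return {
        "oracle_match_fraction": oracle_matches / n_instances,
        "n_quartets": len(quartets),
        "criteria_satisfied": criteria_ok,
        "balance_min_p": float(pm["p"].min()),
        "group_mean_residuals": means,
        "monotone_trend": means == sorted(means),
        "p_group1_vs_group4": float(p_g1_g4),
    }


def dms_structure_experiment(
    seed: int = 0,
    n_transcripts: int = 150,
    min_per_group: int = 300,
) -> dict:
    """Desk-scale analogue of the binding-vs-structure analysis.

    Simulates DMS counts with a positive openness gain, scores 100-nt
    fragments, balances the NoRBS/Lenient/Stringent groups on in vitro MFE
    and expression, and compares ΔDMS across groups and across bound-RBP
    counts.
    """
    cfg = SimulationConfig(seed=seed, n_transcripts=n_transcripts,
                           utr_length_mu=5.5, n_rbps=8,
                           rbs_per_utr_poisson_lambda=0.25)
    transcripts, truth = generate_transcriptome(cfg)
    rbs = implant_rbs(transcripts, truth, cfg)
    counts = simulate_dms_counts(transcripts, rbs, cfg)
    levels = dms_levels_from_counts(counts, transcripts, cfg.library_size)
    rbs_by_tx = defaultdict(list)
    for iv in rbs:
        rbs_by_tx[iv.transcript_id].append(iv)
    frags = score_fragments(transcripts, levels, rbs_by_tx)
    balanced = group_fragments(frags, rng_seed=seed)
    by_group = {g: d["delta_dms"].to_numpy() for g, d in balanced.groupby("group")}
    _, p_len_no = stats.wilcoxon_rank_sum(by_group["Lenient"], by_group["NoRBS"])
    _, p_str_len = stats.wilcoxon_rank_sum(by_group["Stringent"], by_group["Lenient"])
    means = {g: float(v.mean()) for g, v in by_group.items()}
    # count trend on the unbalanced fragment table: first vs last count bin
    low = frags.loc[frags["n_rbp"] == 0, "delta_dms"]
    high = frags.loc[frags["n_rbp"] >= 2, "delta_dms"]
    _, p_count = stats.wilcoxon_rank_sum(high, low)
    return {
        "n_fragments_per_group": int(min(len(v) for v in by_group.values())),
        "mean_delta_dms": means,
        "ordered": means["NoRBS"] < means["Lenient"] < means["Stringent"],
        "p_lenient_vs_norbs": float(p_len_no),
        "p_stringent_vs_lenient": float(p_str_len),
        "mean_delta_low_count": float(low.mean()),
        "mean_delta_high_count": float(high.mean()),
        "count_trend_increasing": float(high.mean()) > float(low.mean()),
        "p_count_trend": float(p_count),
        "enough_fragments": int(min(len(v) for v in by_group.values()))
                            >= min_per_group,
    }


def saturation_experiment(
    seed: int = 0,
    p_cover: float = 0.05,
    n_sites: int = 400,
    n_rbps_max: int = 100,
) -> dict:
    """Coverage saturation: fraction of MTSs with >= 1 nearby RBS vs the
    number of RBPs considered, fitted and extrapolated to 1,500 RBPs."""
    rng = np.random.default_rng(seed)
    covered = rng.random((n_rbps_max, n_sites)) < p_cover
    points = []
    for n in (5, 10, 20, 40, 60, 80, 100):
        frac = float(covered[:n].any(axis=0).mean())
        points.append((n, frac))
    fit = stats.fit_saturation_curve(points)
    return {
        "p_true": p_cover,
        "p_hat": fit.p,
        "rel_error": abs(fit.p - p_cover) / p_cover,
        "fraction_at_1500": fit.extrapolate(N_HUMAN_RBPS),
        "points": points,
    }


def kernel_checks() -> dict:
    """Hand-verifiable values of the statistical kernels and DMS equations."""
    from .structure import delta_dms, dms_score

    _, wilcoxon_p = stats.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
    bh_q = stats.bh_fdr([0.01, 0.02, 0.03, 0.04])
    chi2, _ = stats.chi2_contingency_nc([[20, 10], [10, 20]])
    score = float(dms_score([8.0], [2.0], pseudocount=0)[0])
    return {
        "wilcoxon_exact_p": float(wilcoxon_p),
        "bh_q_values": [float(q) for q in bh_q],
        "chi2_toy": float(chi2),
        "dms_score_toy": score,
        "delta_dms_antisymmetric": delta_dms(2.0, 0.5) == -delta_dms(0.5, 2.0),
    }
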