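"""Statistical kernels, each checked against an independent oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rbpmt.simulate import (
    EffectSizes,
    SimulationConfig,
    sample_feature_rows,
    simulate_fold_changes,
)
from rbpmt.stats import (
    SaturationFit,
    bh_fdr,
    chi2_contingency_nc,
    chi2_select_mirnas,
    compare_ko_response,
    cooccurrence_test,
    fit_ols,
    fit_saturation_curve,
    ks_two_sample,
    partition_by_binding_signal,
    per_rbp_association,
    residualize,
    wilcoxon_rank_sum,
)


class TestOls:
    def test_exact_fit_single_covariate(self):
        x = np.arange(10.0)
        fit = fit_ols(2 * x, x)
        assert fit.beta == pytest.approx([0.0, 2.0], abs=1e-12)
        assert np.allclose(fit.residuals, 0.0, atol=1e-12)

    def test_constant_response(self):
        fit = fit_ols(np.full(10, 3.0), np.arange(10.0))
        assert fit.beta[0] == pytest.approx(3.0)
        assert fit.beta[1] == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        """OLS equals an independent normal-equations solve, 100 instances."""
        for _ in range(100):
            n, p = 50, 3
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            fit = fit_ols(y, X)
            D = np.column_stack([np.ones(n), X])
            beta_oracle = np.linalg.solve(D.T @ D, D.T @ y)
            assert np.allclose(fit.beta, beta_oracle, rtol=1e-8)
            # residuals orthogonal to every design column
            assert np.max(np.abs(D.T @ fit.residuals)) < 1e-8 * n

    def test_rank_deficiency_names_column(self, rng):
        x = rng.normal(size=20)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="x1"):
            fit_ols(rng.normal(size=20), X)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError, match="n="):
            fit_ols(np.zeros(3), np.zeros((3, 3)))


class TestResidualize:
    def _conf(self, rng, n=200):
        return pd.DataFrame({
            "local_au": rng.random(n), "ta": rng.normal(2, 1, n),
            "sps": rng.normal(-14, 2, n), "log10_len": rng.normal(2.8, 0.3, n),
        })

    def test_linear_signal_fully_removed(self, rng):
        conf = self._conf(rng)
        y = 1.0 - 2 * conf["local_au"] + 0.3 * conf["ta"] + 0.1 * conf["sps"]
        resid = residualize(y.to_numpy(), conf)
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_orthogonal_effect_retained(self, rng):
        """A distance effect orthogonal to the confounders survives."""
        conf = self._conf(rng, n=400)
        raw = rng.normal(size=400)
        D = np.column_stack([np.ones(400), conf.to_numpy()])
        proj = D @ np.linalg.lstsq(D, raw, rcond=None)[0]
        effect = raw - proj  # orthogonal by construction
        resid = residualize(effect, conf)
        assert np.allclose(resid, effect, atol=1e-10)

    def test_mean_zero(self, rng):
        conf = self._conf(rng)
        resid = residualize(rng.normal(size=200), conf)
        assert abs(resid.mean()) < 1e-12


class TestBhFdr:
    def test_hand_executed_step_up(self):
        # p_(j) * m / j = .04, .04, .04, .04 -> all q = 0.04
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_identity(self):
        assert bh_fdr([0.3]) == pytest.approx([0.3])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_q_dominates_p_and_order_preserved(self, rng):
        p = rng.random(50)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


def wilcoxon_exact_enumeration(a, b):
    """Brute-force two-sided rank-sum p over all C(n_a+n_b, n_a) assignments."""
    pooled = sorted(list(a) + list(b))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in a)
    n = len(pooled)
    mean = len(a) * (n + 1) / 2
    stats = [sum(i + 1 for i in combo)
             for combo in itertools.combinations(range(n), len(a))]
    extreme = sum(abs(s - mean) >= abs(obs - mean) - 1e-9 for s in stats)
    return extreme / len(stats)


class TestWilcoxon:
    def test_exact_p_by_enumeration(self):
        stat, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)
        assert p == pytest.approx(wilcoxon_exact_enumeration([1, 2, 3], [4, 5, 6]))

    def test_identical_samples_p_one(self):
        a = list(np.arange(20.0))
        _, p = wilcoxon_rank_sum(a, a)
        assert p == pytest.approx(1.0)

    def test_symmetry(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=15)
        assert wilcoxon_rank_sum(a, b)[1] == pytest.approx(wilcoxon_rank_sum(b, a)[1])

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_returned_p_matches_enumeration_below_switch(self, rng):
        """Tie-free samples with combined n <= 12 take the exact path."""
        for _ in range(20):
            a = list(np.round(rng.normal(size=4), 6))
            b = list(np.round(rng.normal(1.0, 1, size=5), 6))
            if len(set(a + b)) < 9:
                continue
            _, p = wilcoxon_rank_sum(a, b)
            assert p == pytest.approx(wilcoxon_exact_enumeration(a, b))

    def test_approx_close_to_exact_above_switch(self, rng):
        """Just above the exact switch the normal approximation stays
        within 0.02 of enumeration (groups of 6 and 7)."""
        for _ in range(10):
            a = list(np.round(rng.normal(size=6), 6))
            b = list(np.round(rng.normal(1.0, 1, size=7), 6))
            if len(set(a + b)) < 13:
                continue
            _, p = wilcoxon_rank_sum(a, b)  # asymptotic path (n=13)
            assert abs(p - wilcoxon_exact_enumeration(a, b)) <= 0.02


class TestKs:
    def test_disjoint_supports(self):
        d, _ = ks_two_sample([0, 0, 0], [1, 1, 1])
        assert d == pytest.approx(1.0)

    def test_identical(self):
        d, p = ks_two_sample([1.0, 2.0], [1.0, 2.0])
        assert d == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_matches_brute_force_ecdf(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=20), rng.normal(0.5, 1, size=20)
            d, _ = ks_two_sample(a, b)
            pts = np.concatenate([a, b])
            brute = max(abs((a <= t).mean() - (b <= t).mean()) for t in pts)
            assert d == pytest.approx(brute)


class TestChi2:
    def test_toy_table(self):
        chi2, _ = chi2_contingency_nc([[20, 10], [10, 20]])
        assert chi2 == pytest.approx(20 / 3)

    def test_independent_table_zero(self):
        chi2, _ = chi2_contingency_nc([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0)

    def test_mirna_selection_ranks_true_target(self, rng):
        """Depletion data where only miRNA-1's targets are derepressed."""
        n = 200
        txs = [f"tx{i}" for i in range(n)]
        targets = {f"mir{j}": set(rng.choice(txs, 40, replace=False))
                   for j in range(1, 6)}
        fc = pd.Series(rng.normal(0, 0.3, n), index=txs)
        fc[list(targets["mir1"])] += 2.0  # derepressed on depletion
        top = chi2_select_mirnas(fc, targets, k=5)
        assert top[0] == "mir1"


class TestPartition:
    def test_tertiles_of_1_to_9(self):
        labels = partition_by_binding_signal(np.arange(1.0, 10.0), k=3)
        assert list(labels) == [0, 0, 0, 1, 1, 1, 2, 2, 2]

    def test_all_equal_collapse_to_low_group(self):
        labels = partition_by_binding_signal(np.ones(9), k=3)
        assert set(labels) == {0}

    def test_balanced_sizes_without_ties(self, rng):
        sig = rng.normal(size=91)
        labels = partition_by_binding_signal(sig, k=3)
        sizes = np.bincount(labels)
        assert sizes.max() - sizes.min() <= 1

    def test_k_exceeds_n_rejected(self):
        with pytest.raises(ValueError):
            partition_by_binding_signal([1.0, 2.0], k=3)


class TestSaturation:
    def test_recovers_exact_independence_model(self):
        p = 0.1
        pts = [(n, 1 - (1 - p) ** n) for n in (5, 10, 20, 50)]
        fit = fit_saturation_curve(pts)
        assert fit.p == pytest.approx(0.1)
        assert fit.extrapolate(10) == pytest.approx(1 - 0.9 ** 10)

    def test_zero_coverage(self):
        fit = fit_saturation_curve([(5, 0.0), (10, 0.0), (20, 0.0)])
        assert fit.p == pytest.approx(0.0)
        assert fit.extrapolate(1500) == pytest.approx(0.0)

    def test_simulated_coverage_recovery(self, rng):
        """Independent per-RBP coverage sim, p=0.05: p-hat within 10%."""
        p_true, n_sites = 0.05, 400
        covered = rng.random((100, n_sites)) < p_true
        pts = []
        for n in (5, 10, 20, 40, 60, 80, 100):
            frac = covered[:n].any(axis=0).mean()
            pts.append((n, frac))
        fit = fit_saturation_curve(pts)
        assert fit.p == pytest.approx(p_true, rel=0.10)
        assert fit.extrapolate(1500) > 0.99

    def test_full_coverage_point_excluded(self):
        fit = fit_saturation_curve([(5, 0.4), (10, 0.64), (20, 1.0)])
        assert 0 < fit.p < 1


class TestCooccurrence:
    def test_shifted_signals_detected(self, rng):
        a = rng.normal(1.0, 1, 200)
        b = rng.normal(0.0, 1, 200)
        res = cooccurrence_test(a, b)
        assert res.direction == "co-occurrence" and res.p < 0.05

    def test_swap_flips_direction_keeps_p(self, rng):
        a = rng.normal(1.0, 1, 100)
        b = rng.normal(0.0, 1, 100)
        r1, r2 = cooccurrence_test(a, b), cooccurrence_test(b, a)
        assert r1.p == pytest.approx(r2.p)
        assert {r1.direction, r2.direction} == {"co-occurrence", "mutual-exclusion"}

    def test_null_type_one_error_controlled(self, rng):
        hits = 0
        for _ in range(100):
            a, b = rng.normal(size=50), rng.normal(size=50)
            hits += cooccurrence_test(a, b).p < 0.05
        assert hits <= 12  # binomial(100, .05) upper tail

    def test_empty_control_rejected(self):
        with pytest.raises(ValueError):
            cooccurrence_test([1.0], [])


class TestPerRbpAssociation:
    def _tables(self, n_rbps, beta_d, n=500, seed=0):
        cfg = SimulationConfig(seed=seed, n_transcripts=n)
        tables = {}
        for r in range(n_rbps):
            cfg_r = SimulationConfig(seed=seed + 17 * r, n_transcripts=n)
            rows = sample_feature_rows(n, cfg_r, rbp_id=f"RBP{r:03d}")
            eff = EffectSizes(beta_d=beta_d)
            tables[f"RBP{r:03d}"] = simulate_fold_changes(
                rows, eff, tau=50.0, noise_sigma=1.0, seed=seed + 1000 + r)
        return tables

    def test_enhancers_detected_with_power(self):
        tables = self._tables(20, beta_d=-1.0)
        res = per_rbp_association(
            tables, distance_transform=lambda d: np.exp(-d / 50.0))
        assert len(res) == 20
        assert all(r.direction == "enhancer" and r.q < 0.05 for r in res)

    def test_raw_distance_regressor_same_calls(self):
        tables = self._tables(5, beta_d=-1.0)
        res = per_rbp_association(tables)  # raw d: enhancer iff beta > 0
        assert all(r.direction == "enhancer" for r in res)

    def test_single_rbp_q_equals_p(self):
        tables = self._tables(1, beta_d=-1.0)
        (res,) = per_rbp_association(tables)
        assert res.q == pytest.approx(res.p)

    def test_invariant_q_dominates_p(self):
        res = per_rbp_association(self._tables(10, beta_d=-0.3))
        assert all(r.q >= r.p - 1e-12 for r in res)


class TestCompareKo:
    def _data(self, rng, gated=True):
        n = 300
        d = {f"tx{i}": (float(rng.integers(0, 300)) if i < 200 else None)
             for i in range(n)}
        parental = {t: float(rng.normal(-1 if d[t] is not None else 0, 0.3))
                    for t in d}
        ko = {}
        for t in d:
            shift = 0.0
            if gated and d[t] is not None and d[t] < 100:
                shift = 1.0  # derepression only for close-binding targets
            ko[t] = parental[t] + shift + float(rng.normal(0, 0.1))
        return parental, ko, d

    def test_distance_gated_derepression(self, rng):
        parental, ko, d = self._data(rng, gated=True)
        results, ks = compare_ko_response(parental, ko, d, cutoff=100)
        assert results["short"].mean_shift > 0.8
        assert abs(results["long"].mean_shift) < 0.2
        assert ks[("short", "long")][1] < 0.05

    def test_identical_conditions_null(self, rng):
        parental, _, d = self._data(rng)
        results, ks = compare_ko_response(parental, dict(parental), d)
        for r in results.values():
            assert r.mean_shift == pytest.approx(0.0, abs=1e-12)
        assert ks[("short", "long")][1] == pytest.approx(1.0)

    def test_no_site_stratum_centered_at_zero(self, rng):
        parental, ko, d = self._data(rng, gated=True)
        results, _ = compare_ko_response(parental, ko, d)
        assert abs(results["no-site"].mean_shift) < 0.05
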