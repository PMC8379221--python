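"""Covariate-balanced sampling: quartets, cutoff search, balance checks."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rbpmt.features import CONFOUNDERS
from rbpmt.matching import (
    composition_split,
    optimize_cutoffs,
    quartet_groups,
    sample_count_groups,
    sample_quartets,
    sample_quartets_verified,
    verify_indistinguishable,
)
from rbpmt.simulate import (
    EffectSizes,
    SimulationConfig,
    sample_feature_rows,
    simulate_fold_changes,
)
from rbpmt.stats import residualize, wilcoxon_rank_sum

CUT_WIDE = {"local_au": 1.0, "ta": 5.0, "sps": 20.0, "log10_len": 3.0}


def make_candidates(specs):
    """Build a candidate frame from (transcript, d, overlapped, site_type,
    au, ta, sps, len) tuples."""
    rows = [dict(zip(("transcript", "d", "overlapped", "site_type",
                      "local_au", "ta", "sps", "log10_len"), s)) for s in specs]
    return pd.DataFrame(rows)


def exhaustive_max_packing(df, cutoffs):
    """Oracle: maximum number of disjoint valid quartets by exhaustive search."""
    idx = list(df.index)

    def valid(quad):
        sub = df.loc[list(quad)]
        if sub["overlapped"].sum() != 1:
            return False
        if (sub.loc[~sub["overlapped"], "d"] <= 0).any():
            return False
        if sub["site_type"].nunique() != 1:
            return False
        return all(sub[c].max() - sub[c].min() <= cutoffs[c] for c in CONFOUNDERS)

    quads = [q for q in itertools.combinations(idx, 4) if valid(q)]

    def best(remaining, pool):
        top = 0
        for i, q in enumerate(pool):
            if set(q) <= remaining:
                top = max(top, 1 + best(remaining - set(q), pool[i + 1:]))
        return top

    return best(set(idx), quads)


class TestSampleQuartets:
    def test_unique_feasible_set(self):
        df = make_candidates([
            ("a", 0, True, "8mer", 0.5, 2.0, -14.0, 2.5),
            ("b", 10, False, "8mer", 0.5, 2.0, -14.0, 2.5),
            ("c", 40, False, "8mer", 0.5, 2.0, -14.0, 2.5),
            ("d", 90, False, "8mer", 0.5, 2.0, -14.0, 2.5),
        ])
        (q,) = sample_quartets(df, CUT_WIDE, rng_seed=0)
        assert q.members == ["a", "b", "c", "d"]  # ascending d
        assert q.d_values == [0.0, 10.0, 40.0, 90.0]
        assert q.groups == [1, 2, 3, 4]

    def test_cutoff_violation_blocks_quartet(self):
        df = make_candidates([
            ("a", 0, True, "8mer", 0.1, 2.0, -14.0, 2.5),
            ("b", 10, False, "8mer", 0.9, 2.0, -14.0, 2.5),
            ("c", 40, False, "8mer", 0.5, 2.0, -14.0, 2.5),
            ("d", 90, False, "8mer", 0.5, 2.0, -14.0, 2.5),
        ])
        cut = dict(CUT_WIDE, local_au=0.2)
        assert sample_quartets(df, cut, rng_seed=0) == []

    def test_site_types_must_match(self):
        df = make_candidates([
            ("a", 0, True, "8mer", 0.5, 2.0, -14.0, 2.5),
            ("b", 10, False, "7mer-m8", 0.5, 2.0, -14.0, 2.5),
            ("c", 40, False, "8mer", 0.5, 2.0, -14.0, 2.5),
            ("d", 90, False, "8mer", 0.5, 2.0, -14.0, 2.5),
        ])
        assert sample_quartets(df, CUT_WIDE, rng_seed=0) == []

    def test_no_overlapped_candidates_empty(self):
        df = make_candidates([
            ("a", 5, False, "8mer", 0.5, 2.0, -14.0, 2.5),
            ("b", 10, False, "8mer", 0.5, 2.0, -14.0, 2.5),
            ("c", 40, False, "8mer", 0.5, 2.0, -14.0, 2.5),
            ("d", 90, False, "8mer", 0.5, 2.0, -14.0, 2.5),
        ])
        assert sample_quartets(df, CUT_WIDE, rng_seed=0) == []

    def test_deterministic_under_seed_and_disjoint(self):
        cfg = SimulationConfig(seed=21, p_overlap=0.3)
        df = sample_feature_rows(80, cfg)
        q1 = sample_quartets(df, CUT_WIDE, rng_seed=7)
        q2 = sample_quartets(df, CUT_WIDE, rng_seed=7)
        assert [q.members for q in q1] == [q.members for q in q2]
        all_members = [m for q in q1 for m in q.members]
        assert len(all_members) == len(set(all_members))

    def test_emitted_quartets_satisfy_all_criteria(self):
        """Post-hoc exhaustive check of the three selection criteria."""
        cfg = SimulationConfig(seed=22, p_overlap=0.3)
        df = sample_feature_rows(120, cfg)
        cut = {"local_au": 0.3, "ta": 0.5, "sps": 2.0, "log10_len": 0.3}
        feat = df.set_index("transcript")
        for q in sample_quartets(df, cut, rng_seed=3):
            sub = feat.loc[q.members]
            assert sub["site_type"].nunique() == 1
            assert sub["overlapped"].sum() == 1
            assert bool(sub["overlapped"].iloc[0])  # group 1 is the overlapped one
            assert (sub["d"].iloc[1:] > 0).all()
            assert list(sub["d"]) == sorted(sub["d"])
            for c in CONFOUNDERS:
                assert sub[c].max() - sub[c].min() <= cut[c] + 1e-12

    def test_greedy_matches_exhaustive_packing_oracle(self, rng):
        """On greedy-friendly 20-candidate instances the greedy packing
        count equals the exhaustive optimum."""
        for trial in range(5):
            specs = []
            # 4 well-separated confounder clusters, each holding one
            # overlapped candidate and four d>0 candidates
            for c in range(4):
                base = 10.0 * c
                specs.append((f"o{c}", 0, True, "8mer", base, base, base, base))
                for j in range(4):
                    eps = 0.01 * j
                    specs.append((f"c{c}{j}", 10 + 10 * j, False, "8mer",
                                  base + eps, base + eps, base + eps, base + eps))
            df = make_candidates(specs)
            cut = {c: 1.0 for c in CONFOUNDERS}
            got = len(sample_quartets(df, cut, rng_seed=trial))
            assert got == exhaustive_max_packing(df, cut) == 4


class TestVerifyIndistinguishable:
    def _groups(self, rng, shift=0.0):
        def grp(mu_shift=0.0):
            return pd.DataFrame({
                "local_au": rng.normal(0.5 + mu_shift, 0.1, 50).clip(0, 1),
                "ta": rng.normal(2.5, 0.4, 50),
                "sps": rng.normal(-14, 2, 50),
                "log10_len": rng.normal(2.8, 0.25, 50),
            })
        return {1: grp(), 2: grp(shift)}

    def test_identical_copies_pass(self, rng):
        g = self._groups(rng)[1]
        ok, pm = verify_indistinguishable({1: g, 2: g.copy()})
        assert ok and (pm["p"] == 1.0).all()

    def test_null_groups_usually_pass(self, rng):
        passes = sum(verify_indistinguishable(self._groups(rng))[0]
                     for _ in range(40))
        # pass prob ~ (1-alpha)^4 tests ~ 0.81; demand well above half
        assert passes >= 25

    def test_shifted_group_fails(self, rng):
        ok, pm = verify_indistinguishable(self._groups(rng, shift=0.3))
        assert not ok
        worst = pm.loc[pm["p"].idxmin(), "confounder"]
        assert worst == "local_au"

    def test_small_group_comparison_skipped(self, rng):
        g = self._groups(rng)[1]
        ok, pm = verify_indistinguishable({1: g, 2: g.head(2)})
        assert pm.empty and ok


class TestOptimizeCutoffs:
    def test_degenerate_landscape_consumes_everything(self):
        specs = [(f"o{i}", 0, True, "8mer", 0.5, 2.0, -14.0, 2.5)
                 for i in range(5)]
        specs += [(f"c{i}", 10 + i, False, "8mer", 0.5, 2.0, -14.0, 2.5)
                  for i in range(15)]
        df = make_candidates(specs)
        cut = optimize_cutoffs(df, optimizer="grid", n_grid=3)
        assert len(sample_quartets(df, cut, rng_seed=0)) == 5  # 20 = 4*5 consumed

    def test_bimodal_confounder_respects_modes(self):
        """Optimum admits within-mode quartets only; equals grid oracle."""
        specs = []
        for mode, base in (("lo", 0.0), ("hi", 1.0)):
            specs.append((f"o_{mode}", 0, True, "8mer", 0.5, 2.0, -14.0 + base, 2.5))
            for j in range(3):
                specs.append((f"c_{mode}{j}", 10 + j, False, "8mer",
                              0.5, 2.0, -14.0 + base + 0.001 * j, 2.5))
        df = make_candidates(specs)
        cut = optimize_cutoffs(df, optimizer="grid", n_grid=5)
        qs = sample_quartets(df, cut, rng_seed=0)
        assert len(qs) == 2
        for q in qs:
            modes = {m.split("_")[1][:2] for m in q.members}
            assert len(modes) == 1

    def test_grid_deterministic_across_seeds(self):
        cfg = SimulationConfig(seed=23, p_overlap=0.3)
        df = sample_feature_rows(60, cfg)
        c1 = optimize_cutoffs(df, optimizer="grid", n_grid=3, rng_seed=1)
        c2 = optimize_cutoffs(df, optimizer="grid", n_grid=3, rng_seed=1)
        assert c1 == c2

    def test_gp_surrogate_runs_and_selects(self):
        cfg = SimulationConfig(seed=24, p_overlap=0.3)
        df = sample_feature_rows(60, cfg)
        cut = optimize_cutoffs(df, optimizer="gp", budget=15, rng_seed=2)
        assert len(sample_quartets(df, cut, rng_seed=2)) > 0


class TestDistanceQuartetAnalysis:
    """Desk-scale analogue of the confounder-corrected distance analysis."""

    def _cohort(self, beta_d, seed=31):
        # decay scale 150 nt spreads the effect across the full distance
        # range so all four group means are separable at desk scale
        cfg = SimulationConfig(seed=seed, p_overlap=0.25, noise_sigma=0.5,
                               distance_decay_scale=150.0)
        rows = sample_feature_rows(1500, cfg, confounder_d_corr=0.5)
        eff = EffectSizes(beta_d=beta_d)
        fc = simulate_fold_changes(rows, eff, cfg.distance_decay_scale,
                                   cfg.noise_sigma, seed=seed + 1)
        fc["resid"] = residualize(fc["log2fc"].to_numpy(), fc)
        return fc

    def test_monotone_residual_trend_with_injected_effect(self):
        fc = self._cohort(beta_d=-1.0)
        qs, pm = sample_quartets_verified(
            fc, {"local_au": 0.3, "ta": 0.5, "sps": 2.5, "log10_len": 0.3},
            rng_seed=1, max_retries=15)
        groups = quartet_groups(qs, fc)
        assert len(groups[1]) >= 40
        means = [groups[g]["resid"].mean() for g in (1, 2, 3, 4)]
        assert means == sorted(means)  # monotone: strongest repression at d=0
        _, p = wilcoxon_rank_sum(groups[1]["resid"], groups[4]["resid"])
        assert p < 0.05
        assert pm["p"].min() > 0.05  # confounders balanced

    def test_no_false_positive_without_effect(self):
        """beta_d = 0 with the same correlated confounders: the sampler
        itself must not create a group difference."""
        fc = self._cohort(beta_d=0.0, seed=32)
        qs, _ = sample_quartets_verified(
            fc, {"local_au": 0.3, "ta": 0.5, "sps": 2.5, "log10_len": 0.3},
            rng_seed=1, max_retries=15)
        groups = quartet_groups(qs, fc)
        _, p = wilcoxon_rank_sum(groups[1]["resid"], groups[4]["resid"])
        assert p > 0.05


class TestCountGroups:
    def _rows(self, rng, n=300, confounded=False):
        n_rbp = rng.integers(0, 20, n)
        log10_len = rng.normal(2.8, 0.25, n)
        if confounded:
            log10_len = log10_len + 0.04 * n_rbp  # count-length confounding
        return pd.DataFrame({
            "transcript": [f"tx{i}" for i in range(n)],
            "n_rbp": n_rbp.astype(float),
            "local_au": rng.random(n),
            "ta": rng.normal(2.5, 0.4, n),
            "sps": rng.normal(-14, 2, n),
            "log10_len": log10_len,
        })

    def test_independent_confounders_retain_everything(self, rng):
        df = self._rows(rng)
        out = sample_count_groups(df, k=5, rng_seed=0)
        assert out["count_group"].nunique() == 5

    def test_balances_constructed_confounding(self, rng):
        df = self._rows(rng, confounded=True)
        out = sample_count_groups(df, k=5, rng_seed=0)
        r = np.corrcoef(out["n_rbp"], out["log10_len"])[0, 1]
        assert abs(r) < 0.1

    def test_k1_trivially_passes(self, rng):
        df = self._rows(rng, n=30)
        out = sample_count_groups(df, k=1)
        assert (out["count_group"] == 0).all() and len(out) == 30


class TestCompositionSplit:
    def test_separable_instance_perfect_split(self):
        df = pd.DataFrame({
            "transcript": [f"t{i}" for i in range(24)],
            "n_rbp": [2.0] * 24,
            "rbp_set": [frozenset(("A", "B")) if i % 2 else frozenset(("C", "D"))
                        for i in range(24)],
            "log2fc": 0.0,
        })
        split = composition_split(df, count_range=(1, 10))
        assert len(split.side_a) >= 10 and len(split.side_b) >= 10
        sets_a = set().union(*split.side_a["rbp_set"])
        sets_b = set().union(*split.side_b["rbp_set"])
        assert sets_a.isdisjoint(sets_b)
        assert split.count_histogram_p > 0.05 or np.isnan(split.count_histogram_p)

    def test_composition_fractions_in_range(self, rng):
        rbps = [f"R{i}" for i in range(8)]
        df = pd.DataFrame({
            "transcript": [f"t{i}" for i in range(100)],
            "n_rbp": [float(rng.integers(1, 6)) for _ in range(100)],
        })
        df["rbp_set"] = [frozenset(rng.choice(rbps, int(k), replace=False))
                         for k in df["n_rbp"]]
        df["log2fc"] = rng.normal(size=100)
        split = composition_split(df, count_range=(1, 10))
        comp = split.composition
        assert ((comp["frac_a"] >= 0) & (comp["frac_a"] <= 1)).all()
        assert ((comp["frac_b"] >= 0) & (comp["frac_b"] <= 1)).all()

    def test_exchangeable_composition_no_efficacy_difference(self, rng):
        """When composition carries no signal, fold changes of the two
        sides are indistinguishable (analogue of the identity-vs-count
        comparison)."""
        rbps = [f"R{i}" for i in range(10)]
        ps = []
        for rep in range(30):
            n = 120
            counts = rng.integers(1, 8, n)
            df = pd.DataFrame({
                "transcript": [f"t{i}" for i in range(n)],
                "n_rbp": counts.astype(float),
                "rbp_set": [frozenset(rng.choice(rbps, int(k), replace=False))
                            for k in counts],
                "log2fc": rng.normal(size=n),
            })
            split = composition_split(df, count_range=(1, 10), rng_seed=rep)
            _, p = wilcoxon_rank_sum(split.side_a["log2fc"],
                                     split.side_b["log2fc"])
            ps.append(p)
        assert np.mean(np.array(ps) < 0.05) <= 0.2  # near-uniform p under null
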