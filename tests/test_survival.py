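"""Tests for the Cox machinery, log-rank statistics and LOOCV stratification."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as lifelines_logrank

from megsurv.io import AlterationMatrix, ClinicalTable
from megsurv import survival as sv


class TestCoxFit:
    def test_matches_lifelines(self, survival_clinical):
        fit = sv.fit_cox(survival_clinical, ["megs", "age", "gender"])
        df = survival_clinical.to_frame()
        df["age"] = (df["age"] >= 50).astype(float)
        t, e = sv.apply_horizon(df["time"].to_numpy(),
                                df["event"].to_numpy(), 60.0)
        df["time"], df["event"] = t, e
        cph = CoxPHFitter().fit(df[["time", "event", "megs", "age", "gender"]],
                                "time", "event")
        assert fit.beta == pytest.approx(cph.params_.to_numpy(), abs=1e-4)
        assert fit.se == pytest.approx(cph.standard_errors_.to_numpy(),
                                       abs=1e-4)

    def test_summary_identities(self, survival_clinical):
        fit = sv.fit_cox(survival_clinical, ["megs", "age"])
        assert fit.hr == pytest.approx(np.exp(fit.beta))
        assert fit.wald == pytest.approx((fit.beta / fit.se) ** 2)
        lo, hi = fit.ci95[:, 0], fit.ci95[:, 1]
        assert np.all(lo <= fit.hr) and np.all(fit.hr <= hi)

    def test_constant_covariate_gets_zero_beta(self, survival_clinical):
        clin = survival_clinical
        clin.extra["flat"] = 0.0
        fit = sv.fit_cox(clin, ["megs", "flat"])
        assert fit.beta[1] == 0.0
        assert fit.hr[1] == 1.0

    def test_recovers_known_hazard_ratio(self):
        # two-group exponential data, HR 2, no censoring
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            N = 2000
            x = (rng.random(N) < 0.5).astype(float)
            t = rng.exponential(1.0 / (0.05 * np.exp(np.log(2) * x)))
            clin = ClinicalTable([f"P{i}" for i in range(N)],
                                 np.maximum(t, 1e-3), np.ones(N, dtype=int),
                                 extra=pd.DataFrame({"x": x}))
            fit = sv.fit_cox(clin, ["x"], horizon_months=None)
            if abs(fit.beta[0] - np.log(2)) <= 3 * fit.se[0]:
                hits += 1
        assert hits >= 4

    def test_no_events_errors(self):
        clin = ClinicalTable(["A", "B"], [5.0, 6.0], [0, 0],
                             extra=pd.DataFrame({"x": [0.0, 1.0]}))
        with pytest.raises(ValueError, match="event"):
            sv.fit_cox(clin, ["x"])


class TestStepwise:
    def test_keeps_strong_drops_noise(self):
        kept = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            N = 1000
            strong = (rng.random(N) < 0.5).astype(float)
            noise = rng.normal(size=N)
            t = rng.exponential(1.0 / (0.05 * np.exp(np.log(2) * strong)))
            clin = ClinicalTable(
                [f"P{i}" for i in range(N)], np.maximum(t, 1e-3),
                np.ones(N, dtype=int),
                extra=pd.DataFrame({"strong": strong, "noise": noise}))
            fit = sv.stepwise_cox(clin, ["strong", "noise"],
                                  horizon_months=None)
            if fit.names == ["strong"]:
                kept += 1
        assert kept >= 4

    def test_all_noise_selects_nothing(self):
        empties = 0
        for seed in range(8):
            rng = np.random.default_rng(200 + seed)
            N = 500
            clin = ClinicalTable(
                [f"P{i}" for i in range(N)],
                rng.exponential(20, N) + 1e-3, np.ones(N, dtype=int),
                extra=pd.DataFrame({"a": rng.normal(size=N),
                                    "b": rng.normal(size=N)}))
            try:
                sv.stepwise_cox(clin, ["a", "b"], horizon_months=None)
            except ValueError:
                empties += 1
        assert empties >= 6

    def test_single_significant_candidate_retained(self, survival_clinical):
        fit = sv.stepwise_cox(survival_clinical, ["megs"])
        assert fit.names == ["megs"]


class TestKaplanMeier:
    def test_no_events_constant_one(self):
        km = sv.km_estimate([3.0, 5.0, 7.0], [0, 0, 0], ["g"] * 3)
        _, surv, _ = km["g"]
        assert np.all(surv == 1.0)

    def test_product_limit_by_hand(self):
        km = sv.km_estimate([1.0, 2.0, 3.0], [1, 1, 1], ["g"] * 3)
        _, surv, _ = km["g"]
        assert surv == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_censored_only_keeps_curve_at_one(self):
        km = sv.km_estimate([5.0], [0], ["g"])
        t, surv, cens = km["g"]
        assert surv[0] == 1.0 and cens[0] == 1


class TestLogrank:
    def test_identical_groups_give_zero(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.array([1, 1, 0, 1, 1, 0])
        g = np.array([0, 0, 0, 1, 1, 1])
        chi2, p = sv.logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_separated_groups_hand_value(self):
        t = np.array([1.0, 2, 3, 4, 5, 6])
        e = np.ones(6, dtype=int)
        g = np.array([0, 0, 0, 1, 1, 1])
        chi2, _ = sv.logrank_test(t, e, g)
        assert chi2 == pytest.approx(5.0517, abs=1e-3)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 60) + 0.01
        e = (rng.random(60) < 0.7).astype(int)
        g = (rng.random(60) < 0.5).astype(int)
        c1, _ = sv.logrank_test(t, e, g)
        c2, _ = sv.logrank_test(t, e, 1 - g)
        assert c1 == pytest.approx(c2, abs=1e-10)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10, 80) + 0.01
        e = (rng.random(80) < 0.7).astype(int)
        g = (rng.random(80) < 0.4).astype(int)
        chi2, p = sv.logrank_test(t, e, g)
        ref = lifelines_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)


class TestMaxSelectedCutoff:
    def test_forced_binary_split(self):
        scores = np.array([0.0] * 10 + [1.0] * 10)
        t = np.concatenate([np.full(10, 50.0), np.arange(1.0, 11)])
        e = np.concatenate([np.zeros(10, int), np.ones(10, int)])
        cutoff, _ = sv.max_selected_cutoff(scores, t, e)
        assert cutoff == pytest.approx(0.5)

    def test_patient_order_invariance(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=50)
        t = rng.exponential(10, 50) + 0.01
        e = (rng.random(50) < 0.8).astype(int)
        c1, _ = sv.max_selected_cutoff(scores, t, e)
        perm = rng.permutation(50)
        c2, _ = sv.max_selected_cutoff(scores[perm], t[perm], e[perm])
        assert c1 == pytest.approx(c2)

    def test_matches_bruteforce_on_three_levels(self):
        scores = np.array([0.0] * 6 + [1.0] * 6 + [2.0] * 6)
        rng = np.random.default_rng(4)
        t = rng.exponential(10, 18) + 0.01
        e = np.ones(18, int)
        cutoff, stat = sv.max_selected_cutoff(scores, t, e,
                                              min_group_frac=0.1)
        best = max(
            (sv.logrank_test(t, e, (scores > c).astype(int))[0], c)
            for c in (0.5, 1.5))
        assert stat == pytest.approx(best[0], abs=1e-9)
        assert cutoff == pytest.approx(best[1])

    def test_single_level_errors(self):
        with pytest.raises(ValueError):
            sv.max_selected_cutoff(np.ones(5), np.arange(1.0, 6),
                                   np.ones(5, int))


class TestLoocv:
    def test_onestep_matches_full_refits(self, survival_clinical):
        X, t, e, _ = sv.design_matrix(survival_clinical,
                                      ["megs", "age", "gender"])
        t, e = sv.apply_horizon(t, e, 60.0)
        beta, _, _, _ = sv._cox_newton(X, t, e)
        fast = sv._loocv_scores(X, t, e, beta, [])
        slow = sv._loocv_scores_refit(X, t, e, beta, [])
        assert np.abs(fast - slow).max() < 1e-3

    def test_scores_invariant_to_patient_order(self, survival_clinical):
        s1 = sv.loocv_stratify(survival_clinical, ["megs", "age"],
                               n_perm=0, seed=None)
        rng = np.random.default_rng(0)
        perm = rng.permutation(survival_clinical.n_patients)
        shuffled = survival_clinical.subset(perm)
        s2 = sv.loocv_stratify(shuffled, ["megs", "age"], n_perm=0, seed=None)
        lookup = dict(zip(s2.patient_ids, s2.scores))
        reordered = np.array([lookup[p] for p in s1.patient_ids])
        assert reordered == pytest.approx(s1.scores, abs=1e-9)

    def test_strong_effect_detected(self, survival_clinical):
        strat = sv.loocv_stratify(survival_clinical,
                                  ["megs", "age", "gender"],
                                  n_perm=100, seed=11)
        assert strat.adjusted_p <= 0.05
        assert strat.n_high + strat.n_low == strat.scores.shape[0]
        assert strat.adjusted_p >= 1 / 101

    def test_same_seed_reproduces(self, survival_clinical):
        a = sv.loocv_stratify(survival_clinical, ["megs", "age"],
                              n_perm=30, seed=5)
        b = sv.loocv_stratify(survival_clinical, ["megs", "age"],
                              n_perm=30, seed=5)
        assert a.adjusted_p == b.adjusted_p
        assert a.cutoff == b.cutoff

    def test_no_permutations_warns_and_leaves_p_unset(self, survival_clinical):
        with pytest.warns(UserWarning, match="n_perm=0"):
            strat = sv.loocv_stratify(survival_clinical, ["megs"],
                                      n_perm=0, seed=None)
        assert strat.adjusted_p is None

    def test_group_assignment_consistent_with_cutoff(self, survival_clinical):
        strat = sv.loocv_stratify(survival_clinical, ["megs", "age"],
                                  n_perm=0, seed=None)
        assert np.array_equal(strat.group,
                              (strat.scores > strat.cutoff).astype(int))


class TestMegsProfile:
    def test_any_member_mutation_counts(self):
        mat = AlterationMatrix(
            ["P1", "P2", "P3"], ["CDK4(A)", "CDKN2A(D)", "RB1"],
            np.array([[0, 1, 0], [0, 0, 0], [1, 0, 1]], dtype=np.int8))
        prof = sv.megs_profile(mat, ["CDK4(A)", "CDKN2A(D)", "RB1"])
        assert prof.tolist() == [1, 0, 1]

    def test_profile_sum_equals_coverage_times_n(self, planted_matrix):
        from megsurv.search import coverage
        prof = sv.megs_profile(planted_matrix, ["A", "B", "C"])
        cov = coverage(planted_matrix, ["A", "B", "C"])
        assert prof.sum() == pytest.approx(cov * planted_matrix.n_patients)

    def test_unknown_gene_errors(self, planted_matrix):
        with pytest.raises(KeyError):
            sv.megs_profile(planted_matrix, ["A", "NOPE"])
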