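"""Unit and oracle tests for the survival core.

Independent oracles: hand computations for the KM/log-rank worked
examples, a grid-search partial-likelihood maximizer for Cox, brute-force
enumeration for the cutoff scan, and lifelines as an external
cross-check implementation.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from senosurv.survival import (
    ConvergenceError,
    bh_adjust,
    cox_score_test,
    fit_cox,
    km_estimate,
    logrank_test,
    scan_cutoffs,
    two_variable_cox,
)

from conftest import random_survival


# ----------------------------------------------------------------------
# Kaplan–Meier
# ----------------------------------------------------------------------
class TestKaplanMeier:
    def test_no_censoring_matches_empirical_survival(self):
        times = np.array([1.0, 2.0, 3.0])
        km = km_estimate(times, [1, 1, 1])
        assert np.allclose(km["survival"], [1.0, 2 / 3, 1 / 3, 0.0])
        assert np.allclose(km["time"], [0.0, 1.0, 2.0, 3.0])

    def test_no_events_survival_stays_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_hand_product_limit_with_censoring(self):
        # risk sets 3,2,1; censored subject only shrinks the risk set
        km = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        s = km.set_index("time")["survival"]
        assert s[1.0] == pytest.approx(2 / 3)
        assert s[3.0] == pytest.approx(0.0)
        assert 2.0 not in s.index  # censored-only time adds no step

    def test_equals_one_minus_ecdf_without_censoring(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(10, 200)
        km = km_estimate(times, np.ones(200, int))
        ecdf = np.searchsorted(np.sort(times), km["time"], side="right") / 200
        assert np.allclose(km["survival"], 1 - ecdf)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])

    def test_lifelines_cross_check(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(7)
        times, events = random_survival(rng, 150)
        times = np.round(times) + 1  # force ties
        km = km_estimate(times, events).set_index("time")["survival"]
        ref = KaplanMeierFitter().fit(times, events).survival_function_["KM_estimate"]
        common = km.index.intersection(ref.index)
        assert len(common) > 10
        assert np.allclose(km[common], ref[common])


# ----------------------------------------------------------------------
# Log-rank
# ----------------------------------------------------------------------
class TestLogrank:
    def test_identical_groups_give_null(self):
        times = np.array([1.0, 2, 3, 1, 2, 3])
        events = np.array([1, 1, 0, 1, 1, 0])
        group = np.array([0, 0, 0, 1, 1, 1], bool)
        r = logrank_test(times, events, group)
        assert r.chi2 == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_hand_computed_four_subject_example(self):
        # group A dies at 1,2; group B at 3,4: O_A=2, E_A=5/6, V=17/36
        r = logrank_test([1.0, 2, 3, 4], [1, 1, 1, 1], [1, 1, 0, 0])
        assert r.observed == pytest.approx(2.0)
        assert r.expected == pytest.approx(5 / 6)
        assert r.variance == pytest.approx(17 / 36)
        assert r.chi2 == pytest.approx(49 / 17, abs=1e-12)

    def test_doubling_subjects_increases_chi2(self):
        times = np.array([1.0, 2, 3, 4, 5, 6])
        events = np.ones(6, int)
        group = np.array([1, 1, 1, 0, 0, 0], bool)
        base = logrank_test(times, events, group).chi2
        doubled = logrank_test(
            np.tile(times, 2), np.tile(events, 2), np.tile(group, 2)
        ).chi2
        assert doubled > base

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [1, 1], [1, 1])

    def test_matches_lifelines_with_ties(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(3)
        for _ in range(5):
            times, events = random_survival(rng, 80)
            times = np.ceil(times)
            group = rng.integers(0, 2, 80).astype(bool)
            mine = logrank_test(times, events, group)
            ref = ll_logrank(times[group], times[~group], events[group], events[~group])
            assert mine.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
            assert mine.p == pytest.approx(ref.p_value, rel=1e-9)

    def test_equals_cox_score_test_on_untied_data(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            n = 60
            times = rng.exponential(5, n)  # continuous, untied a.s.
            events = rng.integers(0, 2, n)
            events[:5] = 1
            group = rng.integers(0, 2, n)
            stat, _ = cox_score_test(group.astype(float), times, events)
            assert stat == pytest.approx(
                logrank_test(times, events, group.astype(bool)).chi2, abs=1e-6
            )


# ----------------------------------------------------------------------
# Cox PH
# ----------------------------------------------------------------------
def grid_search_partial_likelihood(x, times, events, lo=-5.0, hi=5.0, num=500_001):
    """Brute-force maximizer of the untied Cox partial likelihood."""
    order = np.argsort(times)
    x, events = np.asarray(x, float)[order], np.asarray(events)[order]
    betas = np.linspace(lo, hi, num)
    ll = np.zeros_like(betas)
    exb = np.exp(np.outer(betas, x))  # (B, n)
    for i in range(len(x)):
        if events[i]:
            ll += betas * x[i] - np.log(exb[:, i:].sum(axis=1))
    return betas[np.argmax(ll)]


class TestCox:
    def test_exchangeable_groups_give_hr_one(self):
        times = np.array([1.0, 2, 3, 1, 2, 3])
        events = np.array([1, 1, 1, 1, 1, 1])
        x = np.array([0.0, 0, 0, 1, 1, 1])
        fit = fit_cox(x, times, events)
        assert fit.table["coef"].iloc[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.table["hr"].iloc[0] == pytest.approx(1.0, abs=1e-8)

    def test_four_subject_toy_matches_grid_search(self):
        times = np.array([1.0, 2, 3, 4])
        events = np.array([1, 1, 1, 1])
        x = np.array([1.0, 0, 1, 0])
        fit = fit_cox(x, times, events)
        beta_grid = grid_search_partial_likelihood(x, times, events)
        assert fit.table["coef"].iloc[0] == pytest.approx(beta_grid, abs=1e-4)

    def test_replication_preserves_beta_and_scales_se(self):
        # exact under Breslow ties: doubled risk sets shift each event's
        # log-denominator by log 2, leaving the score equations unchanged
        rng = np.random.default_rng(12)
        n = 80
        x = rng.standard_normal(n)
        times = rng.exponential(10 / np.exp(0.5 * x))
        events = np.ones(n, int)
        fit1 = fit_cox(x, times, events, ties="breslow")
        fit2 = fit_cox(
            np.tile(x, 2), np.tile(times, 2), np.tile(events, 2), ties="breslow"
        )
        assert fit2.table["coef"].iloc[0] == pytest.approx(
            fit1.table["coef"].iloc[0], abs=1e-6
        )
        assert fit2.table["se"].iloc[0] == pytest.approx(
            fit1.table["se"].iloc[0] / np.sqrt(2), rel=1e-6
        )

    def test_matches_lifelines_multivariate_with_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(1)
        n = 150
        X = rng.standard_normal((n, 3))
        times = np.round(rng.exponential(10 / np.exp(X @ [0.5, -0.3, 0.2]))) + 1
        events = rng.integers(0, 2, n)
        events[:10] = 1
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        fit = fit_cox(df, times, events)
        df2 = df.assign(t=times, e=events)
        ref = CoxPHFitter().fit(df2, "t", "e")
        assert np.allclose(fit.params.to_numpy(), ref.params_.to_numpy(), atol=1e-4)
        assert fit.loglik == pytest.approx(ref.log_likelihood_, abs=1e-6)

    def test_wald_interval_brackets_hr(self):
        rng = np.random.default_rng(2)
        times, events = random_survival(rng, 100)
        x = rng.standard_normal(100)
        fit = fit_cox(x, times, events)
        row = fit.table.iloc[0]
        assert row["ci_low"] <= row["hr"] <= row["ci_high"]
        assert row["hr"] > 0

    def test_constant_covariate_rejected_by_name(self):
        with pytest.raises(ValueError, match="flat"):
            fit_cox(
                pd.DataFrame({"flat": [1.0, 1, 1, 1]}),
                [1.0, 2, 3, 4],
                [1, 1, 1, 1],
            )

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            fit_cox([1.0, 0, 1], [1.0, 2, 3], [0, 0, 0])

    def test_perfect_separation_is_flagged_not_silent(self):
        # all treated subjects outlive all controls: monotone likelihood
        times = np.array([1.0, 2, 3, 4, 10, 11, 12, 13])
        events = np.ones(8, int)
        x = np.array([0.0, 0, 0, 0, 1, 1, 1, 1])
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_cox(x, times, events)
        assert fit.flags.get("monotone_likelihood")


# ----------------------------------------------------------------------
# Cutoff scan
# ----------------------------------------------------------------------
def enumerate_best_cutoff(score, times, events, window=(0.25, 0.75), min_group=1):
    """Brute-force oracle: every distinct score value inside the quantile
    window, scored with lifelines' log-rank."""
    from lifelines.statistics import logrank_test as ll_logrank

    score = np.asarray(score, float)
    q_lo, q_hi = np.quantile(score, window)
    best = None
    for v in np.unique(score):
        high = score > v
        if not (q_lo <= v <= q_hi):
            continue
        if high.sum() < min_group or (~high).sum() < min_group:
            continue
        p = ll_logrank(
            times[high], times[~high], events[high], events[~high]
        ).p_value
        if best is None or p < best[1] - 1e-15:
            best = (v, p)
    return best


class TestCutoffScan:
    def test_toy_matches_exhaustive_enumeration(self):
        times = np.array([5.0, 1, 6, 2, 7, 3, 8, 4])
        events = np.ones(8, int)
        score = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        res = scan_cutoffs(score, times, events, min_group=1)
        cut, p = enumerate_best_cutoff(score, times, events, min_group=1)
        assert res.cutoff == pytest.approx(cut)
        assert res.p_selected == pytest.approx(p, rel=1e-9)

    def test_selected_p_is_minimum_over_candidates(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            n = 40
            times, events = random_survival(rng, n)
            score = rng.standard_normal(n)
            res = scan_cutoffs(score, times, events, min_group=3)
            assert res.p_selected == res.pvalues.min()
            assert (res.pvalues >= res.p_selected).all()

    def test_candidates_lie_in_iqr_window(self):
        rng = np.random.default_rng(4)
        score = rng.standard_normal(200)
        times, events = random_survival(rng, 200)
        res = scan_cutoffs(score, times, events)
        q1, q3 = np.quantile(score, [0.25, 0.75])
        assert res.candidates.min() >= q1 - 1e-9
        assert res.candidates.max() <= q3 + 1e-9
        # every candidate leaves both groups populated
        for v in res.candidates:
            assert (score > v).sum() >= 5 and (score <= v).sum() >= 5

    def test_perfectly_separated_cohort(self):
        # low scorers all die before any high scorer's event
        score = np.array([0.0, 0.1, 0.2, 0.3, 0.35, 1.0, 1.1, 1.2, 1.3, 1.35])
        times = np.array([1.0, 1, 1, 1, 1, 10, 10, 10, 10, 10])
        events = np.ones(10, int)
        with pytest.warns(UserWarning):  # perfect separation is flagged
            res = scan_cutoffs(score, times, events, min_group=2)
        assert 0.35 <= res.cutoff < 1.0  # between the two score clusters
        assert res.hazard_ratio < 1.0
        assert res.cox.flags.get("monotone_likelihood")

    def test_too_few_candidates_rejected(self):
        with pytest.raises(ValueError):
            scan_cutoffs(
                np.ones(20), np.arange(1.0, 21), np.ones(20, int), min_group=2
            )

    def test_null_selection_inflation_and_permutation_fix(self):
        """Min-p selection inflates type-I error; permutation adjusts it."""
        rng = np.random.default_rng(99)
        n, reps = 60, 120
        raw_hits = perm_hits = 0
        for i in range(reps):
            times, events = random_survival(rng, n)
            score = rng.standard_normal(n)  # independent of survival
            res = scan_cutoffs(
                score, times, events, min_group=5, n_permutations=99, seed=1000 + i
            )
            raw_hits += res.p_selected < 0.05
            perm_hits += res.p_permutation < 0.05
        assert raw_hits / reps > 0.12  # far above the nominal 5%
        assert perm_hits / reps < 0.12  # permutation restores calibration
        assert "minimum over" in res.multiplicity_note


# ----------------------------------------------------------------------
# Benjamini–Hochberg
# ----------------------------------------------------------------------
class TestBH:
    def test_single_p_unchanged(self):
        r = bh_adjust([0.03])
        assert r.qvalues[0] == pytest.approx(0.03)

    def test_step_up_worked_example(self):
        r = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(r.qvalues, [0.04, 0.04, 0.04, 0.04])

    def test_default_threshold_is_ten_percent(self):
        r = bh_adjust([0.01, 0.5])
        assert r.fdr == 0.10
        assert list(r.significant) == [True, False]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    def test_monotone_and_permutation_invariant(self, pvals):
        p = np.array(pvals)
        q = bh_adjust(p).qvalues
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()  # monotone in sorted-p order
        perm = np.random.default_rng(0).permutation(len(p))
        q_perm = bh_adjust(p[perm]).qvalues
        assert np.allclose(np.sort(q_perm), np.sort(q))
        assert (q >= p - 1e-12).all() and (q <= 1 + 1e-12).all()


# ----------------------------------------------------------------------
# Two-variable adjusted models
# ----------------------------------------------------------------------
class TestTwoVariableCox:
    def _cohort(self, rng, n=400, confounded=False):
        cov = rng.integers(0, 2, n).astype(float)
        if confounded:
            # covariate drives both the score and the hazard; the score
            # itself has no direct effect on survival
            score = rng.standard_normal(n) + 1.2 * cov
            hazard = 0.1 * np.exp(0.9 * cov)
        else:
            score = rng.standard_normal(n)
            hazard = 0.1 * np.exp(-0.8 * score)
        t_event = rng.exponential(1 / hazard)
        t_cens = rng.exponential(30, n)
        times = np.minimum(t_event, t_cens)
        events = (t_event <= t_cens).astype(int)
        return score, cov, times, events

    def test_independent_covariate_leaves_score_hr(self):
        rng = np.random.default_rng(30)
        score, cov, times, events = self._cohort(rng)
        uni = fit_cox(score, times, events).table.iloc[0]["hr"]
        adj = two_variable_cox(score, cov, times, events).table.iloc[0]["hr"]
        assert adj == pytest.approx(uni, rel=0.05)

    def test_planted_confounder_attenuates_toward_one(self):
        rng = np.random.default_rng(31)
        score, cov, times, events = self._cohort(rng, confounded=True)
        uni = fit_cox(score, times, events).table.iloc[0]["coef"]
        adj = two_variable_cox(score, cov, times, events).table.iloc[0]["coef"]
        assert abs(adj) < abs(uni)  # adjusted effect pulled toward 0

    def test_complete_cases_and_missing_handling(self):
        rng = np.random.default_rng(32)
        score, _, times, events = self._cohort(rng, n=100)
        cov = pd.Series(["a"] * 40 + ["b"] * 40 + ["missing"] * 20)
        fit = two_variable_cox(score, cov, times, events)
        assert fit.n == 80  # missing rows excluded per model
        assert fit.table.index[0] == "signature"

    def test_determinism(self):
        rng = np.random.default_rng(33)
        score, cov, times, events = self._cohort(rng, n=120)
        f1 = two_variable_cox(score, cov, times, events)
        f2 = two_variable_cox(score, cov, times, events)
        pd.testing.assert_frame_equal(f1.table, f2.table)

    def test_all_missing_covariate_rejected(self):
        with pytest.raises(ValueError):
            two_variable_cox(
                np.arange(4.0), pd.Series(["missing"] * 4), [1.0, 2, 3, 4], [1, 1, 1, 1]
            )
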