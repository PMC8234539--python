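import numpy as np
import pytest
from scipy import stats

from oracles import (brute_cox_loglik, brute_logrank_2group, brute_time_auc,
                     exact_wilcoxon_p)
from radsurv import survstats
from radsurv.survstats import (calibration_3yr, cindex_ci, compare_cindex,
                               decision_curve, fit_cox, idi_nri,
                               kaplan_meier, km_prob_at, log_rank,
                               risk_to_prob, time_roc, wilcoxon_signed_rank)


class TestKaplanMeier:
    def test_no_censoring_matches_empirical(self, rng):
        t = rng.uniform(1, 10, 50)
        km = kaplan_meier(t, np.ones(50, int))
        for u in [2.0, 5.0, 8.0]:
            assert km_prob_at(km, u) == pytest.approx((t > u).mean())

    def test_hand_product_limit(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [1, 0, 1])
        assert km_prob_at(km, 1.5) == pytest.approx(2 / 3)
        assert km_prob_at(km, 3.0) == pytest.approx(0.0)

    def test_all_censored_is_one(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [0, 0, 0])
        assert np.all(km.survival == 1.0)

    def test_monotone_and_greenwood_nonnegative(self, rng):
        t = rng.uniform(1, 30, 80)
        e = rng.integers(0, 2, 80)
        e[0] = 1
        km = kaplan_meier(t, e)
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert np.all(km.variance >= 0)
        assert km_prob_at(km, 0.0) == 1.0

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.uniform(1, 30, 120)
        e = rng.integers(0, 2, 120)
        e[:3] = 1
        km = kaplan_meier(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ours = km.survival
        theirs = kmf.survival_function_at_times(km.times).to_numpy()
        np.testing.assert_allclose(ours, theirs, atol=1e-12)


class TestLogRank:
    def test_identical_groups_zero(self, rng):
        t = rng.uniform(1, 10, 30)
        e = rng.integers(0, 2, 30)
        e[0] = 1
        time = np.concatenate([t, t])
        event = np.concatenate([e, e])
        group = np.repeat([0, 1], 30)
        chi2, df, p = log_rank(time, event, group)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert df == 1

    def test_four_patient_hand_table(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 1, 0])
        group = np.array([0, 1, 0, 1])
        chi2, _, _ = log_rank(time, event, group)
        expected = brute_logrank_2group(time, event, group)
        assert chi2 == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_on_random(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 40))
            time = rng.uniform(1, 20, n)
            event = rng.integers(0, 2, n)
            group = rng.integers(0, 2, n)
            if event.sum() == 0 or len(np.unique(group)) < 2:
                continue
            chi2, _, _ = log_rank(time, event, group)
            assert chi2 == pytest.approx(
                brute_logrank_2group(time, event, group), abs=1e-10)

    def test_three_groups_df(self, rng):
        t = rng.uniform(1, 10, 60)
        e = np.ones(60, int)
        g = rng.integers(0, 3, 60)
        _, df, p = log_rank(t, e, g)
        assert df == 2
        assert 0 <= p <= 1


class TestCindexCI:
    def test_perfect_score_collapses(self):
        t = np.arange(1.0, 21.0)
        e = np.ones(20, int)
        c, lo, hi = cindex_ci(-t, t, e, n_boot=100, seed=1)
        assert c == 1.0 and lo == 1.0 and hi == 1.0

    def test_wider_ci_at_smaller_n(self):
        rng = np.random.default_rng(5)
        eta = rng.normal(size=368)
        t = rng.exponential(np.exp(-eta))
        e = np.ones(368, int)
        c1, lo1, hi1 = cindex_ci(eta, t, e, n_boot=300, seed=2)
        idx = rng.choice(368, 34, replace=False)
        c2, lo2, hi2 = cindex_ci(eta[idx], t[idx], e[idx], n_boot=300, seed=2)
        assert (hi2 - lo2) > (hi1 - lo1)


class TestCompareCindex:
    def test_self_comparison_is_one(self, rng):
        t = rng.uniform(1, 10, 50)
        e = np.ones(50, int)
        s = rng.normal(size=50)
        assert compare_cindex(s, s, t, e) == 1.0

    def test_signal_vs_noise_significant(self):
        rng = np.random.default_rng(9)
        n = 400
        eta = rng.normal(size=n)
        t = rng.exponential(np.exp(-2 * eta))
        e = np.ones(n, int)
        noise = rng.normal(size=n)
        assert compare_cindex(eta, noise, t, e) < 0.01


class TestTimeROC:
    def test_no_censoring_equals_plain_roc(self, rng):
        n = 80
        s = rng.normal(size=n)
        t = rng.uniform(1, 10, n)
        e = np.ones(n, int)
        horizon = float(np.median(t))
        roc = time_roc(s, t, e, horizon)
        y = (t <= horizon).astype(int)
        # plain Mann-Whitney AUC
        pos, neg = s[y == 1], s[y == 0]
        auc = ((pos[:, None] > neg[None, :]).sum()
               + 0.5 * (pos[:, None] == neg[None, :]).sum()) / (
                   len(pos) * len(neg))
        assert roc.auc == pytest.approx(auc, abs=1e-12)

    def test_matches_brute_oracle_with_censoring(self, rng):
        n = 60
        s = rng.normal(size=n)
        t = rng.uniform(1, 40, n)
        e = rng.integers(0, 2, n)
        e[:5] = 1
        roc = time_roc(s, t, e, 20.0)
        assert roc.auc == pytest.approx(
            brute_time_auc(s, t, e, 20.0), abs=1e-10)

    def test_antisymmetry(self, rng):
        n = 50
        s = rng.normal(size=n)
        t = rng.uniform(1, 10, n)
        e = np.ones(n, int)
        a1 = time_roc(s, t, e, 5.0).auc
        a2 = time_roc(-s, t, e, 5.0).auc
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_horizon_beyond_data_errors(self, rng):
        t = rng.uniform(1, 10, 20)
        with pytest.raises(ValueError, match="horizon"):
            time_roc(rng.normal(size=20), t, np.ones(20, int), 99.0)

    def test_youden_cutoff_maximizes(self, rng):
        n = 100
        s = rng.normal(size=n)
        t = rng.uniform(1, 10, n)
        e = np.ones(n, int)
        roc = time_roc(s, t, e, 5.0)
        j = roc.sensitivity + roc.specificity - 1.0
        best = roc.cutoffs[np.argmax(j)]
        assert roc.youden_cutoff == best


class TestCalibration:
    def test_constant_prediction_errors(self, rng):
        t = rng.uniform(1, 10, 50)
        e = np.ones(50, int)
        with pytest.raises(ValueError, match="group"):
            calibration_3yr(np.full(50, 0.3), t, e, horizon=5.0)

    def test_probabilities_out_of_range_error(self, rng):
        t = rng.uniform(1, 10, 20)
        with pytest.raises(ValueError):
            calibration_3yr(np.linspace(-0.1, 0.5, 20), t,
                            np.ones(20, int), horizon=5.0)

    def test_calibrated_model_not_rejected(self):
        rng = np.random.default_rng(17)
        n = 800
        eta = rng.normal(size=n)
        rate = 0.02 * np.exp(eta)
        t = rng.exponential(1.0 / rate)
        e = np.ones(n, int)
        prob = 1.0 - np.exp(-36.0 * rate)
        _, chi2, p = calibration_3yr(prob, t, e, horizon=36.0)
        assert p > 0.01

    def test_miscalibrated_model_rejected(self):
        rng = np.random.default_rng(18)
        n = 1000
        rate = 0.02 * np.exp(rng.normal(size=n))
        t = rng.exponential(1.0 / rate)
        prob = np.clip(2.0 * (1.0 - np.exp(-36.0 * rate)), 0, 1)
        _, _, p = calibration_3yr(prob, t, np.ones(n, int), horizon=36.0)
        assert p < 0.05


class TestRiskToProb:
    def test_in_unit_interval(self, rng):
        n = 100
        s = rng.normal(size=n)
        t = rng.uniform(1, 50, n)
        e = rng.integers(0, 2, n)
        e[0] = 1
        p = risk_to_prob(s, t, e, 20.0)
        assert np.all((p >= 0) & (p <= 1))

    def test_constant_score_equals_km_complement(self, rng):
        n = 120
        t = rng.uniform(1, 50, n)
        e = rng.integers(0, 2, n)
        e[0] = 1
        p = risk_to_prob(np.zeros(n), t, e, 25.0)
        km = kaplan_meier(t, e)
        # Breslow baseline with beta=0 is the Nelson-Aalen analogue of KM
        expected = 1.0 - km_prob_at(km, 25.0)
        assert np.ptp(p) == 0
        assert p[0] == pytest.approx(expected, abs=0.02)

    def test_agrees_with_exponential_closed_form(self):
        rng = np.random.default_rng(77)
        n = 4000
        eta = 0.7 * rng.normal(size=n)
        t = rng.exponential(np.exp(-eta) / 0.03)
        e = np.ones(n, int)
        p = risk_to_prob(eta, t, e, 30.0)
        truth = 1.0 - np.exp(-0.03 * 30.0 * np.exp(eta))
        assert np.abs(p - truth).mean() < 0.02


class TestDecisionCurve:
    def test_treat_none_zero(self, rng):
        t = rng.uniform(1, 50, 60)
        e = np.ones(60, int)
        dca = decision_curve(rng.uniform(size=60), t, e, 20.0,
                             [0.1, 0.3, 0.5])
        assert np.all(dca["treat_none"] == 0.0)

    def test_treat_all_closed_form(self, rng):
        n = 100
        t = rng.uniform(1, 50, n)
        e = np.ones(n, int)
        horizon = 20.0
        rate = (t <= horizon).mean()  # no censoring: KM = empirical
        thr = np.array([0.1, 0.25, 0.4])
        dca = decision_curve(rng.uniform(size=n), t, e, horizon, thr)
        expected = rate - (1 - rate) * thr / (1 - thr)
        np.testing.assert_allclose(dca["treat_all"], expected, atol=1e-12)

    def test_perfect_predictor_net_benefit(self):
        # events all before horizon with prob 1, others prob 0
        t = np.array([5.0] * 30 + [50.0] * 70)
        e = np.array([1] * 30 + [0] * 70)
        prob = np.array([1.0] * 30 + [0.0] * 70)
        thr = np.array([0.1, 0.3, 0.5, 0.8])
        dca = decision_curve(prob, t, e, 20.0, thr)
        np.testing.assert_allclose(dca["net_benefit"], 0.3, atol=1e-12)


class TestIdiNri:
    def test_identical_models_zero(self, rng):
        n = 80
        t = rng.uniform(1, 50, n)
        e = np.ones(n, int)
        p = rng.uniform(size=n)
        res = idi_nri(p, p, t, e, 20.0, n_boot=50, seed=0)
        assert res["idi"] == 0.0 and res["nri"] == 0.0
        assert res["idi_p"] == 1.0 and res["nri_p"] == 1.0

    def test_antisymmetry(self, rng):
        n = 80
        t = rng.uniform(1, 50, n)
        e = rng.integers(0, 2, n)
        e[:5] = 1
        pa = rng.uniform(size=n)
        pb = rng.uniform(size=n)
        r1 = idi_nri(pa, pb, t, e, 20.0, n_boot=10, seed=0)
        r2 = idi_nri(pb, pa, t, e, 20.0, n_boot=10, seed=0)
        assert r1["idi"] == pytest.approx(-r2["idi"], abs=1e-12)
        assert r1["nri"] == pytest.approx(-r2["nri"], abs=1e-12)

    def test_truth_beats_noise(self):
        rng = np.random.default_rng(23)
        n = 500
        eta = rng.normal(size=n)
        rate = 0.03 * np.exp(eta)
        t = rng.exponential(1.0 / rate)
        e = np.ones(n, int)
        p_true = 1.0 - np.exp(-20.0 * rate)
        p_noise = rng.uniform(size=n)
        res = idi_nri(p_true, p_noise, t, e, 20.0, n_boot=200, seed=1)
        assert res["idi"] > 0 and res["nri"] > 0
        assert res["idi_p"] < 0.01 and res["nri_p"] < 0.01


class TestFitCox:
    def test_matches_lifelines(self, rng):
        from lifelines import CoxPHFitter
        import pandas as pd

        n = 150
        X = rng.normal(size=(n, 3))
        eta = X @ np.array([0.5, -0.4, 0.0])
        t = rng.exponential(np.exp(-eta))
        e = rng.integers(0, 2, n)
        e[:5] = 1
        fit = fit_cox(X, t, e)
        df = pd.DataFrame(X, columns=list("abc"))
        df["T"], df["E"] = t, e
        cph = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(fit.coef, cph.params_.to_numpy(),
                                   atol=1e-5)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.to_numpy(),
                                   atol=1e-5)

    def test_binary_covariate_vs_likelihood_grid(self):
        time = np.array([2.0, 4.0, 6.0, 8.0])
        event = np.array([1, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        fit = fit_cox(x[:, None], time, event)
        grid = np.linspace(-4, 4, 20001)
        lls = [brute_cox_loglik(b, x, time, event) for b in grid]
        beta_grid = grid[int(np.argmax(lls))]
        assert fit.coef[0] == pytest.approx(beta_grid, abs=5e-4)
        assert fit.log_likelihood == pytest.approx(max(lls), abs=1e-6)

    def test_null_covariate(self, rng):
        n = 300
        x = rng.normal(size=n)
        t = rng.exponential(size=n)
        fit = fit_cox(x[:, None], t, np.ones(n, int))
        assert abs(np.log(fit.hr[0])) < 0.25
        assert fit.ci_low[0] < fit.hr[0] < fit.ci_high[0]

    def test_separation_warns(self):
        # perfectly separating covariate -> monotone likelihood
        t = np.arange(1.0, 11.0)
        e = np.ones(10, int)
        x = -t  # larger x = strictly earlier failure
        with pytest.warns(UserWarning):
            fit = fit_cox(x[:, None], t, e, max_iter=200)
        assert np.isfinite(fit.coef[0])

    def test_zero_events_error(self):
        with pytest.raises(ValueError):
            fit_cox(np.ones((5, 1)), np.arange(1.0, 6.0), np.zeros(5, int))


class TestWilcoxon:
    def test_identical_vectors(self):
        a = np.array([1.0, 2.0, 3.0])
        assert wilcoxon_signed_rank(a, a) == 1.0

    def test_exact_enumeration_n6(self):
        a = np.array([3.1, 4.5, 2.2, 6.8, 1.0, 5.45])
        b = np.array([2.0, 5.1, 1.3, 4.0, 1.5, 5.0])
        p = wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(exact_wilcoxon_p(a - b), abs=1e-12)

    def test_shifted_pairs_minimal_p(self):
        rng = np.random.default_rng(2)
        b = rng.normal(size=8)
        # distinct magnitudes, all positive differences
        a = b + np.linspace(1.0, 2.0, 8)
        p = wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(2 / 2**8, abs=1e-12)


class TestProperties:
    def test_c_plus_c_negated_is_one(self, rng):
        from radsurv.screening import harrell_cindex

        for _ in range(10):
            n = int(rng.integers(10, 40))
            s = rng.normal(size=n)  # continuous: no ties a.s.
            t = rng.uniform(1, 10, n)
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                e[0] = 1
            try:
                c1 = harrell_cindex(s, t, e)
            except ValueError:
                continue
            c2 = harrell_cindex(-s, t, e)
            assert c1 + c2 == pytest.approx(1.0, abs=1e-12)

    def test_c_monotone_invariance(self, rng):
        from radsurv.screening import harrell_cindex

        n = 40
        s = rng.normal(size=n)
        t = rng.uniform(1, 10, n)
        e = np.ones(n, int)
        c1 = harrell_cindex(s, t, e)
        c2 = harrell_cindex(np.exp(2 * s) + 5, t, e)
        assert c1 == pytest.approx(c2, abs=1e-12)

    def test_auc_equals_c_on_two_valued_times(self, rng):
        # all events observed, times two-valued, horizon between them:
        # the only usable C pairs are exactly the case/control pairs,
        # so Harrell's C and AUC(t*) coincide
        n = 60
        s = rng.normal(size=n)
        t = np.where(rng.uniform(size=n) < 0.5, 5.0, 50.0)
        e = np.ones(n, int)
        from radsurv.screening import harrell_cindex

        auc = time_roc(s, t, e, 20.0).auc
        c = harrell_cindex(s, t, e)
        assert c == pytest.approx(auc, abs=1e-12)
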