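import numpy as np
import pytest

from cortmed.regression import (
    CoxProblem,
    FitError,
    SeparationError,
    cox_partial_loglik,
    fit_cox,
    fit_logistic,
    wald_summary,
)


def _two_by_two(a, b, c, d):
    """Design/outcome for a saturated 2x2 table: a=(x1,y1), b=(x1,y0), c=(x0,y1), d=(x0,y0)."""
    x = np.r_[np.ones(a + b), np.zeros(c + d)]
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    X = np.column_stack([np.ones_like(x), x])
    return X, y


class TestLogistic:
    def test_saturated_2x2_log_odds_ratio(self):
        X, y = _two_by_two(10, 5, 5, 10)
        fit = fit_logistic(X, y, ["intercept", "x"])
        assert fit.coef[1] == pytest.approx(np.log(4.0), abs=1e-8)

    @pytest.mark.parametrize("a,b,c,d", [(3, 7, 9, 1), (12, 4, 6, 8), (2, 2, 5, 9)])
    def test_any_saturated_2x2_matches_closed_form(self, a, b, c, d):
        X, y = _two_by_two(a, b, c, d)
        fit = fit_logistic(X, y)
        assert fit.coef[1] == pytest.approx(np.log(a * d / (b * c)), abs=1e-8)

    def test_intercept_only_half_ones(self):
        X = np.ones((40, 1))
        y = np.r_[np.ones(20), np.zeros(20)]
        fit = fit_logistic(X, y)
        assert fit.coef[0] == pytest.approx(0.0, abs=1e-10)

    def test_matches_statsmodels_on_random_design(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(200), rng.normal(size=(200, 3))])
        beta_true = np.array([-0.3, 0.8, -0.5, 0.2])
        p = 1 / (1 + np.exp(-X @ beta_true))
        y = (rng.random(200) < p).astype(float)
        fit = fit_logistic(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse, atol=1e-6)

    def test_score_at_mle_is_tiny(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(150), rng.normal(size=150)])
        y = (rng.random(150) < 0.4).astype(float)
        fit = fit_logistic(X, y)
        from cortmed.regression import logistic_loglik

        _, score = logistic_loglik(fit.coef, X, y, grad=True)
        assert np.max(np.abs(score)) < 1e-6

    def test_complete_separation_detected(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = x.copy()
        X = np.column_stack([np.ones_like(x), x])
        with pytest.raises(SeparationError):
            fit_logistic(X, y)

    def test_single_class_outcome_rejected(self):
        X = np.ones((10, 1))
        with pytest.raises(FitError):
            fit_logistic(X, np.ones(10))


class TestCoxOracle:
    def _grid_max(self, time, event, X, ties="efron"):
        """Two-stage brute-force maximizer of the partial likelihood."""
        grid = np.linspace(-5, 5, 4001)
        lls = [cox_partial_loglik(np.array([b]), time, event, X, ties) for b in grid]
        center = grid[int(np.argmax(lls))]
        fine = np.linspace(center - 0.005, center + 0.005, 2001)
        lls = [cox_partial_loglik(np.array([b]), time, event, X, ties) for b in fine]
        return fine[int(np.argmax(lls))]

    def test_four_subject_example_matches_grid_search(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 1, 1])
        X = np.array([[1.0], [0.0], [1.0], [0.0]])
        fit = fit_cox(time, event, X)
        assert fit.coef[0] == pytest.approx(self._grid_max(time, event, X), abs=1e-4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_small_datasets_match_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        time = rng.uniform(0.5, 10, n)
        event = rng.integers(0, 2, n)
        event[0] = 1
        X = rng.integers(0, 2, (n, 1)).astype(float)
        if np.ptp(X) == 0:
            X[0, 0] = 1 - X[0, 0]
        try:
            fit = fit_cox(time, event, X)
        except SeparationError:
            return  # monotone likelihood: grid check not applicable
        if abs(fit.coef[0]) > 4.5:
            return  # no interior maximizer within the oracle grid
        assert fit.coef[0] == pytest.approx(self._grid_max(time, event, X), abs=1e-4)

    def test_loglik_at_zero_is_minus_log_risk_set_sizes(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        event = np.array([1, 0, 1, 1, 0])
        X = np.array([[0.2], [1.0], [-0.3], [0.5], [0.1]])
        ll = cox_partial_loglik(np.zeros(1), time, event, X)
        # risk set sizes at event times 1, 3, 4 are 5, 3, 2
        assert ll == pytest.approx(-(np.log(5) + np.log(3) + np.log(2)))

    def test_mle_beats_grid(self):
        rng = np.random.default_rng(9)
        time = rng.uniform(1, 20, 30)
        event = rng.integers(0, 2, 30)
        event[:3] = 1
        X = rng.normal(size=(30, 1))
        fit = fit_cox(time, event, X)
        ll_hat = cox_partial_loglik(fit.coef, time, event, X)
        for b in np.linspace(-3, 3, 61):
            assert ll_hat >= cox_partial_loglik(np.array([b]), time, event, X) - 1e-9


class TestCoxTies:
    def _tied_data(self):
        time = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        event = np.array([1, 1, 0, 1, 1, 0, 1, 0])
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 2))
        return time, event, X

    def test_breslow_equals_efron_without_ties(self):
        rng = np.random.default_rng(1)
        time = np.arange(1.0, 13.0)
        event = rng.integers(0, 2, 12)
        event[0] = 1
        X = rng.normal(size=(12, 2))
        b = rng.normal(size=2) * 0.5
        assert cox_partial_loglik(b, time, event, X, "efron") == pytest.approx(
            cox_partial_loglik(b, time, event, X, "breslow"), abs=1e-12
        )

    def test_efron_geq_breslow_at_mle_with_ties(self):
        time, event, X = self._tied_data()
        fe = fit_cox(time, event, X, ties="efron")
        fb = fit_cox(time, event, X, ties="breslow")
        assert fe.loglik >= fb.loglik

    def test_matches_lifelines_with_ties(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(7)
        n = 200
        X = np.column_stack([rng.integers(0, 2, n), rng.normal(size=n)])
        lam = 0.05 * np.exp(0.7 * X[:, 0] - 0.3 * X[:, 1])
        time = np.ceil(rng.exponential(1 / lam))  # discrete times force ties
        event = (time <= 40).astype(int)
        time = np.minimum(time, 40)
        df = pd.DataFrame({"t": time, "e": event, "x0": X[:, 0], "x1": X[:, 1]})
        fit = fit_cox(time, event, X, ["x0", "x1"], ties="efron")
        ref = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        np.testing.assert_allclose(fit.coef, ref.params_.values, atol=1e-5)
        np.testing.assert_allclose(fit.se, ref.standard_errors_.values, atol=1e-5)

    def test_gradient_matches_finite_differences(self):
        time, event, X = self._tied_data()
        prob = CoxProblem(time, event, X, "efron")
        beta = np.array([0.3, -0.2])
        _, g = prob.loglik(beta, grad=True)
        eps = 1e-6
        for j in range(2):
            db = np.zeros(2)
            db[j] = eps
            num = (prob.loglik(beta + db) - prob.loglik(beta - db)) / (2 * eps)
            assert g[j] == pytest.approx(num, abs=1e-5)


class TestCoxRecoveryAndErrors:
    def test_simulation_recovery_log_hr(self):
        rng = np.random.default_rng(12)
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        lam = 0.02 * np.exp(1.1 * x)
        t = rng.exponential(1 / lam)
        event = (t <= 100).astype(int)
        t = np.minimum(t, 100)
        fit = fit_cox(t, event, x[:, None])
        assert fit.coef[0] == pytest.approx(1.1, abs=0.1)

    def test_score_at_mle_small(self, cohort):
        subj, _ = cohort
        X = np.column_stack([subj["true_bdnf_high"], subj["age_high"],
                             subj["gcs"] - 5.5])
        fit = fit_cox(subj["time"], subj["event"], X)
        prob = CoxProblem(subj["time"], subj["event"], X)
        score, _ = prob.score_info(fit.coef)
        assert np.max(np.abs(score)) < 1e-6

    def test_constant_covariate_rejected(self):
        time = np.array([1.0, 2.0, 3.0])
        event = np.array([1, 1, 0])
        with pytest.raises(FitError):
            fit_cox(time, event, np.ones((3, 1)))

    def test_no_events_rejected(self):
        with pytest.raises(FitError):
            fit_cox(np.array([1.0, 2.0]), np.array([0, 0]), np.array([[0.0], [1.0]]))

    def test_nonpositive_times_rejected(self):
        with pytest.raises(FitError):
            fit_cox(np.array([0.0, 2.0]), np.array([1, 0]), np.array([[0.0], [1.0]]))


class TestWaldSummary:
    def test_direct_evaluation(self):
        from cortmed.regression import ModelFit

        fit = ModelFit("cox", ["x"], np.array([0.0]), np.array([0.5]),
                       np.array([[0.25]]), -1.0, n=10, events=5)
        tbl = wald_summary(fit)
        assert tbl.loc[0, "HR"] == pytest.approx(1.0)
        assert tbl.loc[0, "ci_low"] == pytest.approx(np.exp(-1.959964 * 0.5), abs=1e-4)
        assert tbl.loc[0, "ci_high"] == pytest.approx(2.66, abs=0.01)

    def test_interval_collapses_as_se_vanishes(self):
        from cortmed.regression import ModelFit

        fit = ModelFit("cox", ["x"], np.array([np.log(2.0)]), np.array([1e-12]),
                       np.eye(1) * 1e-24, -1.0, n=10, events=5)
        tbl = wald_summary(fit)
        assert tbl.loc[0, "ci_low"] == pytest.approx(2.0, abs=1e-9)
        assert tbl.loc[0, "ci_high"] == pytest.approx(2.0, abs=1e-9)

    def test_interval_contains_point(self):
        from cortmed.regression import ModelFit

        rng = np.random.default_rng(0)
        for _ in range(20):
            b, se = rng.normal(), abs(rng.normal()) + 0.01
            fit = ModelFit("logistic", ["x"], np.array([b]), np.array([se]),
                           np.array([[se**2]]), -1.0, n=10)
            tbl = wald_summary(fit)
            assert tbl.loc[0, "ci_low"] <= tbl.loc[0, "OR"] <= tbl.loc[0, "ci_high"]
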