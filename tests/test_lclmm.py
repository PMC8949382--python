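import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from actitraj.lclmm import (
    LclmmParams,
    LclmmSpec,
    classify,
    fit,
    loglikelihood,
    n_parameters,
    relative_entropy,
)

from conftest import aligned_agreement, simulate_lclmm_panel, two_class_params


def _single_class_params(var_i=0.3, var_s=0.08, cov=0.05, sigma2=0.25):
    return LclmmParams(
        pi=np.array([1.0]),
        beta=np.array([[[0.3, 0.4]]]),
        re_cov=np.array([[[var_i, cov], [cov, var_s]]]),
        sigma2=np.array([sigma2]),
    )


class TestLoglikelihood:
    def test_single_observation_closed_form(self):
        # G=1, K=1, one observation at t=0: y ~ N(beta0, var_intercept + sigma2)
        rng = np.random.default_rng(0)
        y = rng.normal(size=25)
        df = pd.DataFrame({"participant_id": np.arange(25), "time_years": 0.0, "y0": y})
        params = _single_class_params()
        spec = LclmmSpec(n_classes=1, outcomes=("y0",))
        ll = loglikelihood(spec, df, params)
        closed = norm.logpdf(y, loc=0.3, scale=np.sqrt(0.3 + 0.25)).sum()
        assert ll == pytest.approx(closed, abs=1e-10)

    def test_duplicating_subjects_doubles_ll(self):
        params = two_class_params()
        data, _ = simulate_lclmm_panel(params, 30, [0, 1, 2], seed=2)
        spec = LclmmSpec(n_classes=2, outcomes=("y0", "y1"))
        ll = loglikelihood(spec, data, params)
        dup = data.copy()
        dup["participant_id"] += 1000
        ll2 = loglikelihood(spec, pd.concat([data, dup]), params)
        assert ll2 == pytest.approx(2 * ll, rel=1e-12)

    def test_label_permutation_invariance(self):
        params = two_class_params()
        data, _ = simulate_lclmm_panel(params, 30, [0, 1, 2], seed=3)
        spec = LclmmSpec(n_classes=2, outcomes=("y0", "y1"))
        ll = loglikelihood(spec, data, params)
        flipped = params.permuted(np.array([1, 0]))
        assert loglikelihood(spec, data, flipped) == pytest.approx(ll, rel=1e-12)

    def test_invalid_variances_rejected(self):
        params = _single_class_params(sigma2=-1.0)
        df = pd.DataFrame({"participant_id": [1], "time_years": [0.0], "y0": [0.0]})
        with pytest.raises(ValueError):
            loglikelihood(LclmmSpec(n_classes=1, outcomes=("y0",)), df, params)
        params = _single_class_params(var_i=1.0, var_s=1.0, cov=1.5)
        with pytest.raises(ValueError):
            loglikelihood(LclmmSpec(n_classes=1, outcomes=("y0",)), df, params)


class TestFit:
    def test_em_monotone_ll(self):
        data, _ = simulate_lclmm_panel(two_class_params(), 80, [0, 0.5, 1, 1.5, 2], seed=4, miss=0.1)
        spec = LclmmSpec(n_classes=2, outcomes=("y0", "y1"), n_starts=2, seed=4, max_iter=200)
        res = fit(spec, data)
        assert np.all(np.diff(res.ll_trace) >= -1e-8)

    def test_canonical_order_descending_pi(self):
        data, _ = simulate_lclmm_panel(two_class_params(), 100, [0, 1, 2], seed=5)
        spec = LclmmSpec(n_classes=2, outcomes=("y0", "y1"), n_starts=2, seed=5, max_iter=300)
        res = fit(spec, data)
        assert np.all(np.diff(res.params.pi) <= 0)
        assert res.posterior.shape == (100, 2)
        assert np.allclose(res.posterior.sum(axis=1), 1.0, atol=1e-9)

    def test_determinism_under_seed(self):
        data, _ = simulate_lclmm_panel(two_class_params(), 60, [0, 1, 2], seed=6)
        spec = LclmmSpec(n_classes=2, outcomes=("y0", "y1"), n_starts=3, seed=6, max_iter=150)
        a = fit(spec, data)
        b = fit(spec, data)
        assert a.loglik == b.loglik
        assert np.array_equal(a.assignments, b.assignments)

    def test_aic_bic_formulas_and_param_count(self):
        data, _ = simulate_lclmm_panel(two_class_params(), 50, [0, 1, 2], seed=7)
        spec = LclmmSpec(n_classes=2, outcomes=("y0", "y1"), n_starts=1, seed=7, max_iter=100)
        res = fit(spec, data)
        G, K, N = 2, 2, 50
        expected_p = (G - 1) + 2 * K * G + 4 * K
        assert res.n_params == n_parameters(G, K) == expected_p
        assert res.aic == pytest.approx(-2 * res.loglik + 2 * expected_p)
        assert res.bic == pytest.approx(-2 * res.loglik + expected_p * np.log(N))

    def test_g1_matches_direct_mixed_model(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        times = np.array([0, 0.5, 1, 1.5, 2])
        rows = []
        for i in range(60):
            b = rng.multivariate_normal([0, 0], [[0.3, 0.05], [0.05, 0.08]])
            X = np.column_stack([np.ones_like(times), times])
            y = X @ (np.array([0.3, 0.4]) + b) + rng.normal(0, 0.5, len(times))
            rows.extend(
                {"participant_id": i + 1, "time_years": t, "y0": yy}
                for t, yy in zip(times, y)
            )
        df = pd.DataFrame(rows)
        spec = LclmmSpec(n_classes=1, outcomes=("y0",), n_starts=1, seed=0,
                         max_iter=20000, tol=1e-13)
        res = fit(spec, df)
        ml = sm.MixedLM.from_formula(
            "y0 ~ time_years", groups="participant_id", re_formula="~time_years", data=df
        ).fit(reml=False)
        assert res.loglik == pytest.approx(ml.llf, abs=1e-6)

    def test_fewer_subjects_than_classes_rejected(self):
        df = pd.DataFrame({"participant_id": [1], "time_years": [0.0], "y0": [1.0]})
        with pytest.raises(ValueError):
            fit(LclmmSpec(n_classes=2, outcomes=("y0",)), df)

    def test_high_separation_recovery_single_seed(self):
        params = two_class_params()
        data, labels = simulate_lclmm_panel(params, 200, [0, 0.5, 1, 1.5, 2], seed=1, miss=0.1)
        spec = LclmmSpec(n_classes=2, outcomes=("y0", "y1"), n_starts=3, seed=1, max_iter=300)
        res = fit(spec, data)
        assert aligned_agreement(res.assignments, labels) >= 0.9
        assert res.converged


class TestEntropy:
    def test_degenerate_posteriors(self):
        assert relative_entropy(np.array([[1.0, 0.0]] * 5)) == pytest.approx(1.0)

    def test_uniform_posteriors(self):
        assert relative_entropy(np.array([[0.5, 0.5]] * 5)) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        post = np.array([[0.9, 0.1], [0.8, 0.2]])
        assert relative_entropy(post) == pytest.approx(0.4045381557616782, abs=1e-6)

    def test_single_class_defined_as_one(self):
        assert relative_entropy(np.ones((4, 1))) == 1.0

    def test_zero_log_zero_handled(self):
        assert np.isfinite(relative_entropy(np.array([[1.0, 0.0], [0.3, 0.7]])))


class TestClassify:
    def test_modal_assignment(self):
        assignments, means, lowest = classify(np.array([[0.6, 0.4]]))
        assert assignments.tolist() == [0]

    def test_tie_goes_to_lowest_index(self):
        assignments, *_ = classify(np.array([[0.5, 0.5]]))
        assert assignments.tolist() == [0]

    def test_degenerate_lowest_mean_posterior(self):
        post = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        _, means, lowest = classify(post)
        assert lowest == pytest.approx(1.0)

    def test_hand_computed_fixture(self):
        post = np.array([[0.9, 0.1], [0.7, 0.3], [0.2, 0.8]])
        assignments, means, lowest = classify(post)
        assert assignments.tolist() == [0, 0, 1]
        assert means[0] == pytest.approx(0.8)
        assert means[1] == pytest.approx(0.8)
        assert lowest == pytest.approx(0.8)

    def test_empty_class_flagged_nan(self):
        post = np.array([[0.9, 0.1], [0.8, 0.2]])
        _, means, lowest = classify(post)
        assert np.isnan(means[1])
        assert lowest == pytest.approx(np.nanmin(means))
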