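"""The additive penalized-spline conditional-mean engine."""

import numpy as np
import pytest

import essga
from essga.estimators import fit_conditional_mean
from essga.smoothing import AdditiveSplineSmoother


class TestSmootherBasics:
    def test_noiseless_linear_signal_is_interpolated(self, rng):
        x = rng.uniform(0, 3, 500)
        y = 2.0 * x - 1.0
        fit = fit_conditional_mean(y, x)
        assert fit.fitted_var / fit.response_var == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(fit.fitted, y, atol=1e-5)

    def test_pure_noise_fitted_variance_is_tiny(self, rng):
        M = 10_000
        y = rng.standard_normal(M)
        x = rng.standard_normal(M)  # independent of y
        fit = fit_conditional_mean(y, x)
        # for a linear smoother the expected ratio is ~ (edf-1)/M
        assert fit.fitted_var / fit.response_var < 5e-3
        assert fit.fitted_var / fit.response_var < 5 * fit.effective_df / M

    def test_fit_is_deterministic(self, rng):
        x = rng.uniform(size=1000)
        y = np.sin(4 * x) + 0.1 * rng.standard_normal(1000)
        a = AdditiveSplineSmoother().fit(x, y)
        b = AdditiveSplineSmoother().fit(x, y)
        np.testing.assert_array_equal(a.fitted_values_, b.fitted_values_)
        assert a.lambda_ == b.lambda_

    def test_predict_matches_fitted_on_training_data(self, rng):
        x = rng.uniform(size=800, low=-1, high=1)
        y = x**2 + 0.05 * rng.standard_normal(800)
        sm = AdditiveSplineSmoother().fit(x, y)
        np.testing.assert_allclose(sm.predict(x), sm.fitted_values_, atol=1e-10)

    def test_constant_column_dropped_with_warning(self, rng):
        X = np.column_stack([rng.uniform(size=500), np.full(500, 3.0)])
        y = X[:, 0] + 0.1 * rng.standard_normal(500)
        with pytest.warns(RuntimeWarning, match="constant"):
            sm = AdditiveSplineSmoother().fit(X, y)
        assert sm.dropped_terms_ == [1]
        assert np.corrcoef(sm.fitted_values_, X[:, 0])[0, 1] > 0.9

    def test_residuals_have_mean_near_zero(self, rng):
        x = rng.uniform(size=2000)
        y = np.exp(x) + 0.2 * rng.standard_normal(2000)
        fit = fit_conditional_mean(y, x)
        assert abs((y - fit.fitted).mean()) < 1e-8

    def test_too_many_predictors_rejected(self, rng):
        X = rng.standard_normal((200, 5))
        with pytest.raises(ValueError, match="Gaussian-process"):
            fit_conditional_mean(rng.standard_normal(200), X)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError, match="M >= 100"):
            fit_conditional_mean(rng.standard_normal(50), rng.standard_normal(50))

    def test_fitted_variance_never_exceeds_response_variance(self, rng):
        # shrinkage property of intercept-containing penalized least squares
        for k in range(5):
            x = rng.uniform(size=1000)
            y = np.cos(6 * x) + rng.standard_normal(1000)
            fit = fit_conditional_mean(y, x)
            assert fit.fitted_var <= fit.response_var * (1 + 1e-10)


class TestSmootherAccuracy:
    def test_matches_statsmodels_gam_oracle(self, rng):
        """Independent GAM implementation agrees on a smooth 1-D signal."""
        statsmodels = pytest.importorskip("statsmodels.gam.api")
        from statsmodels.gam.api import BSplines, GLMGam

        x = rng.uniform(0, 1, 2000)
        truth = np.sin(2 * np.pi * x)
        y = truth + 0.3 * rng.standard_normal(2000)
        ours = AdditiveSplineSmoother().fit(x, y)

        bs = BSplines(x[:, None], df=[10], degree=[3])
        gam = GLMGam(y, smoother=bs, alpha=[1.0])
        gam.fit()  # initializes the scale needed by the penalty search
        alpha = gam.select_penweight()[0]
        theirs = GLMGam(y, smoother=bs, alpha=alpha).fit().fittedvalues

        scale = y.std()
        rms = np.sqrt(np.mean((ours.fitted_values_ - theirs) ** 2)) / scale
        assert rms < 0.03
        # and both are close to the true conditional mean
        assert np.sqrt(np.mean((ours.fitted_values_ - truth) ** 2)) / scale < 0.05

    def test_beta_binomial_fit_tracks_closed_form_posterior_mean(self):
        """Fitted values approximate E[P|x] = (4+x)/30 on the discrete support."""
        scn = essga.builtin_scenario("beta_binomial")
        ds = essga.simulate_drawset(scn, 20_000, seed=21)
        fit = fit_conditional_mean(ds.phi[:, 0], ds.summary)
        x = ds.summary[:, 0] * 20
        closed = (4.0 + x) / 30.0
        # compare where the support is well populated (>=100 draws)
        vals, counts = np.unique(x, return_counts=True)
        well = np.isin(x, vals[counts >= 100])
        assert np.max(np.abs(fit.fitted[well] - closed[well])) < 0.02
        # monotone nondecreasing in x up to spline wiggle
        order = np.argsort(x[well])
        f = fit.fitted[well][order]
        assert np.all(np.diff(f) > -1e-3)

    def test_tensor_product_captures_pure_interaction(self, rng):
        """An x1*x2 surface defeats the additive fit but not the tensor one."""
        M = 4000
        x1 = rng.uniform(-1, 1, M)
        x2 = rng.uniform(-1, 1, M)
        y = x1 * x2 + 0.05 * rng.standard_normal(M)
        X = np.column_stack([x1, x2])
        additive = AdditiveSplineSmoother().fit(X, y)
        surface = AdditiveSplineSmoother(tensor=True).fit(X, y)
        var_y = np.var(y, ddof=1)
        assert np.var(additive.fitted_values_, ddof=1) / var_y < 0.05
        assert np.var(surface.fitted_values_, ddof=1) / var_y > 0.85
        with pytest.raises(ValueError, match="exactly 2"):
            AdditiveSplineSmoother(tensor=True).fit(x1, y)

    def test_affine_invariance_of_downstream_variance_ratio(self):
        scn = essga.builtin_scenario("gamma_exponential")
        ds = essga.simulate_drawset(scn, 10_000, seed=31)
        base = fit_conditional_mean(ds.phi[:, 0], ds.summary)
        shifted = fit_conditional_mean(ds.phi[:, 0], 3.5 * ds.summary - 1.2)
        r1 = base.fitted_var / base.response_var
        r2 = shifted.fitted_var / shifted.response_var
        assert r2 == pytest.approx(r1, rel=0.01)
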