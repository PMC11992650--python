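"""ESS estimators: nonparametric regression, summary statistic, posterior mean.

All three follow the scikit-learn estimator protocol — construct with
hyper-parameters, ``fit(X, y)`` with ``X`` the M x q matrix of dataset summary
statistics and ``y`` the matching prior draws of ``phi`` — and expose the
effective-sample-size estimate as the fitted attribute ``n0_``.

* :class:`RegressionESS` — the headline method: fit an additive penalized
  spline of ``phi`` on ``T(X_n)``, take the variance of fitted values as
  ``Var[E[phi|X_n]]``, and invert the preposterior variance ratio,
  ``n0 = n (Var[phi] / Var[fitted] - 1)``.
* :class:`SummaryStatisticESS` — requires the summary to be on phi's scale
  and uses its marginal variance, ``n0 = n (Var[S] / Var[phi] - 1)``.
* :class:`PosteriorMeanESS` — the gold standard: exact per-dataset posterior
  means (conjugate closed form or quadrature) in place of fitted values.

Module-level functions (:func:`ess_regression`, etc.) are thin wrappers that
operate on :class:`~essga.scenarios.DrawSet` objects and return
:class:`~essga.ga.ESSEstimate` records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from .ga import ESSEstimate, ess_from_posterior_mean_var, ess_from_sample_mean_var
from .posterior import posterior_mean_batch
from .scenarios import DrawSet, Scenario, simulate_drawset
from .smoothing import AdditiveSplineSmoother

__all__ = [
    "RegressionFit",
    "fit_conditional_mean",
    "RegressionESS",
    "SummaryStatisticESS",
    "PosteriorMeanESS",
    "ess_regression",
    "ess_regression_multivariate",
    "ess_summary_statistic",
    "ess_posterior_mean",
]

MAX_SPLINE_PREDICTORS = 4


@dataclass
class RegressionFit:
    """Fitted conditional-mean values and variance diagnostics."""

    fitted: np.ndarray
    response_var: float
    fitted_var: float
    effective_df: float
    backend: str = "spline_additive"

    @property
    def variance_ratio(self) -> float:
        """Var[fitted] / Var[phi] — the estimated preposterior shrinkage v."""
        return self.fitted_var / self.response_var


def fit_conditional_mean(
    phi: np.ndarray,
    summary: np.ndarray,
    n_bases: int = 10,
    lambda_grid=None,
    tensor: bool = False,
) -> RegressionFit:
    """Estimate E[phi | T(X_n)] by additive penalized-spline regression.

    Requires M >= 100 rows and at most 4 summary columns (the spline backend's
    practical range; richer summaries call for a Gaussian-process backend,
    which is deliberately not provided here).
    """
    phi = np.asarray(phi, dtype=float).ravel()
    summary = np.atleast_2d(np.asarray(summary, dtype=float))
    if summary.shape[0] == 1 and phi.shape[0] > 1:
        summary = summary.T
    if phi.shape[0] < 100:
        raise ValueError(
            f"need M >= 100 draws for a stable spline fit, got {phi.shape[0]}"
        )
    if summary.shape[1] > MAX_SPLINE_PREDICTORS:
        raise ValueError(
            f"{summary.shape[1]} summary statistics exceed the spline "
            f"backend's limit of {MAX_SPLINE_PREDICTORS}; use a "
            "Gaussian-process regression backend for high-dimensional "
            "summaries"
        )
    sm = AdditiveSplineSmoother(
        n_bases=n_bases, lambda_grid=lambda_grid, tensor=tensor
    )
    sm.fit(summary, phi)
    return RegressionFit(
        fitted=sm.fitted_values_,
        response_var=float(np.var(phi, ddof=1)),
        fitted_var=float(np.var(sm.fitted_values_, ddof=1)),
        effective_df=sm.edf_,
    )


class RegressionESS(BaseEstimator):
    """Nonparametric-regression ESS estimator.

    Parameters
    ----------
    n_obs : int
        Number of information units per simulated dataset (the ``n`` in the
        variance-ratio formula).
    n_bases : int
        Spline basis dimension per summary statistic.
    lambda_grid : array-like or None
        Smoothing-parameter candidates passed to the spline backend.

    Attributes
    ----------
    n0_ : float
        ESS estimate (mean of per-component estimates when y is 2-D).
    n0_components_ : ndarray
        Per-component estimates (length phi_dim).
    fits_ : list of RegressionFit
        One conditional-mean fit per phi component.
    """

    def __init__(
        self,
        n_obs: int,
        n_bases: int = 10,
        lambda_grid=None,
        tensor: bool = False,
    ):
        self.n_obs = n_obs
        self.n_bases = n_bases
        self.lambda_grid = lambda_grid
        self.tensor = tensor

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if X.shape[0] == 1 and y.shape[0] > 1:
            X = X.T
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y row counts differ")
        self.fits_ = []
        comps = []
        for j in range(y.shape[1]):
            fit = fit_conditional_mean(
                y[:, j], X, n_bases=self.n_bases,
                lambda_grid=self.lambda_grid, tensor=self.tensor,
            )
            if fit.fitted_var <= 1e-12 * fit.response_var:
                raise ValueError(
                    "regression found no signal (zero fitted-value variance); "
                    "the ESS is not identified from these draws"
                )
            comps.append(
                ess_from_posterior_mean_var(
                    fit.response_var, fit.fitted_var, self.n_obs
                )
            )
            self.fits_.append(fit)
        self.n0_components_ = np.asarray(comps)
        self.n0_ = float(self.n0_components_.mean())
        self.n_features_in_ = X.shape[1]
        return self

    def to_estimate(self, method: str = "regression", **meta) -> ESSEstimate:
        return ESSEstimate(n0_hat=self.n0_, method=method, n_obs=self.n_obs, **meta)


class SummaryStatisticESS(BaseEstimator):
    """Summary-statistics ESS estimator (marginal-variance ratio).

    Requires the summary statistic to live on the same scale as ``phi``;
    when it does not (or is biased, like the exponential rate MLE), the
    estimate is systematically off — the failure mode the regression
    estimator exists to avoid.
    """

    def __init__(self, n_obs: int):
        self.n_obs = n_obs

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if X.shape[0] == 1 and y.shape[0] > 1:
            X = X.T
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y row counts differ")
        if X.shape[1] not in (y.shape[1], y.shape[1] - 1):
            raise ValueError(
                f"summary dimension {X.shape[1]} does not match phi dimension "
                f"{y.shape[1]} (scale comparison needs matched components)"
            )
        if X.shape[1] == y.shape[1] - 1:
            # multinomial-style summary: reconstruct the redundant proportion
            X = np.hstack([X, 1.0 - X.sum(axis=1, keepdims=True)])
        comps = [
            ess_from_sample_mean_var(
                float(np.var(X[:, j], ddof=1)),
                float(np.var(y[:, j], ddof=1)),
                self.n_obs,
            )
            for j in range(y.shape[1])
        ]
        self.n0_components_ = np.asarray(comps)
        self.n0_ = float(self.n0_components_.mean())
        self.n_features_in_ = X.shape[1]
        return self


class PosteriorMeanESS(BaseEstimator):
    """Gold-standard ESS estimator from exact per-dataset posterior means.

    The scenario supplies prior and likelihood; ``fit(X, y)`` takes the
    simulated summaries and the matching prior draws, computes each dataset's
    posterior mean with the best available backend (conjugate closed form,
    else deterministic quadrature, optionally MCMC) and applies the
    preposterior variance-ratio formula.
    """

    def __init__(
        self,
        scenario: Scenario,
        backend: str = "auto",
        grid_size: int = 2049,
        n_posterior_draws: int = 10_000,
        seed: int = 0,
    ):
        self.scenario = scenario
        self.backend = backend
        self.grid_size = grid_size
        self.n_posterior_draws = n_posterior_draws
        self.seed = seed

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        ds = DrawSet(y, np.atleast_2d(np.asarray(X, dtype=float)),
                     self.scenario.likelihood.n_obs)
        batch = posterior_mean_batch(
            self.scenario,
            ds,
            backend=self.backend,
            grid_size=self.grid_size,
            n_posterior_draws=self.n_posterior_draws,
            seed=self.seed,
        )
        pm = np.atleast_2d(batch.post_means.T).T
        if pm.ndim == 1:
            pm = pm[:, None]
        comps = [
            ess_from_posterior_mean_var(
                float(np.var(y[:, j], ddof=1)),
                float(np.var(pm[:, j], ddof=1)),
                self.scenario.likelihood.n_obs,
            )
            for j in range(y.shape[1])
        ]
        self.batch_ = batch
        self.n0_components_ = np.asarray(comps)
        self.n0_ = float(self.n0_components_.mean())
        self.n_features_in_ = np.atleast_2d(np.asarray(X)).shape[1]
        return self


# ---------------------------------------------------------------------------
# DrawSet-level convenience functions
# ---------------------------------------------------------------------------

def ess_regression(ds: DrawSet, phi_column: int = 0, **spline_kw) -> ESSEstimate:
    """Regression-based ESS for one phi component of a DrawSet."""
    if not 0 <= phi_column < ds.phi_dim:
        raise IndexError(
            f"phi_column {phi_column} out of range for phi_dim {ds.phi_dim}"
        )
    est = RegressionESS(n_obs=ds.n_obs, **spline_kw)
    est.fit(ds.summary, ds.phi[:, phi_column])
    return est.to_estimate(M=ds.M, seed=ds.seed)


def ess_regression_multivariate(ds: DrawSet, **spline_kw):
    """Per-component regression ESS estimates plus their arithmetic mean.

    Returns ``(components, aggregate)`` where ``components`` is a list of
    :class:`ESSEstimate` (one per phi column, each regressed on all summary
    columns) and ``aggregate`` carries their mean.
    """
    if ds.phi_dim < 2:
        raise ValueError(
            "DrawSet has a scalar phi; use ess_regression instead"
        )
    est = RegressionESS(n_obs=ds.n_obs, **spline_kw)
    est.fit(ds.summary, ds.phi)
    components = [
        ESSEstimate(
            n0_hat=float(v), method="regression", M=ds.M,
            n_obs=ds.n_obs, seed=ds.seed,
        )
        for v in est.n0_components_
    ]
    aggregate = est.to_estimate(M=ds.M, seed=ds.seed)
    return components, aggregate


def ess_any_regression(ds: DrawSet, **spline_kw) -> float:
    """Scalar regression estimate for any phi dimension (bootstrap handle)."""
    est = RegressionESS(n_obs=ds.n_obs, **spline_kw)
    est.fit(ds.summary, ds.phi if ds.phi_dim > 1 else ds.phi[:, 0])
    return est.n0_


def ess_summary_statistic(ds: DrawSet) -> ESSEstimate:
    """Summary-statistics ESS (aggregated over components for vector phi)."""
    est = SummaryStatisticESS(n_obs=ds.n_obs)
    est.fit(ds.summary, ds.phi if ds.phi_dim > 1 else ds.phi[:, 0])
    return ESSEstimate(
        n0_hat=est.n0_, method="summary_statistic", M=ds.M,
        n_obs=ds.n_obs, seed=ds.seed,
    )


def ess_posterior_mean(
    scenario: Scenario,
    K: int = 10_000,
    seed: int = 0,
    backend: str = "auto",
    grid_size: int = 2049,
    n_posterior_draws: int = 10_000,
    ds: Optional[DrawSet] = None,
) -> ESSEstimate:
    """Gold-standard ESS: simulate K datasets, use exact posterior means.

    ``Var[phi]`` is computed from the same K prior draws that generated the
    datasets, so numerator and denominator share Monte-Carlo noise.
    """
    if ds is None:
        if K < 100:
            raise ValueError(f"need K >= 100 datasets, got {K}")
        ds = simulate_drawset(scenario, K, seed)
    est = PosteriorMeanESS(
        scenario,
        backend=backend,
        grid_size=grid_size,
        n_posterior_draws=n_posterior_draws,
        seed=seed,
    )
    est.fit(ds.summary, ds.phi if ds.phi_dim > 1 else ds.phi[:, 0])
    return ESSEstimate(
        n0_hat=est.n0_, method="posterior_mean", M=ds.M,
        n_obs=scenario.likelihood.n_obs, seed=seed,
    )
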