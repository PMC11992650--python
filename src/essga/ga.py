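"""Gaussian-approximation (GA) model and closed-form effective-sample-size formulas.

Under the GA framework a parameter ``phi`` is modelled as
``phi ~ N(mu0, sigma2 / n0)`` — the uncertainty one would have after observing
``n0`` hypothetical individuals with individual-level variance ``sigma2`` —
and the mean of a future dataset of ``n`` observations as
``Xbar | phi ~ N(phi, sigma2 / n)``.  Posterior updating is then linear
shrinkage with weight ``v = n / (n0 + n)``, and ``n0`` (the effective sample
size, ESS) can be recovered from variance ratios:

* from the variance of preposterior means:  ``n0 = n (Var[phi] / Var[E[phi|X]] - 1)``
* from the variance of the sample mean (or any summary statistic ``S`` on the
  scale of ``phi``):  ``n0 = n (Var[S] / Var[phi] - 1)``

These identities are exact under the GA and are used as plug-in estimators for
non-Gaussian prior/likelihood pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

__all__ = [
    "GAModel",
    "ESSEstimate",
    "ess_from_posterior_mean_var",
    "ess_from_sample_mean_var",
    "analytic_ess",
    "preposterior_shrink",
]


@dataclass(frozen=True)
class GAModel:
    """Gaussian-approximation triple (mu0, sigma2, n0).

    The implied prior is ``N(mu0, sigma2 / n0)`` and the sampling model for a
    future dataset of size ``n`` has mean variance ``sigma2 / n``.
    """

    mu0: float
    sigma2: float
    n0: float

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError(f"sigma2 must be > 0, got {self.sigma2}")
        if self.n0 <= 0:
            raise ValueError(f"n0 must be > 0, got {self.n0}")

    @property
    def prior_var(self) -> float:
        return self.sigma2 / self.n0

    def shrinkage(self, n_obs: int) -> float:
        """Posterior-mean weight ``v = n / (n0 + n)`` on the data mean."""
        return n_obs / (self.n0 + n_obs)


@dataclass
class ESSEstimate:
    """A point estimate of the effective sample size with provenance.

    ``method`` is one of ``regression``, ``summary_statistic``,
    ``posterior_mean`` or ``analytic``.  Confidence-interval bounds are absent
    (None) unless a bootstrap was run.  ``flags`` records soft warnings such
    as a negative variance-ratio estimate.
    """

    n0_hat: float
    method: str
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    M: Optional[int] = None
    B: Optional[int] = None
    n_obs: Optional[int] = None
    seed: Optional[int] = None
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.ci_high):
                raise ValueError("ci_low must be <= ci_high")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["flags"] = ";".join(self.flags)
        return d


def ess_from_posterior_mean_var(
    var_phi: float, var_post_mean: float, n_obs: int
) -> float:
    """ESS from the variance of preposterior means.

    ``n0 = n (Var[phi] / Var[E[phi|X]] - 1)``.  A negative return value
    (possible when Monte-Carlo noise makes the fitted/posterior-mean variance
    exceed the prior variance) is flagged with a warning but never clamped:
    clamping would bias bootstrap intervals built on top of this estimator.
    """
    if var_post_mean <= 0:
        raise ValueError(
            f"var_post_mean must be > 0 (got {var_post_mean}); "
            "the variance ratio is undefined"
        )
    n0 = n_obs * (var_phi / var_post_mean - 1.0)
    if n0 < 0:
        warnings.warn(
            f"negative ESS estimate ({n0:.4g}): posterior-mean variance "
            "exceeds the prior variance (Monte-Carlo noise?)",
            RuntimeWarning,
            stacklevel=2,
        )
    return n0


def ess_from_sample_mean_var(var_stat: float, var_phi: float, n_obs: int) -> float:
    """ESS from the marginal variance of a summary statistic on phi's scale.

    ``n0 = n (Var[S] / Var[phi] - 1)`` where ``S`` is the dataset sample mean
    or any summary statistic sharing the scale of ``phi``.
    """
    if var_phi <= 0:
        raise ValueError(f"var_phi must be > 0, got {var_phi}")
    n0 = n_obs * (var_stat / var_phi - 1.0)
    if n0 < 0:
        warnings.warn(
            f"negative ESS estimate ({n0:.4g}): summary-statistic variance "
            "is below the prior variance",
            RuntimeWarning,
            stacklevel=2,
        )
    return n0


def analytic_ess(scenario) -> float:
    """Closed-form ESS for the conjugate scenarios.

    beta-binomial: alpha + beta; gamma-exponential: alpha (shape);
    Poisson-gamma: beta (rate); Dirichlet-multinomial: sum of concentrations.

    Raises ValueError for scenarios with no closed form.
    """
    prior = scenario.prior
    lik = scenario.likelihood
    pair = (prior.family, lik.family)
    if pair == ("beta", "binomial"):
        return float(prior.params["alpha"] + prior.params["beta"])
    if pair == ("gamma", "exponential"):
        return float(prior.params["alpha"])
    if pair == ("gamma", "poisson"):
        return float(prior.params["beta"])
    if pair == ("dirichlet", "multinomial"):
        return float(np.sum(prior.params["alpha"]))
    raise ValueError(
        f"no closed-form ESS exists for the {prior.family}-{lik.family} pair "
        f"(scenario {scenario.name!r}); use a simulation-based estimator"
    )


def preposterior_shrink(
    phi_draws: np.ndarray, n0: float, n_obs: int
) -> np.ndarray:
    """Shrink prior draws toward their mean by the GA preposterior factor.

    Returns ``mu_hat + sqrt(v) * (phi - mu_hat)`` with ``v = n / (n0 + n)``
    and ``mu_hat`` the sample mean of the draws, so that the output draws have
    (sample) variance ``v`` times the input variance — the GA marginal
    variance of the preposterior mean.  This is the primitive that feeds
    EVSI-by-sample-size curves; note it is *not* additive: shrinking by n then
    m is not the same as shrinking once by n + m.
    """
    if n0 <= 0:
        raise ValueError(f"n0 must be > 0, got {n0}")
    if n_obs < 0:
        raise ValueError(f"n_obs must be >= 0, got {n_obs}")
    phi = np.asarray(phi_draws, dtype=float)
    v = n_obs / (n0 + n_obs)
    mu_hat = phi.mean()
    return mu_hat + np.sqrt(v) * (phi - mu_hat)
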