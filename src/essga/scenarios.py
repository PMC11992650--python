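"""Scenario specifications and the synthetic draw generator.

A *scenario* couples a prior on a parameter ``phi`` with a likelihood for a
dataset of ``n_obs`` information units (Bernoulli trials for binomial and
multinomial likelihoods, i.i.d. observations otherwise).  The generator draws
``M`` parameter values from the prior, simulates one dataset per draw, and
reduces each dataset to its maximum-likelihood summary statistic — the
(phi, T(X_n)) pairs that every ESS estimator in this package consumes.

Seven built-in scenarios spanning conjugate and non-conjugate pairs are
addressable by name via :func:`builtin_scenario`; the four conjugate ones
carry their closed-form ESS.
"""

from __future__ import annotations

import dataclasses
import io
import numbers
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "PriorSpec",
    "LikelihoodSpec",
    "Scenario",
    "DrawSet",
    "BUILTIN_SCENARIOS",
    "builtin_scenario",
    "scenario_from_dict",
    "sample_prior",
    "simulate_summary",
    "simulate_drawset",
    "prior_moments",
    "save_drawset",
    "load_drawset",
]

_PRIOR_FAMILIES = {
    "beta": ("alpha", "beta"),
    "gamma": ("alpha", "beta"),  # beta is a RATE: mean alpha/beta
    "dirichlet": ("alpha",),
    "normal": ("mu0", "var"),
    "truncated_normal": ("mu0", "var", "lower", "upper"),
    "neglog_beta": ("alpha", "beta"),  # lambda = -ln(1-P), P ~ Beta(alpha, beta)
}

_LIKELIHOOD_FAMILIES = ("binomial", "exponential", "poisson", "multinomial", "weibull")


@dataclass(frozen=True)
class PriorSpec:
    """Prior distribution specification (family + named parameters)."""

    family: str
    params: dict

    def __post_init__(self) -> None:
        if self.family not in _PRIOR_FAMILIES:
            raise ValueError(
                f"unknown prior family {self.family!r}; "
                f"choose from {sorted(_PRIOR_FAMILIES)}"
            )
        required = _PRIOR_FAMILIES[self.family]
        missing = [k for k in required if k not in self.params]
        if missing:
            raise ValueError(f"{self.family} prior is missing parameters {missing}")
        p = self.params
        if self.family in ("beta", "gamma", "neglog_beta"):
            if p["alpha"] <= 0 or p["beta"] <= 0:
                raise ValueError(f"{self.family} parameters must be > 0, got {p}")
        elif self.family == "dirichlet":
            conc = np.asarray(p["alpha"], dtype=float)
            if conc.ndim != 1 or conc.size < 2 or np.any(conc <= 0):
                raise ValueError(
                    "dirichlet concentration must be a vector of >= 2 positive reals"
                )
        elif self.family in ("normal", "truncated_normal"):
            if p["var"] <= 0:
                raise ValueError(f"variance must be > 0, got {p['var']}")
            if self.family == "truncated_normal" and not p["lower"] < p["upper"]:
                raise ValueError("truncated_normal requires lower < upper")

    @property
    def phi_dim(self) -> int:
        if self.family == "dirichlet":
            return int(np.asarray(self.params["alpha"]).size)
        return 1


@dataclass(frozen=True)
class LikelihoodSpec:
    """Likelihood specification: family, information units per dataset.

    ``n_obs`` counts the information units contributing to one dataset —
    Bernoulli trials for binomial/multinomial, i.i.d. observations otherwise.
    It is the ``n`` entering the variance-ratio ESS formulas.
    """

    family: str
    n_obs: int
    fixed_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _LIKELIHOOD_FAMILIES:
            raise ValueError(
                f"unknown likelihood family {self.family!r}; "
                f"choose from {sorted(_LIKELIHOOD_FAMILIES)}"
            )
        if self.n_obs < 1:
            raise ValueError(f"n_obs must be >= 1, got {self.n_obs}")
        if self.family == "weibull":
            shape = self.fixed_params.get("shape", 1.0)
            if shape <= 0:
                raise ValueError("weibull shape must be > 0")
            if shape != 1.0:
                raise NotImplementedError(
                    "only the shape-1 Weibull (exponential with rate theta) "
                    "is supported"
                )


@dataclass(frozen=True)
class Scenario:
    """A prior/likelihood pair with optional closed-form ESS."""

    name: str
    prior: PriorSpec
    likelihood: LikelihoodSpec
    analytic_n0: Optional[float] = None

    @property
    def phi_dim(self) -> int:
        return self.prior.phi_dim

    @property
    def summary_dim(self) -> int:
        if self.likelihood.family == "multinomial":
            return self.phi_dim - 1
        return 1

    @property
    def n_obs(self) -> int:
        return self.likelihood.n_obs

    def with_n_obs(self, n_obs: int) -> "Scenario":
        """Variant of this scenario with a different per-dataset size."""
        lik = dataclasses.replace(self.likelihood, n_obs=n_obs)
        return dataclasses.replace(self, likelihood=lik, name=f"{self.name}_n{n_obs}")


@dataclass
class DrawSet:
    """M paired prior draws and dataset summary statistics.

    ``phi`` is M x phi_dim, ``summary`` M x q; rows are aligned (row m holds
    the draw phi_m and the MLE summary of the dataset simulated from it).
    """

    phi: np.ndarray
    summary: np.ndarray
    n_obs: int
    seed: Optional[int] = None
    scenario_name: Optional[str] = None

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.summary = np.asarray(self.summary, dtype=float)
        if self.phi.ndim == 1:
            self.phi = self.phi[:, None]
        if self.summary.ndim == 1:
            self.summary = self.summary[:, None]
        if self.phi.shape[0] != self.summary.shape[0]:
            raise ValueError(
                f"phi and summary row counts differ "
                f"({self.phi.shape[0]} vs {self.summary.shape[0]})"
            )
        if self.phi.shape[0] < 2:
            raise ValueError("a DrawSet needs at least M = 2 rows")
        for name, arr in (("phi", self.phi), ("summary", self.summary)):
            bad = ~np.isfinite(arr)
            if bad.any():
                rows = np.unique(np.nonzero(bad)[0])
                raise ValueError(
                    f"non-finite entries in {name} at rows {rows[:10].tolist()}"
                )
        if self.n_obs < 1:
            raise ValueError(f"n_obs must be >= 1, got {self.n_obs}")

    @property
    def M(self) -> int:
        return self.phi.shape[0]

    @property
    def phi_dim(self) -> int:
        return self.phi.shape[1]

    def subset(self, idx: np.ndarray) -> "DrawSet":
        """Row-subset (used by the pairs bootstrap)."""
        return DrawSet(
            self.phi[idx], self.summary[idx], self.n_obs,
            seed=self.seed, scenario_name=self.scenario_name,
        )


def _builtins() -> dict:
    b = {
        "beta_binomial": Scenario(
            "beta_binomial",
            PriorSpec("beta", {"alpha": 4.0, "beta": 6.0}),
            LikelihoodSpec("binomial", 20),
            analytic_n0=10.0,
        ),
        "gamma_exponential": Scenario(
            "gamma_exponential",
            PriorSpec("gamma", {"alpha": 20.0, "beta": 10.0}),
            LikelihoodSpec("exponential", 100),
            analytic_n0=20.0,
        ),
        "poisson_gamma": Scenario(
            "poisson_gamma",
            PriorSpec("gamma", {"alpha": 50.0, "beta": 100.0}),
            LikelihoodSpec("poisson", 100),
            analytic_n0=100.0,
        ),
        "dirichlet_multinomial": Scenario(
            "dirichlet_multinomial",
            PriorSpec("dirichlet", {"alpha": (10.0, 5.0, 8.0)}),
            LikelihoodSpec("multinomial", 50),
            analytic_n0=23.0,
        ),
        "normal_weibull": Scenario(
            "normal_weibull",
            PriorSpec("normal", {"mu0": 1.0, "var": 0.04}),
            LikelihoodSpec("weibull", 100, {"shape": 1.0}),
        ),
        "truncnorm_binomial": Scenario(
            "truncnorm_binomial",
            PriorSpec(
                "truncated_normal",
                {"mu0": 0.2, "var": 0.01, "lower": 0.0, "upper": 1.0},
            ),
            LikelihoodSpec("binomial", 20),
        ),
        "neglogbeta_exponential": Scenario(
            "neglogbeta_exponential",
            PriorSpec("neglog_beta", {"alpha": 4.0, "beta": 6.0}),
            LikelihoodSpec("exponential", 100),
        ),
    }
    return b


BUILTIN_SCENARIOS: dict = _builtins()


def builtin_scenario(name: str) -> Scenario:
    """Return a built-in scenario by name.

    Valid names: beta_binomial, gamma_exponential, poisson_gamma,
    dirichlet_multinomial, normal_weibull, truncnorm_binomial,
    neglogbeta_exponential.
    """
    try:
        return BUILTIN_SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: "
            f"{', '.join(sorted(BUILTIN_SCENARIOS))}"
        ) from None


def scenario_from_dict(cfg: dict) -> Scenario:
    """Build a Scenario from a plain mapping (the config-file schema).

    Expected keys: ``name``, ``prior`` (with ``family`` and parameters) and
    ``likelihood`` (with ``family``, ``n_obs``, optional fixed parameters).
    A mapping with only a ``name`` matching a built-in returns that built-in.
    """
    if set(cfg) <= {"name"} and cfg.get("name") in BUILTIN_SCENARIOS:
        return builtin_scenario(cfg["name"])
    for key in ("name", "prior", "likelihood"):
        if key not in cfg:
            raise ValueError(f"scenario config is missing {key!r}")
    prior_cfg = dict(cfg["prior"])
    lik_cfg = dict(cfg["likelihood"])
    prior = PriorSpec(prior_cfg.pop("family"), prior_cfg)
    fixed = {k: v for k, v in lik_cfg.items() if k not in ("family", "n_obs")}
    lik = LikelihoodSpec(lik_cfg["family"], int(lik_cfg["n_obs"]), fixed)
    return Scenario(str(cfg["name"]), prior, lik, cfg.get("analytic_n0"))


def _rng(seed: int, stream: int) -> np.random.Generator:
    # deterministic per-stage child stream from the run's root seed
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def sample_prior(scenario: Scenario, M: int, seed: int) -> np.ndarray:
    """Draw M i.i.d. parameter values from the scenario prior (M x phi_dim)."""
    if M < 2:
        raise ValueError(f"M must be >= 2, got {M}")
    rng = _rng(seed, 1)
    prior = scenario.prior
    p = prior.params
    if prior.family == "beta":
        draws = rng.beta(p["alpha"], p["beta"], size=M)
    elif prior.family == "gamma":
        draws = rng.gamma(shape=p["alpha"], scale=1.0 / p["beta"], size=M)
    elif prior.family == "dirichlet":
        return rng.dirichlet(np.asarray(p["alpha"], dtype=float), size=M)
    elif prior.family == "normal":
        draws = rng.normal(p["mu0"], np.sqrt(p["var"]), size=M)
    elif prior.family == "truncated_normal":
        sd = np.sqrt(p["var"])
        a = (p["lower"] - p["mu0"]) / sd
        b = (p["upper"] - p["mu0"]) / sd
        draws = stats.truncnorm.rvs(
            a, b, loc=p["mu0"], scale=sd, size=M, random_state=rng
        )
    elif prior.family == "neglog_beta":
        P = rng.beta(p["alpha"], p["beta"], size=M)
        draws = -np.log1p(-P)
    else:  # pragma: no cover - guarded by PriorSpec
        raise AssertionError(prior.family)
    return draws.reshape(M, 1)


def simulate_summary(
    scenario: Scenario, phi_draws: np.ndarray, seed: int
) -> DrawSet:
    """Simulate one dataset per prior draw and reduce it to its MLE summary.

    Summaries: binomial -> x / n_trials; exponential (and shape-1 Weibull,
    and the transformed-beta exponential) -> 1 / xbar, the rate MLE;
    poisson -> xbar; multinomial -> first k-1 category proportions.

    Continuous datasets are simulated through their sufficient statistic
    (sum of n exponentials ~ Gamma(n, rate), sum of n Poissons ~
    Poisson(n * lambda)), which is distributionally exact and fast.
    """
    phi = np.asarray(phi_draws, dtype=float)
    if phi.ndim == 1:
        phi = phi[:, None]
    M = phi.shape[0]
    rng = _rng(seed, 2)
    lik = scenario.likelihood
    n = lik.n_obs
    if lik.family == "binomial":
        x = rng.binomial(n, phi[:, 0])
        summary = (x / n).reshape(M, 1)
    elif lik.family in ("exponential", "weibull"):
        rate = phi[:, 0]
        sum_x = rng.gamma(shape=float(n), scale=1.0 / rate, size=M)
        summary = (n / sum_x).reshape(M, 1)  # 1 / xbar, the rate MLE
    elif lik.family == "poisson":
        sum_x = rng.poisson(n * phi[:, 0])
        summary = (sum_x / n).reshape(M, 1)
    elif lik.family == "multinomial":
        counts = rng.multinomial(n, phi)
        summary = counts[:, :-1] / n  # last proportion is redundant
    else:  # pragma: no cover
        raise AssertionError(lik.family)
    return DrawSet(phi, summary, n, seed=seed, scenario_name=scenario.name)


def simulate_drawset(scenario: Scenario, M: int, seed: int) -> DrawSet:
    """Sample the prior and simulate summaries in one deterministic pass."""
    phi = sample_prior(scenario, M, seed)
    return simulate_summary(scenario, phi, seed)


def prior_moments(prior: PriorSpec):
    """Closed-form (mean, variance) of the prior, per component.

    For the transformed-beta prior, lambda = -ln(1-P) with P ~ Beta(a, b) has
    E[lambda] = psi(a+b) - psi(b) and Var[lambda] = psi'(b) - psi'(a+b)
    (digamma/trigamma identities for -ln(1-P) = -ln(P') with P' ~ Beta(b, a)).
    """
    p = prior.params
    if prior.family == "beta":
        a, b = p["alpha"], p["beta"]
        mean = a / (a + b)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
    elif prior.family == "gamma":
        mean = p["alpha"] / p["beta"]
        var = p["alpha"] / p["beta"] ** 2
    elif prior.family == "dirichlet":
        conc = np.asarray(p["alpha"], dtype=float)
        s = conc.sum()
        mean = conc / s
        var = conc * (s - conc) / (s**2 * (s + 1))
    elif prior.family == "normal":
        mean, var = p["mu0"], p["var"]
    elif prior.family == "truncated_normal":
        sd = np.sqrt(p["var"])
        a = (p["lower"] - p["mu0"]) / sd
        b = (p["upper"] - p["mu0"]) / sd
        mean, var = stats.truncnorm.stats(a, b, loc=p["mu0"], scale=sd, moments="mv")
        mean, var = float(mean), float(var)
    elif prior.family == "neglog_beta":
        a, b = p["alpha"], p["beta"]
        mean = special.digamma(a + b) - special.digamma(b)
        var = special.polygamma(1, b) - special.polygamma(1, a + b)
    else:  # pragma: no cover
        raise AssertionError(prior.family)
    return mean, var


# ---------------------------------------------------------------------------
# DrawSet file format: CSV with columns phi_1..phi_d, t_1..t_q, one row per
# Monte-Carlo replicate; a leading comment line carries n_obs/seed metadata.
# ---------------------------------------------------------------------------

def save_drawset(ds: DrawSet, path) -> None:
    """Write a DrawSet as CSV (full float precision, round-trip safe)."""
    cols = {f"phi_{j + 1}": ds.phi[:, j] for j in range(ds.phi.shape[1])}
    cols.update({f"t_{j + 1}": ds.summary[:, j] for j in range(ds.summary.shape[1])})
    frame = pd.DataFrame(cols)
    meta = f"# essga-drawset n_obs={ds.n_obs}"
    if ds.seed is not None:
        meta += f" seed={ds.seed}"
    if ds.scenario_name:
        meta += f" scenario={ds.scenario_name}"
    with open(path, "w") as fh:
        fh.write(meta + "\n")
        frame.to_csv(fh, index=False, float_format="%.17g")


def load_drawset(path, n_obs: Optional[int] = None) -> DrawSet:
    """Load a DrawSet CSV written by :func:`save_drawset` (or by hand).

    ``n_obs`` may be supplied to override (or stand in for) the metadata
    comment line; it is required when the file has no metadata.
    """
    meta: dict = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first.lstrip("# ").split()[1:]:
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
            body = fh.read()
        else:
            body = first + fh.read()
    frame = pd.read_csv(io.StringIO(body), float_precision="round_trip")
    phi_cols = sorted(
        (c for c in frame.columns if c.startswith("phi_")),
        key=lambda c: int(c.split("_")[1]),
    )
    t_cols = sorted(
        (c for c in frame.columns if c.startswith("t_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if not phi_cols:
        raise ValueError(f"{path}: no parameter columns (phi_1, phi_2, ...) found")
    if not t_cols:
        raise ValueError(
            f"{path}: no summary-statistic columns (t_1, t_2, ...) found"
        )
    for col in phi_cols + t_cols:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            bad = frame[pd.to_numeric(frame[col], errors="coerce").isna()].index
            raise ValueError(
                f"{path}: non-numeric values in column {col!r} "
                f"at rows {bad[:10].tolist()}"
            )
    values = frame[phi_cols + t_cols].to_numpy(dtype=float)
    bad_rows = np.unique(np.nonzero(~np.isfinite(values))[0])
    if bad_rows.size:
        raise ValueError(
            f"{path}: non-finite entries at rows {bad_rows[:10].tolist()}"
        )
    if len(frame) < 2:
        raise ValueError(f"{path}: a DrawSet needs at least 2 rows, got {len(frame)}")
    if n_obs is None:
        if "n_obs" not in meta:
            raise ValueError(
                f"{path}: no n_obs metadata; pass n_obs= explicitly"
            )
        n_obs = int(meta["n_obs"])
    if not isinstance(n_obs, numbers.Integral) or n_obs < 1:
        raise ValueError(f"n_obs must be a positive integer, got {n_obs!r}")
    seed = int(meta["seed"]) if "seed" in meta else None
    return DrawSet(
        frame[phi_cols].to_numpy(dtype=float),
        frame[t_cols].to_numpy(dtype=float),
        int(n_obs),
        seed=seed,
        scenario_name=meta.get("scenario"),
    )
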