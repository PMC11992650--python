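# essga — effective sample size of a prior, for Gaussian-approximation EVSI

`essga` estimates the **effective sample size (ESS, n₀)** of a probability
distribution: the number of hypothetical observations whose information
content equals that of the distribution. A Beta(2, 8) prior on a probability,
for example, is worth 2 successes + 8 failures = 10 observations. The ESS is
the key input of the Gaussian-approximation (GA) approach to the expected
value of sample information (EVSI) in health-economic decision models, and is
also useful on its own — to check whether the uncertainty assigned to a model
input matches an expert's sense of how much evidence stands behind it.

The package is aimed at health-economics / medical-decision-making analysts
who have Monte-Carlo draws of a parameter (e.g., from a probabilistic
sensitivity analysis) and a planned data-collection design, and want n₀
without conjugate algebra or per-dataset MCMC.

## The model and the estimators

Under the GA, a parameter φ is modelled as φ ~ N(μ₀, σ²/n₀) and the mean of
a future dataset of n observations as X̄ₙ | φ ~ N(φ, σ²/n), so Bayesian
updating is linear shrinkage with weight v = n/(n₀ + n). Two exact
variance-ratio identities follow and are used as plug-in estimators:

- from preposterior means:  n̂₀ = n (Var[φ] / Var[E[φ|Xₙ]] − 1)
- from a summary statistic S on φ's scale:  n̂₀ = n (Var[S] / Var[φ] − 1)

The package's central estimator makes the first identity cheap. Writing
φ = g(T(Xₙ)) + ε for a low-dimensional dataset summary T(Xₙ) (the MLE in
practice), the conditional mean E[φ|Xₙ] is the fitted value of a
nonparametric regression of the φ draws on the simulated summaries:

1. draw φ₁,…,φ_M from the distribution; simulate one dataset of size n per
   draw and compute its summary statistic T(Xₙᵐ);
2. regress φₘ on T(Xₙᵐ) with an additive penalized cubic-spline model
   (knots at quantiles, smoothing parameter by GCV);
3. take the sample variance of the fitted values as Var[E[φ|Xₙ]] and invert
   the variance ratio.

Comparators with the same interface: the summary-statistic estimator (fast
but biased when no summary shares φ's scale — the exponential-rate MLE 1/x̄
is the canonical failure), and a gold-standard posterior-mean estimator that
computes each dataset's exact E[φ|Xₙ] by conjugate closed form or
deterministic log-space quadrature (an MCMC backend is also included).
Pairs-bootstrap percentile intervals quantify Monte-Carlo uncertainty for any
of them. Seven built-in prior/likelihood scenarios — four conjugate, with
known n₀ of 10, 20, 100 and 23 — serve as validation fixtures.

## Worked example

```python
import essga

scenario = essga.builtin_scenario("beta_binomial")   # Beta(4,6) prior, 20 trials
draws = essga.simulate_drawset(scenario, 100_000, seed=1)

estimate = essga.ess_regression(draws)
ci = essga.bootstrap_ci(draws, "regression", B=1000, seed=1)
print(f"regression ESS: {estimate.n0_hat:.2f} "
      f"(95% CI {ci.ci_low:.2f}-{ci.ci_high:.2f}); analytic: "
      f"{essga.analytic_ess(scenario):.0f}")

gold = essga.ess_posterior_mean(scenario, K=10_000, seed=1)
print(f"posterior-mean ESS: {gold.n0_hat:.2f}")
```

prints

```
regression ESS: 9.94 (95% CI 9.78-10.09); analytic: 10
posterior-mean ESS: 10.49
```

The regression estimate recovers the Beta(4, 6) prior's analytic ESS of
α + β = 10 from simulation alone; the bootstrap interval covers it, and the
gold-standard comparator (10 000 simulated datasets, exact posterior means)
agrees within Monte-Carlo error. The sklearn-style classes
(`RegressionESS`, `SummaryStatisticESS`, `PosteriorMeanESS`) expose the same
computations as `fit(X, y)` estimators with an `n0_` attribute, for use in
pipelines; your own draws can come from a CSV via `essga.load_drawset`.

The same interface is available from the shell:

```bash
ess-ga estimate --scenario gamma_exponential --method summary_statistic -M 100000 --seed 1
ess-ga grid --config run.yaml     # full scenario-by-method grid as CSV
```

The first command prints `"n0_hat": 23.76…` — the summary-statistic method's
characteristic overestimate for the Gamma(20, 10) exponential-rate scenario,
where the spline regression stays near 21 (see `docs/methods.md` for why the
exact variance-ratio value is 21, not the conjugate count 20).

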