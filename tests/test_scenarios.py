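"""Scenario fixtures, prior sampling, dataset summaries and DrawSet I/O."""

import numpy as np
import pytest

import essga
from essga.scenarios import (
    BUILTIN_SCENARIOS,
    DrawSet,
    LikelihoodSpec,
    PriorSpec,
    builtin_scenario,
    load_drawset,
    prior_moments,
    sample_prior,
    save_drawset,
    scenario_from_dict,
    simulate_drawset,
    simulate_summary,
)

M_BIG = 100_000


class TestBuiltinScenarios:
    def test_seven_builtins_with_expected_parameters(self):
        assert set(BUILTIN_SCENARIOS) == {
            "beta_binomial", "gamma_exponential", "poisson_gamma",
            "dirichlet_multinomial", "normal_weibull", "truncnorm_binomial",
            "neglogbeta_exponential",
        }
        bb = builtin_scenario("beta_binomial")
        assert bb.prior.params == {"alpha": 4.0, "beta": 6.0}
        assert bb.likelihood.n_obs == 20
        assert bb.analytic_n0 == 10
        pg = builtin_scenario("poisson_gamma")
        assert pg.prior.params == {"alpha": 50.0, "beta": 100.0}
        assert pg.likelihood.n_obs == 100
        assert pg.analytic_n0 == 100
        tn = builtin_scenario("truncnorm_binomial")
        assert tn.prior.params["mu0"] == 0.2
        assert tn.prior.params["var"] == 0.01
        assert (tn.prior.params["lower"], tn.prior.params["upper"]) == (0, 1)
        assert tn.analytic_n0 is None

    def test_analytic_n0_exactly_on_conjugate_scenarios(self):
        conj = {"beta_binomial", "gamma_exponential", "poisson_gamma",
                "dirichlet_multinomial"}
        for name, scn in BUILTIN_SCENARIOS.items():
            assert (scn.analytic_n0 is not None) == (name in conj)

    def test_unknown_name_error_lists_valid_names(self):
        with pytest.raises(ValueError, match="beta_binomial"):
            builtin_scenario("nope")

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="> 0"):
            PriorSpec("beta", {"alpha": -1.0, "beta": 2.0})
        with pytest.raises(ValueError, match="lower < upper"):
            PriorSpec("truncated_normal",
                      {"mu0": 0, "var": 1, "lower": 2, "upper": 1})
        with pytest.raises(ValueError, match="n_obs"):
            LikelihoodSpec("binomial", 0)
        with pytest.raises(ValueError, match="family"):
            PriorSpec("cauchy", {})

    def test_scenario_from_dict_and_builtin_shortcut(self):
        scn = scenario_from_dict(
            {
                "name": "custom",
                "prior": {"family": "beta", "alpha": 2.0, "beta": 8.0},
                "likelihood": {"family": "binomial", "n_obs": 10},
            }
        )
        assert scn.prior.params["beta"] == 8.0
        assert scn.summary_dim == 1
        assert scenario_from_dict({"name": "beta_binomial"}).analytic_n0 == 10
        with pytest.raises(ValueError, match="missing"):
            scenario_from_dict({"name": "x", "prior": {"family": "beta",
                                                       "alpha": 1, "beta": 1}})


class TestPriorSampling:
    @pytest.mark.parametrize("name", sorted(BUILTIN_SCENARIOS))
    def test_moments_match_closed_form_within_four_se(self, name):
        scn = builtin_scenario(name)
        draws = sample_prior(scn, M_BIG, seed=5)
        mean, var = prior_moments(scn.prior)
        mean = np.atleast_1d(mean)
        var = np.atleast_1d(var)
        for j in range(draws.shape[1]):
            x = draws[:, j]
            se_mean = x.std(ddof=1) / np.sqrt(M_BIG)
            assert abs(x.mean() - mean[j]) < 4 * se_mean
            m2 = x.var(ddof=1)
            # SE of the sample variance from the empirical fourth moment
            c = x - x.mean()
            se_var = np.sqrt((np.mean(c**4) - m2**2) / M_BIG)
            assert abs(m2 - var[j]) < 4 * se_var

    def test_support_constraints(self):
        d = sample_prior(builtin_scenario("dirichlet_multinomial"), 5000, 1)
        np.testing.assert_allclose(d.sum(axis=1), 1.0, atol=1e-12)
        t = sample_prior(builtin_scenario("truncnorm_binomial"), 5000, 1)
        assert np.all((t > 0) & (t < 1))
        nl = sample_prior(builtin_scenario("neglogbeta_exponential"), 5000, 1)
        assert np.all(nl > 0)

    def test_m_below_two_rejected(self):
        with pytest.raises(ValueError, match="M"):
            sample_prior(builtin_scenario("beta_binomial"), 1, 0)


class TestSimulateSummary:
    def test_degenerate_binomial_at_zero_probability(self, beta_binomial):
        phi = np.concatenate([np.zeros(5), np.full(5, 0.5)])
        ds = simulate_summary(beta_binomial, phi, seed=0)
        assert np.all(ds.summary[:5, 0] == 0.0)

    def test_poisson_marginal_summary_variance(self):
        # law of total variance: Var(xbar) = Var(lambda) + E[lambda]/n
        #   = 50/100^2 + 0.5/100 = 0.01
        scn = builtin_scenario("poisson_gamma")
        ds = simulate_drawset(scn, M_BIG, seed=3)
        assert np.var(ds.summary[:, 0], ddof=1) == pytest.approx(0.01, abs=4e-4)

    def test_exponential_rate_mle_upward_bias(self):
        # E[1/xbar | lambda] = lambda * n/(n-1): mean exceeds E[lambda]=2
        scn = builtin_scenario("gamma_exponential")
        ds = simulate_drawset(scn, M_BIG, seed=3)
        expected = 2.0 * 100 / 99
        assert ds.summary[:, 0].mean() == pytest.approx(expected, abs=0.01)

    @pytest.mark.parametrize(
        "name", ["beta_binomial", "gamma_exponential", "poisson_gamma"]
    )
    def test_conditional_summary_variance_shrinks_as_one_over_n(self, name):
        scn = builtin_scenario(name)
        mean, _ = prior_moments(scn.prior)
        phi = np.full(20_000, float(np.atleast_1d(mean)[0]))
        v = {}
        for n_obs in (10, 1000):
            ds = simulate_summary(scn.with_n_obs(n_obs), phi, seed=9)
            v[n_obs] = np.var(ds.summary[:, 0], ddof=1)
        ratio = v[10] / v[1000]
        assert 50 < ratio < 200  # expected 100, generous Monte-Carlo band

    def test_multinomial_summary_drops_redundant_category(self):
        scn = builtin_scenario("dirichlet_multinomial")
        ds = simulate_drawset(scn, 500, seed=4)
        assert ds.phi.shape == (500, 3)
        assert ds.summary.shape == (500, 2)
        assert np.all(ds.summary.sum(axis=1) <= 1.0 + 1e-12)

    def test_identical_seed_identical_drawset(self, beta_binomial):
        a = simulate_drawset(beta_binomial, 1000, seed=42)
        b = simulate_drawset(beta_binomial, 1000, seed=42)
        c = simulate_drawset(beta_binomial, 1000, seed=43)
        np.testing.assert_array_equal(a.phi, b.phi)
        np.testing.assert_array_equal(a.summary, b.summary)
        assert not np.array_equal(a.summary, c.summary)


class TestDrawSetIO:
    def test_round_trip_is_bitwise(self, tmp_path, beta_binomial):
        ds = simulate_drawset(beta_binomial, 100, seed=8)
        path = tmp_path / "ds.csv"
        save_drawset(ds, path)
        back = load_drawset(path)
        np.testing.assert_array_equal(ds.phi, back.phi)
        np.testing.assert_array_equal(ds.summary, back.summary)
        assert back.n_obs == 20 and back.seed == 8
        assert back.scenario_name == "beta_binomial"

    def test_missing_summary_columns(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("phi_1\n0.1\n0.2\n")
        with pytest.raises(ValueError, match="t_1"):
            load_drawset(p, n_obs=10)

    def test_nan_row_identified(self, tmp_path):
        p = tmp_path / "nan.csv"
        p.write_text("phi_1,t_1\n0.1,0.2\n0.3,nan\n0.4,0.5\n")
        with pytest.raises(ValueError, match=r"rows \[1\]"):
            load_drawset(p, n_obs=10)

    def test_too_few_rows(self, tmp_path):
        p = tmp_path / "tiny.csv"
        p.write_text("phi_1,t_1\n0.1,0.2\n")
        with pytest.raises(ValueError, match="2 rows"):
            load_drawset(p, n_obs=10)

    def test_missing_n_obs_metadata(self, tmp_path):
        p = tmp_path / "nometa.csv"
        p.write_text("phi_1,t_1\n0.1,0.2\n0.3,0.4\n")
        with pytest.raises(ValueError, match="n_obs"):
            load_drawset(p)
        assert load_drawset(p, n_obs=20).n_obs == 20

    def test_mismatched_rows_rejected(self):
        with pytest.raises(ValueError, match="row counts"):
            DrawSet(np.zeros((5, 1)), np.zeros((4, 1)), 10)
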