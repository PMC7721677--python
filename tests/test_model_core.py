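"""Unit tests for the conjugate Gibbs sampler, summaries and HPD intervals."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

import priorscope as ps
from priorscope.model_core import gibbs_batch

from conftest import ols_fit


# ---------------------------------------------------------------------------
# domain type validation
# ---------------------------------------------------------------------------


class TestTypes:
    def test_data_rejects_dimension_mismatch(self):
        with pytest.raises(ps.ConfigurationError):
            ps.RegressionData(np.ones(5), np.ones((4, 1)), ("x",))

    def test_data_rejects_missing_values(self):
        y = np.array([1.0, np.nan, 2.0, 3.0, 0.5])
        with pytest.raises(ps.ConfigurationError):
            ps.RegressionData(y, np.ones((5, 1)), ("x",))

    def test_data_requires_residual_df(self):
        # n >= p + 2
        with pytest.raises(ps.ConfigurationError):
            ps.RegressionData(np.arange(3.0), np.random.default_rng(0).random((3, 2)), ("a", "b"))

    def test_normal_prior_variance_must_be_positive(self):
        with pytest.raises(ps.ConfigurationError):
            ps.NormalPrior(0.0, 0.0)
        with pytest.raises(ps.ConfigurationError):
            ps.NormalPrior(0.0, -1.0)

    def test_inverse_gamma_improper_needs_flag(self):
        with pytest.raises(ps.ConfigurationError):
            ps.InverseGammaPrior(-1.0, 0.0)  # improper without acknowledgement
        prior = ps.InverseGammaPrior(-1.0, 0.0, proper_flag=False)
        assert not prior.proper_flag
        assert ps.InverseGammaPrior(0.001, 0.001).proper_flag

    def test_chain_settings_defaults_and_validation(self):
        settings = ps.ChainSettings()
        assert settings.total_iterations == 5000
        assert settings.burn_in == 2500  # first half discarded
        assert settings.n_chains == 1
        with pytest.raises(ps.ConfigurationError):
            ps.ChainSettings(total_iterations=100, burn_in=100)

    def test_prior_set_pairing(self, tiny_data):
        priors = ps.PriorSet(coefficients=(ps.NormalPrior(0, 1), ps.NormalPrior(0, 1)))
        with pytest.raises(ps.ConfigurationError):
            priors.paired_with(tiny_data)


# ---------------------------------------------------------------------------
# sampler correctness against closed-form and independent oracles
# ---------------------------------------------------------------------------


class TestGibbs:
    def test_fixed_sigma_matches_precision_weighted_posterior(self):
        """Single predictor, sigma^2 = 1, prior N(0, 1): the exact posterior
        mean is (1*0 + sum(xy)) / (1 + sum(x^2))."""
        rng = np.random.default_rng(11)
        x = rng.standard_normal(10)
        y = 2.0 * x + rng.standard_normal(10)
        data = ps.RegressionData(y, x[:, None], ("x",))
        closed_form = float(x @ y) / (1.0 + float(x @ x))
        posterior_var = 1.0 / (1.0 + float(x @ x))

        priors = ps.PriorSet(
            coefficients=(ps.NormalPrior(0.0, 1.0),),
            residual_variance=ps.FixedResidualVariance(1.0),
        )
        settings = ps.ChainSettings(total_iterations=20000, seed=3)
        chain = ps.gibbs_regression(data, priors, settings, fit_intercept=False)
        draws = chain.parameter("x")
        # with sigma^2 fixed the block draws are iid from the exact posterior
        mc_se = math.sqrt(posterior_var / draws.size)
        assert abs(draws.mean() - closed_form) < 3 * mc_se

    def test_diffuse_priors_fixed_sigma_recover_least_squares(self, tiny_data):
        """Prior variances -> 1e10 with sigma^2 fixed: posterior mean equals
        the least-squares solution within Monte-Carlo error."""
        priors = ps.PriorSet(
            intercept=ps.NormalPrior(0, 1e10),
            coefficients=(ps.NormalPrior(0, 1e10),),
            residual_variance=ps.FixedResidualVariance(1.0),
        )
        settings = ps.ChainSettings(total_iterations=20000, seed=5)
        chain = ps.gibbs_regression(tiny_data, priors, settings)
        ols = ols_fit(tiny_data)
        for j, name in enumerate(["intercept", "x"]):
            draws = chain.parameter(name)
            mc_se = draws.std(ddof=1) / math.sqrt(draws.size)
            assert abs(draws.mean() - ols[j]) < 3 * mc_se

    def test_sigma2_posterior_mean_matches_quadrature_oracle(self):
        """Proper IG(3, 2) residual prior, n = 50: the sampler's posterior
        mean of sigma^2 matches 1-D quadrature of the exact marginal
        p(sigma^2 | y) ~ IG(s2; 3, 2) * N(y; X mu0, s2 I + X V0 X')."""
        rng = np.random.default_rng(21)
        n = 50
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        beta_true = np.array([1.0, 0.5])
        y = x @ beta_true + rng.normal(0, math.sqrt(0.5), n)

        mu0 = np.zeros(2)
        v0 = np.diag([1e4, 1e4])
        a0, b0 = 3.0, 2.0

        def log_marginal(s2):
            cov = s2 * np.eye(n) + x @ v0 @ x.T
            resid = y - x @ mu0
            sign, logdet = np.linalg.slogdet(cov)
            quad = resid @ np.linalg.solve(cov, resid)
            log_prior = -(a0 + 1) * math.log(s2) - b0 / s2
            return log_prior - 0.5 * (logdet + quad)

        grid = np.linspace(0.15, 3.0, 4000)
        logs = np.array([log_marginal(s) for s in grid])
        w = np.exp(logs - logs.max())
        oracle_mean = integrate.trapezoid(grid * w, grid) / integrate.trapezoid(w, grid)

        data = ps.RegressionData(y, x[:, 1:], ("x",))
        priors = ps.PriorSet(
            intercept=ps.NormalPrior(0, 1e4),
            coefficients=(ps.NormalPrior(0, 1e4),),
            residual_variance=ps.InverseGammaPrior(a0, b0),
        )
        chain = ps.gibbs_regression(data, priors, ps.ChainSettings(total_iterations=100_000, seed=9))
        draws = chain.parameter("residual_variance")
        ess = ps.effective_sample_size(draws)
        mc_se = draws.std(ddof=1) / math.sqrt(min(ess, draws.size))
        assert abs(draws.mean() - oracle_mean) < 3 * mc_se

    def test_prior_washout_is_monotone_in_prior_variance(self, tiny_data):
        """With the prior mean shifted away from the least-squares estimate,
        the posterior mean's distance to it shrinks monotonically as the
        prior variance grows."""
        ols_slope = ols_fit(tiny_data)[1]
        prior_mean = ols_slope - 5.0
        distances = []
        for v in [0.05, 1.0, 100.0, 1e10]:
            priors = ps.PriorSet(
                intercept=ps.NormalPrior(0, 1e10),
                coefficients=(ps.NormalPrior(prior_mean, v),),
                residual_variance=ps.FixedResidualVariance(1.0),
            )
            chain = ps.gibbs_regression(
                tiny_data, priors, ps.ChainSettings(total_iterations=20000, seed=13)
            )
            distances.append(abs(chain.parameter("x").mean() - ols_slope))
        assert distances == sorted(distances, reverse=True)
        assert distances[-1] < 0.05

    def test_shrinkage_keeps_posterior_between_prior_and_ols(self, tiny_data):
        ols_slope = ols_fit(tiny_data)[1]
        prior_mean = ols_slope - 3.0
        priors = ps.PriorSet(
            intercept=ps.NormalPrior(0, 1e10),
            coefficients=(ps.NormalPrior(prior_mean, 0.5),),
            residual_variance=ps.FixedResidualVariance(1.0),
        )
        chain = ps.gibbs_regression(
            tiny_data, priors, ps.ChainSettings(total_iterations=20000, seed=17)
        )
        post_mean = chain.parameter("x").mean()
        assert prior_mean < post_mean < ols_slope

    def test_seed_determinism_bit_identical(self, tiny_data):
        priors = ps.PriorSet(coefficients=(ps.NormalPrior(0, 1),))
        settings = ps.ChainSettings(total_iterations=500, seed=123)
        a = ps.gibbs_regression(tiny_data, priors, settings)
        b = ps.gibbs_regression(tiny_data, priors, settings)
        assert np.array_equal(a.full_draws, b.full_draws)

    def test_batched_engine_matches_single_runs(self, tiny_data):
        """A batch member's chain is bit-identical to a standalone run with
        the same seed, regardless of batch composition."""
        x = np.column_stack([np.ones(tiny_data.n), tiny_data.predictors])
        y = tiny_data.outcome
        xtx, xty, yty = x.T @ x, x.T @ y, float(y @ y)
        mu0 = np.zeros(2)
        v0 = np.array([1e10, 1.0])
        prior = ps.InverseGammaPrior(-1.0, 0.0, proper_flag=False)
        init = np.array([float(np.var(y, ddof=1))])

        def run(seeds):
            return gibbs_batch(
                np.repeat(xtx[None], len(seeds), axis=0),
                np.repeat(xty[None], len(seeds), axis=0),
                np.full(len(seeds), yty),
                tiny_data.n, mu0, v0, prior, 300, seeds,
                np.full(len(seeds), init[0]),
            )

        batch = run([101, 102, 103])
        solo = run([102])
        assert np.array_equal(batch[1], solo[0])

    def test_residual_variance_draws_strictly_positive(self, tiny_data):
        priors = ps.PriorSet(coefficients=(ps.NormalPrior(0, 1),))
        chain = ps.gibbs_regression(tiny_data, priors, ps.ChainSettings(total_iterations=2000, seed=1))
        assert np.all(chain.full_draws[..., -1] > 0)

    def test_improper_conditional_raises_named_error(self, tiny_data):
        priors = ps.PriorSet(
            coefficients=(ps.NormalPrior(0, 1),),
            residual_variance=ps.InverseGammaPrior(-30.0, 0.0, proper_flag=False),
        )
        with pytest.raises(ps.EstimationError, match="IG"):
            ps.gibbs_regression(tiny_data, priors, ps.ChainSettings(total_iterations=100, seed=0))

    def test_dimension_mismatch_is_configuration_error(self, tiny_data):
        priors = ps.PriorSet(coefficients=(ps.NormalPrior(0, 1), ps.NormalPrior(0, 1)))
        with pytest.raises(ps.ConfigurationError):
            ps.gibbs_regression(tiny_data, priors, ps.ChainSettings())


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------


def _chain_from_array(values, burn_in=0):
    values = np.asarray(values, dtype=float)
    settings = ps.ChainSettings(total_iterations=len(values), burn_in=burn_in, seed=0)
    return ps.PosteriorChain(values.reshape(1, -1, 1), settings, ["theta"])


class TestSummaries:
    def test_constant_chain_degenerate_summary(self):
        chain = _chain_from_array(np.full(100, 3.5))
        summary = ps.summarize_posterior(chain, 0.9)
        row = summary.table.loc["theta"]
        assert row["mean"] == 3.5 and row["sd"] == 0.0
        assert (row["hpd_lower"], row["hpd_upper"]) == (3.5, 3.5)

    def test_alternating_chain_mean_zero(self):
        chain = _chain_from_array(np.tile([-1.0, 1.0], 50))
        assert ps.summarize_posterior(chain).table.loc["theta", "mean"] == 0.0

    def test_standard_normal_mean_within_tolerance(self):
        draws = np.random.default_rng(0).standard_normal(10_000)
        chain = _chain_from_array(draws)
        assert abs(ps.summarize_posterior(chain).table.loc["theta", "mean"]) < 3 / 100.0

    def test_summary_uses_post_burn_in_draws_only(self):
        values = np.concatenate([np.full(50, 100.0), np.zeros(50)])
        chain = _chain_from_array(values, burn_in=50)
        assert ps.summarize_posterior(chain).table.loc["theta", "mean"] == 0.0

    def test_empty_kept_segment_errors(self):
        chain = _chain_from_array(np.arange(10.0), burn_in=9)
        with pytest.raises(ps.ConfigurationError):
            ps.summarize_posterior(chain)


def brute_force_hpd(samples, level):
    """Exhaustive scan over every window start index."""
    ordered = np.sort(np.asarray(samples, dtype=float))
    n = ordered.size
    m = max(math.ceil(level * n), 1)
    if m >= n:
        return float(ordered[0]), float(ordered[-1])
    best = None
    for start in range(n - m + 1):
        lo, hi = ordered[start], ordered[start + m - 1]
        if best is None or hi - lo < best[1] - best[0]:
            best = (float(lo), float(hi))
    return best


class TestHpd:
    def test_uniform_grid_tie_break_lowest(self):
        lo, hi = ps.hpd_interval(np.arange(1.0, 101.0), 0.90)
        assert (lo, hi) == (1.0, 90.0)

    def test_constant_samples(self):
        assert ps.hpd_interval(np.full(20, 2.0), 0.9) == (2.0, 2.0)

    def test_matches_brute_force_on_exponential_draws(self):
        draws = np.random.default_rng(42).exponential(1.0, 5000)
        assert ps.hpd_interval(draws, 0.90) == brute_force_hpd(draws, 0.90)

    @pytest.mark.parametrize("level", [0.5, 0.9, 0.95])
    def test_matches_brute_force_random_sets(self, level):
        rng = np.random.default_rng(int(level * 100))
        for _ in range(20):
            n = int(rng.integers(2, 500))
            draws = rng.normal(size=n) * rng.exponential()
            assert ps.hpd_interval(draws, level) == brute_force_hpd(draws, level)

    def test_rejects_non_finite(self):
        with pytest.raises(ps.ConfigurationError):
            ps.hpd_interval(np.array([1.0, np.inf, 2.0]), 0.9)

    def test_rejects_bad_level(self):
        with pytest.raises(ps.ConfigurationError):
            ps.hpd_interval(np.arange(10.0), 1.5)

    def test_interval_is_ordered(self):
        draws = np.random.default_rng(3).normal(size=500)
        lo, hi = ps.hpd_interval(draws, 0.9)
        assert lo < hi
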