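import numpy as np
import pytest
from scipy import stats

from orddcm.design import QMatrix
from orddcm.estimate import (
    SamplerConfig,
    elpd_loo,
    fit,
    fit_map,
    multivariate_rhat,
    rhat,
)
from orddcm.exceptions import ConfigError, DataError
from orddcm.simulate import generate_dataset

from conftest import random_natural


@pytest.fixture(scope="module")
def small_fit_inputs():
    q = QMatrix(entries=np.array([[1, 0], [1, 0], [0, 1], [0, 1]]))
    rng = np.random.default_rng(4)
    params = random_natural("ordm", q, 3, rng)
    ds = generate_dataset("ordm", params, [0.3, 0.2, 0.2, 0.3], 150, 5, q)
    return q, params, ds


class TestSamplerConfig:
    def test_burnin_must_be_smaller(self):
        with pytest.raises(ConfigError):
            SamplerConfig(iterations=100, burnin=100)

    def test_needs_two_chains(self):
        with pytest.raises(ConfigError):
            SamplerConfig(chains=1)


class TestRhat:
    def test_same_stream_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((2, 4000))
        assert 0.97 < rhat(chains) < 1.03

    def test_separated_chains_large(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert rhat(chains) > 1.1

    def test_constant_chains_convention(self):
        assert rhat(np.ones((2, 100))) == 1.0

    def test_input_validation(self):
        with pytest.raises(ConfigError):
            rhat(np.ones(10))
        with pytest.raises(ConfigError):
            rhat(np.ones((2, 3)))

    def test_multivariate_mixed_chains(self):
        rng = np.random.default_rng(2)
        draws = rng.standard_normal((2, 2000, 3))
        assert multivariate_rhat(draws) < 1.1
        shifted = draws.copy()
        shifted[1] += 8.0
        assert multivariate_rhat(shifted) > 1.5


class TestElpdLoo:
    def test_no_posterior_uncertainty(self):
        ll = np.tile(np.array([-1.0, -2.0, -0.5]), (200, 1))
        res = elpd_loo(ll)
        assert res.elpd == pytest.approx(-3.5, abs=1e-12)
        assert res.looic == pytest.approx(7.0, abs=1e-12)

    def test_looic_identity(self):
        rng = np.random.default_rng(3)
        ll = -np.abs(rng.standard_normal((2, 400, 10))) - 1.0
        res = elpd_loo(ll)
        assert res.looic == pytest.approx(-2 * res.elpd, abs=1e-10)
        assert res.looic_se == pytest.approx(2 * res.elpd_se, abs=1e-10)

    def test_matches_exact_loo_on_conjugate_model(self):
        # y_i ~ N(mu, 1), mu ~ N(0, 1): closed-form posterior and exact LOO
        rng = np.random.default_rng(10)
        y = np.array([0.3, -0.6, 1.1])
        n = y.size
        post_mean = y.sum() / (n + 1)
        post_var = 1.0 / (n + 1)
        draws = rng.normal(post_mean, np.sqrt(post_var), 4000)
        ll = stats.norm.logpdf(y[None, :], loc=draws[:, None], scale=1.0)
        res = elpd_loo(ll)
        exact = 0.0
        for i in range(n):
            rest = np.delete(y, i)
            m = rest.sum() / (rest.size + 1)
            v = 1.0 / (rest.size + 1)
            exact += stats.norm.logpdf(y[i], loc=m, scale=np.sqrt(1 + v))
        assert res.elpd == pytest.approx(exact, abs=max(res.elpd_se, 0.05))

    def test_nonfinite_rejected(self):
        with pytest.raises(DataError):
            elpd_loo(np.array([[0.0, -np.inf]]))


class TestFitMap:
    def test_determinism(self, small_fit_inputs):
        q, _, ds = small_fit_inputs
        r1 = fit_map("ordm", ds, q)
        r2 = fit_map("ordm", ds, q)
        np.testing.assert_array_equal(r1.theta, r2.theta)
        np.testing.assert_array_equal(r1.prevalence, r2.prevalence)

    def test_prevalence_recovery(self, survey_q, ordm_truth, truth_prevalence):
        ds = generate_dataset("ordm", ordm_truth, truth_prevalence, 500, 11, survey_q)
        res = fit_map("ordm", ds, survey_q)
        assert np.abs(res.prevalence - truth_prevalence).max() < 0.05

    def test_result_satisfies_constraints(self, small_fit_inputs):
        from orddcm.models import validate_constraints

        q, _, ds = small_fit_inputs
        res = fit_map("ordm", ds, q)
        assert validate_constraints(res.params, q=q).ok

    def test_prior_dominated_fits_are_data_driven(self, survey_q, ordm_truth, truth_prevalence):
        # halving the prior sd barely moves well-populated estimates
        ds = generate_dataset("ordm", ordm_truth, truth_prevalence, 500, 11, survey_q)
        wide = fit_map("ordm", ds, survey_q, prior_sd=20.0)
        narrow = fit_map("ordm", ds, survey_q, prior_sd=10.0)
        populated = np.abs(wide.theta) < 5  # exclude weakly identified tails
        assert np.abs(wide.theta - narrow.theta)[populated].max() < 0.2

    def test_degenerate_option_warns(self, survey_q):
        rng = np.random.default_rng(6)
        params = random_natural("ordm", survey_q, 4, rng)
        ds = generate_dataset("ordm", params, [0.25] * 4, 40, 2, survey_q)
        ds.responses[ds.responses == 3] = 2  # option 3 never chosen anywhere
        from orddcm.simulate import ResponseDataset

        clipped = ResponseDataset(responses=ds.responses, options=(4,) * 8)
        with pytest.warns(UserWarning, match="never chosen"):
            fit_map("ordm", clipped, survey_q, max_iter=2)


class TestFitMcmc:
    @pytest.fixture(scope="class")
    def short_config(self):
        return SamplerConfig(chains=2, iterations=700, burnin=300, seed=42, loglik_thin=10)

    @pytest.fixture(scope="class")
    def small_summary(self, short_config):
        q = QMatrix(entries=np.array([[1, 0], [1, 0], [0, 1], [0, 1]]))
        rng = np.random.default_rng(4)
        params = random_natural("ordm", q, 3, rng)
        ds = generate_dataset("ordm", params, [0.3, 0.2, 0.2, 0.3], 150, 5, q)
        return q, ds, fit("ordm", ds, q, short_config)

    def test_determinism(self, small_summary, short_config):
        q, ds, summary = small_summary
        again = fit("ordm", ds, q, short_config)
        np.testing.assert_array_equal(summary.theta_draws, again.theta_draws)
        np.testing.assert_array_equal(summary.prevalence_draws, again.prevalence_draws)

    def test_draw_shapes_and_simplex(self, small_summary, short_config):
        _, ds, summary = small_summary
        chains, keep = short_config.chains, short_config.iterations - short_config.burnin
        assert summary.theta_draws.shape == (chains, keep, len(summary.param_names))
        np.testing.assert_allclose(summary.prevalence_draws.sum(axis=2), 1.0, atol=1e-9)
        assert summary.pointwise_loglik.shape[2] == ds.n_respondents

    def test_no_draw_violates_constraints(self, small_summary):
        q, _, summary = small_summary
        from orddcm.estimate import _Design

        design = _Design(summary.model_kind, q, (3, 3, 3, 3))
        lo = np.array([b[0] for b in design.bounds])
        hi = np.array([b[1] for b in design.bounds])
        flat = summary.theta_draws.reshape(-1, len(summary.param_names))
        assert (flat >= lo[None, :] - 1e-12).all() and (flat <= hi[None, :] + 1e-12).all()

    def test_summary_table(self, small_summary):
        _, _, summary = small_summary
        table = summary.summary_table()
        assert {"parameter", "mean", "sd", "rhat"} <= set(table.columns)
        assert len(table) == len(summary.param_names) + 4
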