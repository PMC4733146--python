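"""Estimation engines on small datasets: correctness, determinism, agreement."""

import numpy as np
import pandas as pd
import pytest

import multitrait as mt
from multitrait.exceptions import DomainError
from multitrait.infer import (
    fit_laplace,
    fit_mcmc,
    fit_reml,
    mc_standard_error,
)
from multitrait.model import HyperParams


@pytest.fixture(scope="module")
def univariate_data():
    """Large single-trait sample with K = I: variance components add up to
    the phenotypic variance."""
    n = 400
    rng = np.random.default_rng(8)
    ids = tuple(f"i{k}" for k in range(n))
    K = mt.RelationshipMatrix(np.eye(n), ids, "genomic")
    y = rng.normal(0.0, np.sqrt(2.0 + 1.0), size=n)  # iid: σ²_a + σ²_e = 3
    return mt.MultiTraitData(pd.DataFrame({"y": y}, index=ids), K)


@pytest.fixture(scope="module")
def bivariate_data(high_g0, high_r0):
    """One replicate of a 2-trait model on a 36-individual factorial design."""
    K = mt.build_a_matrix(mt.make_factorial_pedigree(4, 5))
    g0 = mt.TraitCovariance(high_g0.values[:2, :2], "genetic")
    r0 = mt.TraitCovariance(high_r0.values[:2, :2], "residual")
    y, truth = mt.simulate_traits(K, g0, r0, seed=21)
    return mt.MultiTraitData(y, K), truth


class TestREML:
    def test_univariate_total_variance_consistency(self, univariate_data):
        fit = fit_reml(univariate_data, n_restarts=0)
        total = fit.g0_hat.values[0, 0] + fit.r0_hat.values[0, 0]
        sample_var = float(univariate_data.phenotypes["y"].var(ddof=1))
        assert total == pytest.approx(sample_var, rel=0.05)

    def test_gradient_norm_contract(self, bivariate_data):
        data, _ = bivariate_data
        fit = fit_reml(data, n_restarts=0)
        assert fit.diagnostics["converged"]
        assert fit.diagnostics["gradient_norm"] < 1e-5

    def test_random_restarts_reach_same_optimum(self, bivariate_data):
        """The restricted likelihood is effectively unimodal at this size."""
        data, _ = bivariate_data
        base = fit_reml(data, n_restarts=0)
        jittered = fit_reml(data, n_restarts=4)
        np.testing.assert_allclose(
            base.theta_mode.to_vector(), jittered.theta_mode.to_vector(), atol=1e-4
        )

    def test_estimates_are_pd(self, bivariate_data):
        data, _ = bivariate_data
        fit = fit_reml(data, n_restarts=0)
        assert np.linalg.eigvalsh(fit.g0_hat.values)[0] > 0
        assert np.linalg.eigvalsh(fit.r0_hat.values)[0] > 0

    def test_explicit_init_is_honored(self, bivariate_data):
        data, _ = bivariate_data
        init = HyperParams(
            mt.CholeskyParams([1.0, 1.0], [0.0]), mt.CholeskyParams([1.0, 1.0], [0.0])
        )
        fit = fit_reml(data, init=init, n_restarts=0)
        assert fit.diagnostics["converged"]


class TestLaplace:
    def test_fixed_seed_is_bit_reproducible(self, bivariate_data):
        data, _ = bivariate_data
        f1 = fit_laplace(data, n_samples=500, seed=3, n_restarts=0)
        f2 = fit_laplace(data, n_samples=500, seed=3, n_restarts=0)
        np.testing.assert_array_equal(f1.theta_samples, f2.theta_samples)
        assert f1.summaries == f2.summaries

    def test_back_transformed_samples_all_pd(self, bivariate_data):
        data, _ = bivariate_data
        fit = fit_laplace(data, n_samples=500, seed=3, n_restarts=0)
        from multitrait.infer import compose_samples

        g0s, r0s = compose_samples(fit.theta_samples, 2)
        assert np.linalg.eigvalsh(g0s).min() > 0
        assert np.linalg.eigvalsh(r0s).min() > 0

    def test_intervals_bracket_point_estimates(self, bivariate_data):
        data, _ = bivariate_data
        fit = fit_laplace(data, n_samples=800, seed=5, n_restarts=0)
        for key, s in fit.summaries.items():
            assert s["lower"] <= s["upper"]
            assert s["lower"] - 1e-9 <= s["mean"] <= s["upper"] + 1e-9

    def test_zero_samples_rejected(self, bivariate_data):
        data, _ = bivariate_data
        with pytest.raises(DomainError):
            fit_laplace(data, n_samples=0, seed=0)


class TestMCMC:
    def test_fixed_seed_is_reproducible(self, bivariate_data):
        data, _ = bivariate_data
        f1 = fit_mcmc(data, n_iter=1500, n_burnin=500, seed=11)
        f2 = fit_mcmc(data, n_iter=1500, n_burnin=500, seed=11)
        np.testing.assert_array_equal(f1.theta_samples, f2.theta_samples)

    def test_acceptance_rate_in_target_band(self, bivariate_data):
        data, _ = bivariate_data
        fit = fit_mcmc(data, n_iter=4000, n_burnin=1500, seed=1)
        assert 0.1 < fit.diagnostics["acceptance_rate"] < 0.6

    def test_iterations_must_exceed_burnin(self, bivariate_data):
        data, _ = bivariate_data
        with pytest.raises(DomainError):
            fit_mcmc(data, n_iter=100, n_burnin=100, seed=0)

    def test_agrees_with_laplace_on_shared_posterior(self, high_g0, high_r0):
        """Engine cross-validation: Laplace and MCMC sample the same
        posterior, so their variance-component means agree within combined
        Monte-Carlo error.  Uses a pedigree K so that the genetic and
        residual variances are identifiable."""
        K = mt.build_a_matrix(mt.make_factorial_pedigree(10, 10))  # 120 ind
        g0 = mt.TraitCovariance(high_g0.values[:1, :1] * 2.0, "genetic")
        r0 = mt.TraitCovariance(high_r0.values[:1, :1], "residual")
        y, _ = mt.simulate_traits(K, g0, r0, seed=14)
        data = mt.MultiTraitData(y, K)
        fl = fit_laplace(data, n_samples=4000, seed=2, n_restarts=0)
        fm = fit_mcmc(data, n_iter=16_000, n_burnin=4_000, seed=2)
        from multitrait.infer import compose_samples, weighted_mc_standard_error

        g_l, r_l = compose_samples(fl.theta_samples, 1)
        g_m, r_m = compose_samples(fm.theta_samples, 1)
        w = fl.sample_weights
        for xl, xm in ((g_l[:, 0, 0], g_m[:, 0, 0]), (r_l[:, 0, 0], r_m[:, 0, 0])):
            mean_l = float(np.sum(w * xl))
            se = np.hypot(weighted_mc_standard_error(xl, w), mc_standard_error(xm))
            assert abs(mean_l - xm.mean()) < 3 * se


def test_fit_result_serialization(tmp_path, bivariate_data):
    data, _ = bivariate_data
    fit = fit_laplace(data, n_samples=200, seed=9, n_restarts=0)
    fit.to_json(tmp_path / "fit.json")
    fit.samples_to_csv(tmp_path / "samples.csv")
    import json

    payload = json.loads((tmp_path / "fit.json").read_text())
    assert payload["engine"] == "laplace"
    assert np.asarray(payload["g0_hat"]).shape == (2, 2)
    df = pd.read_csv(tmp_path / "samples.csv")
    assert list(df.columns)[:2] == ["log_sigma2_a1", "log_sigma2_a2"]
    assert len(df) == 200


def test_mc_standard_error_scaling():
    rng = np.random.default_rng(0)
    x = rng.normal(size=10_000)
    se = mc_standard_error(x)
    assert se == pytest.approx(1.0 / np.sqrt(10_000), rel=0.5)
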