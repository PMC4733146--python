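"""Collapsed Gaussian model: likelihood, posterior, and the eigen-trick."""

import numpy as np
import pytest
from scipy.special import gammaln

import multitrait as mt
from multitrait.exceptions import StructuralError
from multitrait.model import (
    HyperParams,
    MarginalCovariance,
    log_posterior,
    log_restricted_likelihood,
    marginal_covariance,
)


def theta_from(g0, r0):
    return HyperParams(mt.decompose_cov(g0), mt.decompose_cov(r0))


@pytest.fixture()
def tiny_data(high_g0, high_r0):
    """4 individuals, 2 traits — small enough for dense-matrix oracles."""
    ped = mt.Pedigree.from_records(
        [("a", None, None), ("b", None, None), ("c", "a", "b"), ("d", "a", "b")]
    )
    K = mt.build_a_matrix(ped)
    g0 = mt.TraitCovariance(high_g0.values[:2, :2], "genetic")
    r0 = mt.TraitCovariance(high_r0.values[:2, :2], "residual")
    y, _ = mt.simulate_traits(K, g0, r0, seed=77)
    return mt.MultiTraitData(y, K), g0, r0


def dense_v(theta, data):
    K = data.relmat.values
    g0 = mt.compose_cov(theta.genetic).values
    r0 = mt.compose_cov(theta.residual).values
    return np.kron(g0, K) + np.kron(r0, np.eye(data.n_ind))


def stacked(data):
    y = data.phenotypes.to_numpy().T.ravel()
    blocks = []
    t = data.n_traits
    for i, X in enumerate(data.fixed_design):
        row = [np.zeros((X.shape[0], Xj.shape[1])) for Xj in data.fixed_design]
        row[i] = X
        blocks.append(row)
    X = np.block(blocks)
    return y, X


class TestHyperParams:
    def test_transform_round_trip_exact(self):
        rng = np.random.default_rng(1)
        for t in (1, 2, 3, 4):
            m = t * (t - 1) // 2
            theta = HyperParams(
                mt.CholeskyParams(rng.uniform(0.1, 5.0, t), rng.normal(size=m)),
                mt.CholeskyParams(rng.uniform(0.1, 5.0, t), rng.normal(size=m)),
            )
            back = HyperParams.from_vector(theta.to_vector(), t)
            np.testing.assert_array_equal(back.to_vector(), theta.to_vector())

    def test_dimension_count(self):
        assert HyperParams.dimension(3) == 12
        assert HyperParams.dimension(4) == 20


class TestMarginalCovariance:
    def test_single_trait_identity_k_closed_form(self):
        n = 6
        K = mt.RelationshipMatrix(np.eye(n), tuple(f"i{k}" for k in range(n)), "genomic")
        y, _ = mt.simulate_traits(
            K,
            mt.TraitCovariance([[2.0]], "genetic"),
            mt.TraitCovariance([[3.0]], "residual"),
            seed=1,
        )
        data = mt.MultiTraitData(y, K)
        theta = HyperParams(
            mt.CholeskyParams([2.0], []), mt.CholeskyParams([3.0], [])
        )
        V = marginal_covariance(theta, data)
        assert V.logdet() == pytest.approx(n * np.log(5.0))

    def test_logdet_and_solve_match_dense(self, tiny_data):
        data, g0, r0 = tiny_data
        theta = theta_from(g0, r0)
        V = MarginalCovariance(theta, data)
        Vd = dense_v(theta, data)
        assert V.logdet() == pytest.approx(np.linalg.slogdet(Vd)[1], abs=1e-8)
        # quadratic form through the rotation equals the dense solve
        lam, Ytil, _, _ = data.rotated()
        y, _ = stacked(data)
        assert V.quad(Ytil) == pytest.approx(y @ np.linalg.solve(Vd, y), abs=1e-8)

    def test_equal_traits_are_exchangeable(self, tiny_data):
        data, _, _ = tiny_data
        v = mt.CholeskyParams([1.3, 1.3], [0.0])
        theta = HyperParams(v, mt.CholeskyParams([0.7, 0.7], [0.0]))
        V = MarginalCovariance(theta, data)
        np.testing.assert_allclose(V.blocks[:, 0, 0], V.blocks[:, 1, 1])


class TestRestrictedLikelihood:
    def test_matches_dense_gls_oracle(self, tiny_data):
        data, g0, r0 = tiny_data
        rng = np.random.default_rng(4)
        for _ in range(5):
            theta = HyperParams.from_vector(rng.normal(scale=0.5, size=6), 2)
            Vd = dense_v(theta, data)
            y, X = stacked(data)
            Vi = np.linalg.inv(Vd)
            XtVX = X.T @ Vi @ X
            beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
            r = y - X @ beta
            N, p = y.size, X.shape[1]
            ll_dense = -0.5 * (
                np.linalg.slogdet(Vd)[1]
                + np.linalg.slogdet(XtVX)[1]
                + r @ Vi @ r
                + (N - p) * np.log(2 * np.pi)
            )
            assert log_restricted_likelihood(theta, data) == pytest.approx(
                ll_dense, abs=1e-8
            )

    def test_single_trait_profile_closed_form(self):
        """K = I, intercept only, σ²_a fixed ≈ 0: REML equals the textbook
        one-variance restricted likelihood with σ² = σ²_e."""
        n = 8
        rng = np.random.default_rng(2)
        yv = rng.normal(3.0, 1.5, size=n)
        K = mt.RelationshipMatrix(np.eye(n), tuple(f"i{k}" for k in range(n)), "genomic")
        import pandas as pd

        data = mt.MultiTraitData(
            pd.DataFrame({"y": yv}, index=[f"i{k}" for k in range(n)]), K
        )
        s2 = 1.7
        theta = HyperParams(
            mt.CholeskyParams([1e-10], []), mt.CholeskyParams([s2 - 1e-10], [])
        )
        rss = np.sum((yv - yv.mean()) ** 2)
        ll_text = -0.5 * (
            (n - 1) * np.log(2 * np.pi * s2) + np.log(n) + rss / s2
        )
        assert log_restricted_likelihood(theta, data) == pytest.approx(ll_text, abs=1e-6)

    def test_translation_invariance(self, tiny_data):
        data, g0, r0 = tiny_data
        theta = theta_from(g0, r0)
        base = log_restricted_likelihood(theta, data)
        shifted = mt.MultiTraitData(data.phenotypes + 113.7, data.full_relmat)
        assert log_restricted_likelihood(theta, shifted) == pytest.approx(base, abs=1e-8)

    def test_invariant_to_relabeling_individuals(self, tiny_data):
        data, g0, r0 = tiny_data
        theta = theta_from(g0, r0)
        perm = [2, 0, 3, 1]
        pheno = data.phenotypes.iloc[perm]
        assert log_restricted_likelihood(
            theta, mt.MultiTraitData(pheno, data.full_relmat)
        ) == pytest.approx(log_restricted_likelihood(theta, data), abs=1e-8)

    def test_rank_deficient_design_rejected(self, tiny_data):
        data, _, _ = tiny_data
        bad = [np.ones((4, 2)), np.ones((4, 1))]
        with pytest.raises(StructuralError):
            mt.MultiTraitData(data.phenotypes, data.full_relmat, bad)


class TestLogPosterior:
    def test_inverse_gamma_prior_term(self, tiny_data):
        """Moving one variance from 1 to v changes the prior by the closed
        form of the inverse-Gamma(0.5, rate 0.5) log-density (+ Jacobian)."""
        data, g0, r0 = tiny_data
        theta1 = theta_from(g0, r0)

        def ig_logpdf(x):
            return 0.5 * np.log(0.5) - gammaln(0.5) - 1.5 * np.log(x) - 0.5 / x

        # analytic check of the density value quoted at σ² = 1
        assert ig_logpdf(1.0) == pytest.approx(
            0.5 * np.log(0.5) - gammaln(0.5) - 0.5
        )
        prior1 = log_posterior(theta1, data) - log_restricted_likelihood(theta1, data)
        v_new = 2.5
        g0b = g0.values.copy()
        g0b[0, 0] = v_new  # keep same dependencies: edit on the param scale
        p = mt.decompose_cov(g0)
        p2 = mt.CholeskyParams(
            np.concatenate([[v_new], p.variances[1:]]), p.dependencies
        )
        theta2 = HyperParams(p2, theta1.residual)
        prior2 = log_posterior(theta2, data) - log_restricted_likelihood(theta2, data)
        v_old = p.variances[0]
        expected = (ig_logpdf(v_new) + np.log(v_new)) - (
            ig_logpdf(v_old) + np.log(v_old)
        )
        assert prior2 - prior1 == pytest.approx(expected, abs=1e-10)

    def test_dependency_prior_is_gaussian_var10(self, tiny_data):
        data, g0, r0 = tiny_data
        p = mt.decompose_cov(g0)
        p_zero = mt.CholeskyParams(p.variances, np.zeros_like(p.dependencies))
        theta0 = HyperParams(p_zero, mt.decompose_cov(r0))
        pr0 = log_posterior(theta0, data) - log_restricted_likelihood(theta0, data)
        k = 1.7
        p_k = mt.CholeskyParams(p.variances, np.array([k, 0.0, 0.0])[: p.dependencies.size])
        theta_k = HyperParams(p_k, theta0.residual)
        pr_k = log_posterior(theta_k, data) - log_restricted_likelihood(theta_k, data)
        assert pr_k - pr0 == pytest.approx(-0.5 * k**2 / 10.0, abs=1e-10)

    def test_prior_part_is_data_independent(self, tiny_data, high_g0, high_r0):
        data, g0, r0 = tiny_data
        theta = theta_from(g0, r0)
        diff1 = log_posterior(theta, data) - log_restricted_likelihood(theta, data)
        other, _ = mt.simulate_traits(data.relmat, g0, r0, seed=123)
        data2 = mt.MultiTraitData(other, data.full_relmat)
        diff2 = log_posterior(theta, data2) - log_restricted_likelihood(theta, data2)
        assert diff1 == pytest.approx(diff2, abs=1e-10)

    def test_gaussian_beta_prior_approaches_reml(self, tiny_data):
        """The finite-variance Gaussian fixed-effect prior converges to the
        REML value (up to the flat-prior normalization) as τ → ∞."""
        data, g0, r0 = tiny_data
        theta = theta_from(g0, r0)
        reml = log_restricted_likelihood(theta, data)
        from multitrait.model import _log_marginal_gaussian_beta

        p = sum(X.shape[1] for X in data.fixed_design)
        for tau in (1e6, 1e8):
            marg = _log_marginal_gaussian_beta(theta, data, tau)
            # marginal = REML - (p/2)·log(2πτ) + o(1)
            assert marg + 0.5 * p * np.log(2 * np.pi * tau) == pytest.approx(
                reml, abs=1e-3
            )
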