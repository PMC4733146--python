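"""Collapsed Gaussian model for observed multi-trait phenotypes.

With the latent additive effects integrated out, the stacked (trait-major)
phenotype vector is Gaussian with covariance

    V(θ) = G0(θ) ⊗ K + R0(θ) ⊗ I,

where K is the relationship matrix and G0, R0 are composed from the
modified-Cholesky hyperparameters θ.  Because both Kronecker terms share
the eigenvectors of K, rotating each trait by Qᵀ (K = Q Λ Qᵀ) turns V into
n_ind independent n_traits × n_traits blocks ``λ_j G0 + R0``; the restricted
likelihood then costs O(n_ind · n_traits³) per evaluation after a single
eigendecomposition of K.

The optimizer/sampler coordinate system ("transformed scale") is the log of
each variance together with the raw (unconstrained) dependency parameters,
ordered genetic variances, genetic dependencies, residual variances,
residual dependencies.

Priors (for the Bayesian engines): inverse-Gamma(shape 0.5, rate 0.5) on
every variance component — the rate convention, i.e. density
∝ x^{-3/2} exp(-0.5/x) — and Gaussian mean 0, variance 10 on every
dependency parameter.  Fixed effects get a flat prior by default (exact
REML integration); a finite-variance Gaussian prior is available as an
option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .cholparam import CholeskyParams, compose_cov, dependency_pairs
from .exceptions import DegenerateInputError, DomainError, StructuralError
from .relmat import RelationshipMatrix

__all__ = [
    "HyperParams",
    "MultiTraitData",
    "MarginalCovariance",
    "marginal_covariance",
    "log_restricted_likelihood",
    "log_posterior",
]

DEP_PRIOR_VARIANCE = 10.0
IG_SHAPE = 0.5
IG_RATE = 0.5

_EIG_CLIP_TOL = 1e-8


@dataclass(frozen=True)
class HyperParams:
    """Genetic + residual Cholesky-scale parameters with an unconstrained view.

    The transformed vector is
    ``[log σ²_a, κ, log σ²_e, α]`` and round-trips exactly.
    """

    genetic: CholeskyParams
    residual: CholeskyParams

    def __post_init__(self) -> None:
        if self.genetic.n_traits != self.residual.n_traits:
            raise StructuralError("genetic/residual trait counts differ")

    @property
    def n_traits(self) -> int:
        return self.genetic.n_traits

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [
                np.log(self.genetic.variances),
                self.genetic.dependencies,
                np.log(self.residual.variances),
                self.residual.dependencies,
            ]
        )

    @classmethod
    def from_vector(cls, vector: np.ndarray, n_traits: int) -> "HyperParams":
        v = np.asarray(vector, dtype=float)
        m = n_traits * (n_traits - 1) // 2
        if v.size != 2 * (n_traits + m):
            raise StructuralError(
                f"expected {2 * (n_traits + m)} coordinates for {n_traits} traits, got {v.size}"
            )
        g = CholeskyParams(np.exp(v[:n_traits]), v[n_traits : n_traits + m])
        off = n_traits + m
        e = CholeskyParams(np.exp(v[off : off + n_traits]), v[off + n_traits :])
        return cls(g, e)

    @classmethod
    def dimension(cls, n_traits: int) -> int:
        return 2 * (n_traits + n_traits * (n_traits - 1) // 2)

    def to_dict(self) -> dict[str, float]:
        return {**self.genetic.to_dict("a"), **self.residual.to_dict("e")}


class MultiTraitData:
    """Phenotypes, per-trait fixed-effect designs and a relationship matrix.

    Only complete cases are analyzed: rows with any missing trait value are
    dropped (the count is kept in ``n_dropped``).  Fixed-effect designs
    default to a per-trait intercept.
    """

    def __init__(
        self,
        phenotypes: pd.DataFrame,
        relmat: RelationshipMatrix,
        fixed_design: Sequence[np.ndarray] | None = None,
    ) -> None:
        pheno = phenotypes.copy()
        pheno.index = pheno.index.astype(str)
        complete = pheno.dropna()
        self.n_dropped = len(pheno) - len(complete)
        if complete.empty:
            raise DegenerateInputError("no complete-case phenotype rows")
        unknown = set(complete.index) - set(relmat.ids)
        if unknown:
            raise StructuralError(
                f"phenotyped ids missing from relationship matrix: {sorted(unknown)[:5]}"
            )
        self.phenotypes = complete
        self.trait_names = tuple(str(c) for c in complete.columns)
        self.ids = tuple(complete.index)
        if tuple(relmat.ids) == self.ids:
            self.relmat = relmat
        else:
            self.relmat = relmat.subset(self.ids)
        self.full_relmat = relmat
        n, t = complete.shape
        if fixed_design is None:
            fixed_design = [np.ones((n, 1)) for _ in range(t)]
        if len(fixed_design) != t:
            raise StructuralError("one fixed-effect design per trait is required")
        designs = []
        for i, X in enumerate(fixed_design):
            X = np.asarray(X, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            if X.shape[0] != n:
                raise StructuralError(f"design for trait {i + 1} has wrong row count")
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise StructuralError(f"design for trait {i + 1} is rank deficient")
            designs.append(X)
        self.fixed_design = designs
        self._rotated: tuple | None = None

    @property
    def n_ind(self) -> int:
        return len(self.ids)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def single_trait(self, trait: int) -> "MultiTraitData":
        """A univariate view of one trait (shares the relationship matrix)."""
        return MultiTraitData(
            self.phenotypes.iloc[:, [trait]],
            self.relmat,
            [self.fixed_design[trait]],
        )

    # -- cached spectral rotation ------------------------------------------

    def rotated(self):
        """(λ, Ỹ, X̃, p_slices): eigenvalues of K, rotated phenotypes and designs.

        Computed once per data object; the eigendecomposition itself is
        cached on the relationship-matrix instance so that replicates and
        univariate initializer fits sharing a K pay for it once.
        """
        if self._rotated is None:
            lam, Q = _relmat_eigh(self.relmat)
            Y = self.phenotypes.to_numpy(dtype=float)
            Ytil = Q.T @ Y
            p_sizes = [X.shape[1] for X in self.fixed_design]
            p_total = sum(p_sizes)
            n, t = Y.shape
            Xtil = np.zeros((n, t, p_total))
            slices = []
            off = 0
            for i, X in enumerate(self.fixed_design):
                sl = slice(off, off + p_sizes[i])
                Xtil[:, i, sl] = Q.T @ X
                slices.append(sl)
                off += p_sizes[i]
            self._rotated = (lam, Ytil, Xtil, tuple(slices))
        return self._rotated


def _relmat_eigh(rm: RelationshipMatrix) -> tuple[np.ndarray, np.ndarray]:
    cached = getattr(rm, "_eigh_cache", None)
    if cached is None:
        lam, Q = np.linalg.eigh(rm.values)
        if lam.min() < -_EIG_CLIP_TOL * max(1.0, lam.max()):
            raise DomainError("relationship matrix is not PSD")
        lam = np.clip(lam, 0.0, None)
        cached = (lam, Q)
        object.__setattr__(rm, "_eigh_cache", cached)
    return cached


class MarginalCovariance:
    """log-determinant and linear solves with V(θ) in the rotated basis.

    V block-diagonalizes into one n_traits × n_traits block per eigenvalue
    of K: ``M_j = λ_j G0 + R0``.  ``solve`` operates on arrays indexed
    (eigen-index, trait, ...).
    """

    def __init__(self, theta: HyperParams, data: MultiTraitData) -> None:
        lam, _, _, _ = data.rotated()
        g0 = compose_cov(theta.genetic, "genetic").values
        r0 = compose_cov(theta.residual, "residual").values
        blocks = lam[:, None, None] * g0 + r0
        try:
            chol = np.linalg.cholesky(blocks)
        except np.linalg.LinAlgError:
            raise DomainError(
                "marginal covariance block not PD: internal consistency failure"
            ) from None
        self.blocks = blocks
        self._chol = chol
        self.n_traits = g0.shape[0]

    def logdet(self) -> float:
        return float(2.0 * np.sum(np.log(np.diagonal(self._chol, axis1=1, axis2=2))))

    def solve(self, B: np.ndarray) -> np.ndarray:
        """V⁻¹ B for B of shape (n, t) or (n, t, k), in the rotated basis."""
        squeeze = B.ndim == 2
        rhs = B[..., None] if squeeze else B
        out = np.linalg.solve(self.blocks, rhs)
        return out[..., 0] if squeeze else out

    def quad(self, b: np.ndarray) -> float:
        """bᵀ V⁻¹ b for a rotated (n, t) array."""
        return float(np.sum(b * self.solve(b)))


def marginal_covariance(theta: HyperParams, data: MultiTraitData) -> MarginalCovariance:
    """The stacked covariance contract for V(θ) = G0⊗K + R0⊗I."""
    return MarginalCovariance(theta, data)


def _gls_pieces(theta: HyperParams, data: MultiTraitData):
    """Shared GLS quantities: V, XᵀV⁻¹X, XᵀV⁻¹y, yᵀV⁻¹y, β̂."""
    lam, Ytil, Xtil, _ = data.rotated()
    V = MarginalCovariance(theta, data)
    ViX = V.solve(Xtil)  # (n, t, p)
    Viy = V.solve(Ytil)  # (n, t)
    XtVX = np.einsum("ntp,ntq->pq", Xtil, ViX)
    XtVy = np.einsum("ntp,nt->p", Xtil, Viy)
    yVy = float(np.sum(Ytil * Viy))
    beta = np.linalg.solve(XtVX, XtVy)
    return V, XtVX, XtVy, yVy, beta


def log_restricted_likelihood(theta: HyperParams, data: MultiTraitData) -> float:
    """Patterson–Thompson restricted log-likelihood of the collapsed model.

    ℓ_R(θ) = -½ [ log|V| + log|XᵀV⁻¹X| + yᵀPy + (N-p) log 2π ],
    with P the REML projector; invariant to translating y within col(X).
    """
    V, XtVX, XtVy, yVy, beta = _gls_pieces(theta, data)
    sign, logdet_xvx = np.linalg.slogdet(XtVX)
    if sign <= 0:
        raise StructuralError("XᵀV⁻¹X is singular; fixed-effect design is deficient")
    quad = yVy - float(XtVy @ beta)  # = yᵀPy
    N = data.n_ind * data.n_traits
    p = XtVX.shape[0]
    return -0.5 * (V.logdet() + logdet_xvx + quad + (N - p) * np.log(2.0 * np.pi))


def _log_marginal_gaussian_beta(
    theta: HyperParams, data: MultiTraitData, beta_prior_variance: float
) -> float:
    """Marginal log-likelihood with β ~ N(0, τI) integrated out exactly.

    y ~ N(0, V + τ X Xᵀ); evaluated by Woodbury using the same GLS pieces.
    """
    tau = float(beta_prior_variance)
    V, XtVX, XtVy, yVy, _ = _gls_pieces(theta, data)
    p = XtVX.shape[0]
    Ainner = XtVX + np.eye(p) / tau
    sign, logdet_inner = np.linalg.slogdet(Ainner)
    if sign <= 0:
        raise StructuralError("degenerate fixed-effect prior system")
    quad = yVy - float(XtVy @ np.linalg.solve(Ainner, XtVy))
    N = data.n_ind * data.n_traits
    return -0.5 * (
        V.logdet() + logdet_inner + p * np.log(tau) + quad + N * np.log(2.0 * np.pi)
    )


def _log_invgamma(x: np.ndarray, shape: float, rate: float) -> np.ndarray:
    return shape * np.log(rate) - gammaln(shape) - (shape + 1.0) * np.log(x) - rate / x


def log_posterior(
    theta: HyperParams,
    data: MultiTraitData,
    dep_prior_variance: float = DEP_PRIOR_VARIANCE,
    ig_shape: float = IG_SHAPE,
    ig_rate: float = IG_RATE,
    beta_prior_variance: float | None = None,
) -> float:
    """Log posterior of the hyperparameters on the transformed scale.

    Restricted likelihood (flat-β limit; or exact Gaussian-β marginal when
    ``beta_prior_variance`` is given) plus inverse-Gamma log-priors on the
    variances, Gaussian log-priors on the dependencies, and the log-Jacobian
    of the log-variance transform (+log σ² per variance).
    """
    if beta_prior_variance is None:
        ll = log_restricted_likelihood(theta, data)
    else:
        ll = _log_marginal_gaussian_beta(theta, data, beta_prior_variance)
    variances = np.concatenate([theta.genetic.variances, theta.residual.variances])
    deps = np.concatenate([theta.genetic.dependencies, theta.residual.dependencies])
    prior = float(np.sum(_log_invgamma(variances, ig_shape, ig_rate)))
    prior += float(np.sum(np.log(variances)))  # Jacobian of log-variance transform
    if deps.size:
        prior += float(
            np.sum(
                -0.5 * (np.log(2.0 * np.pi * dep_prior_variance) + deps**2 / dep_prior_variance)
            )
        )
    return ll + prior
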