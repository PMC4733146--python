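"""Modified-Cholesky (LDLᵀ) parameterization of trait covariance matrices.

A trait covariance matrix ``C`` (genetic ``G0`` or residual ``R0``) is
written as ``C = L D Lᵀ`` with ``L`` unit lower triangular and ``D``
diagonal and positive.  The diagonal of ``D`` holds per-trait variances on
the transformed scale (σ²_a or σ²_e) and the strictly-lower entries of
``L`` are unconstrained *dependency* parameters (κ for the genetic side, α
for the residual side).  Any real dependency values combined with positive
variances give a valid (symmetric positive-definite) covariance matrix, so
estimation can run on an unconstrained parameter space.

For three traits the map is, entrywise,

    c11 = d1            c21 = κ12 d1                 c31 = κ13 d1
    c22 = κ12² d1 + d2  c32 = κ12 κ13 d1 + κ23 d2    c33 = κ13² d1 + κ23² d2 + d3

and the inverse (``decompose_cov``) solves these pivot by pivot.

Dependency parameters are ordered κ_{1,2}, κ_{1,3}, κ_{2,3}, ... — column
by column down the strictly-lower triangle of ``L`` — and are serialized in
that order everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .exceptions import DegenerateInputError, DomainError, StructuralError

__all__ = [
    "TraitCovariance",
    "CholeskyParams",
    "TransformOperator",
    "dependency_pairs",
    "compose_cov",
    "decompose_cov",
    "build_w",
    "back_transform",
    "summarize_scalar",
]


def dependency_pairs(n_traits: int) -> list[tuple[int, int]]:
    """0-based (j, i) index pairs, j < i, in serialization order.

    For n=3: (0,1), (0,2), (1,2) — i.e. κ_{1,2}, κ_{1,3}, κ_{2,3}.
    """
    return [(j, i) for j in range(n_traits) for i in range(j + 1, n_traits)]


@dataclass(frozen=True)
class TraitCovariance:
    """Symmetric positive-definite among-trait covariance matrix."""

    values: np.ndarray
    role: str = "genetic"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.role not in ("genetic", "residual"):
            raise StructuralError(f"unknown covariance role {self.role!r}")
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise StructuralError("trait covariance must be square")
        if not np.allclose(values, values.T, atol=1e-8):
            raise DomainError("trait covariance is not symmetric")
        try:
            np.linalg.cholesky(values)
        except np.linalg.LinAlgError:
            raise DomainError("trait covariance is not positive definite") from None

    @property
    def n_traits(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class CholeskyParams:
    """Per-trait variances plus strictly-lower-triangular dependencies."""

    variances: np.ndarray
    dependencies: np.ndarray

    def __post_init__(self) -> None:
        variances = np.atleast_1d(np.asarray(self.variances, dtype=float))
        dependencies = np.atleast_1d(np.asarray(self.dependencies, dtype=float)) \
            if np.size(self.dependencies) else np.empty(0)
        object.__setattr__(self, "variances", variances)
        object.__setattr__(self, "dependencies", dependencies)
        n = variances.size
        if np.any(variances <= 0.0):
            raise DomainError("variances must be strictly positive")
        expected = n * (n - 1) // 2
        if dependencies.size != expected:
            raise StructuralError(
                f"{n} traits require {expected} dependency parameters, got {dependencies.size}"
            )

    @property
    def n_traits(self) -> int:
        return self.variances.size

    def unit_lower(self) -> np.ndarray:
        """The unit-lower-triangular factor L with dependencies below the diagonal."""
        n = self.n_traits
        L = np.eye(n)
        for k, (j, i) in enumerate(dependency_pairs(n)):
            L[i, j] = self.dependencies[k]
        return L

    def to_dict(self, prefix: str = "a") -> dict[str, float]:
        """Flat named-value form, e.g. a1_var, ..., dep_g_1_2, ... (1-based)."""
        dep_tag = {"a": "g", "e": "e"}.get(prefix, prefix)
        out = {f"{prefix}{i + 1}_var": float(v) for i, v in enumerate(self.variances)}
        for k, (j, i) in enumerate(dependency_pairs(self.n_traits)):
            out[f"dep_{dep_tag}_{j + 1}_{i + 1}"] = float(self.dependencies[k])
        return out

    @classmethod
    def from_dict(cls, values: dict[str, float], prefix: str = "a") -> "CholeskyParams":
        """Inverse of :meth:`to_dict`."""
        dep_tag = {"a": "g", "e": "e"}.get(prefix, prefix)
        n = sum(1 for k in values if k.startswith(prefix) and k.endswith("_var"))
        variances = np.array([values[f"{prefix}{i + 1}_var"] for i in range(n)])
        deps = np.array(
            [values[f"dep_{dep_tag}_{j + 1}_{i + 1}"] for j, i in dependency_pairs(n)]
        )
        return cls(variances, deps)


@dataclass(frozen=True)
class TransformOperator:
    """The stacked Cholesky factor ``W = L ⊗ I_{n_ind}``.

    ``apply`` acts on a trait-major stacked vector (n_traits blocks of
    length n_ind) without materializing the Kronecker product.
    """

    factor: np.ndarray  # unit lower triangular, n_traits x n_traits
    n_ind: int

    def __post_init__(self) -> None:
        factor = np.asarray(self.factor, dtype=float)
        object.__setattr__(self, "factor", factor)
        if self.n_ind < 1:
            raise StructuralError("n_ind must be >= 1")
        if not np.allclose(np.diag(factor), 1.0):
            raise StructuralError("transform factor must have unit diagonal")
        if np.any(np.triu(factor, 1) != 0.0):
            raise StructuralError("transform factor must be lower triangular")

    @property
    def n_traits(self) -> int:
        return self.factor.shape[0]

    def apply(self, stacked: np.ndarray) -> np.ndarray:
        """Apply ``(L ⊗ I)`` to a stacked vector of n_traits·n_ind values."""
        x = np.asarray(stacked, dtype=float)
        if x.shape[0] != self.n_traits * self.n_ind:
            raise StructuralError(
                f"stacked vector length {x.shape[0]} != n_traits*n_ind "
                f"({self.n_traits}*{self.n_ind})"
            )
        blocks = x.reshape(self.n_traits, self.n_ind, *x.shape[1:])
        out = np.einsum("tj,j...->t...", self.factor, blocks)
        return out.reshape(x.shape)

    def dense(self) -> np.ndarray:
        """Materialized ``L ⊗ I`` (small problems / testing only)."""
        return np.kron(self.factor, np.eye(self.n_ind))


def compose_cov(params: CholeskyParams, role: str = "genetic") -> TraitCovariance:
    """Map Cholesky-scale parameters to the original-scale covariance L D Lᵀ.

    Positive definite by construction for any real dependency values.
    """
    L = params.unit_lower()
    values = (L * params.variances) @ L.T
    return TraitCovariance(values, role=role)


def decompose_cov(cov: TraitCovariance | np.ndarray) -> CholeskyParams:
    """Unique Cholesky-scale parameters of a PD covariance matrix.

    Inverse of :func:`compose_cov`; equals the closed-form back-transform
    identities solved for (σ², κ) pivot by pivot.
    """
    values = cov.values if isinstance(cov, TraitCovariance) else np.asarray(cov, float)
    if not np.allclose(values, values.T, atol=1e-8):
        raise DomainError("covariance is not symmetric")
    try:
        chol = np.linalg.cholesky(values)
    except np.linalg.LinAlgError:
        raise DomainError(
            "covariance is not positive definite (non-positive pivot)"
        ) from None
    diag = np.diag(chol)
    L = chol / diag  # unit lower triangular
    variances = diag**2
    n = values.shape[0]
    deps = np.array([L[i, j] for j, i in dependency_pairs(n)])
    return CholeskyParams(variances, deps)


def build_w(params: CholeskyParams, n_ind: int) -> TransformOperator:
    """Stacked transform ``W = L ⊗ I`` mixing per-trait effect vectors."""
    return TransformOperator(params.unit_lower(), n_ind)


def back_transform(theta_samples: Iterable) -> list[tuple[TraitCovariance, TraitCovariance]]:
    """Map hyperparameter samples to original-scale (G0, R0) pairs.

    Each sample must expose ``genetic`` and ``residual`` CholeskyParams
    (e.g. :class:`multitrait.model.HyperParams`).  Order is preserved; every
    output matrix is PD by construction.
    """
    out = [
        (compose_cov(s.genetic, "genetic"), compose_cov(s.residual, "residual"))
        for s in theta_samples
    ]
    if not out:
        raise DegenerateInputError("back_transform needs at least one sample")
    return out


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: np.ndarray) -> np.ndarray:
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cw = np.cumsum(ws) - 0.5 * ws
    return np.interp(q, cw / np.sum(ws), xs)


def summarize_scalar(
    samples: Sequence[float], weights: Sequence[float] | None = None
) -> dict[str, float]:
    """Mean, kernel-density mode and equal-tail 95% interval of a scalar
    sample, optionally importance-weighted."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise DegenerateInputError("empty sample")
    if weights is None:
        w = np.full(x.size, 1.0 / x.size)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / np.sum(w)
    mean = float(np.sum(w * x))
    lo, hi = (float(q) for q in _weighted_quantile(x, w, np.array([0.025, 0.975])))
    if np.ptp(x) < 1e-12 * max(1.0, abs(mean)):
        mode = float(x[0])
    elif x.size < 3:
        mode = mean
    else:
        kde = gaussian_kde(x, bw_method="silverman", weights=w)
        grid = np.linspace(x.min(), x.max(), 512)
        mode = float(grid[np.argmax(kde(grid))])
    return {"mean": mean, "mode": mode, "lower": lo, "upper": hi}
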