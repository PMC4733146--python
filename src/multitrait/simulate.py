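"""Simulation of correlated traits under the animal model.

The study design simulated here is a factorial mating scheme: a base
population of unrelated lines in which every seed parent is crossed with
every pollen donor, giving one offspring per pair.  Phenotypes for all
individuals (base population included) are drawn as ``y = a + e`` with

    a ~ MVN(0, G0 ⊗ K)   and   e ~ MVN(0, R0 ⊗ I),

sampled through Cholesky factors: ``a = P z_a`` with ``P Pᵀ = G0 ⊗ K`` and
``e = T z_e`` with ``T Tᵀ = R0 ⊗ I``.  The Kronecker factor is never formed
at full size: ``chol(G0 ⊗ K) = chol(G0) ⊗ chol(K)``, applied as a matrix
product on an n_ind × n_traits noise matrix.

Two bundled scenarios reproduce the published simulation designs:

* ``high_heritability`` — h² ≈ (0.50, 0.60, 0.71), all-positive covariances;
* ``low_heritability`` — h² ≈ (0.20, 0.20, 0.22) with negative covariances.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cholparam import TraitCovariance
from .exceptions import DomainError
from .relmat import Pedigree, RelationshipMatrix

__all__ = [
    "SimTruth",
    "Scenario",
    "make_factorial_pedigree",
    "simulate_traits",
    "implied_heritability",
    "implied_correlations",
    "load_scenario",
]


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated replicate (phenotype = BV + residual)."""

    true_breeding_values: pd.DataFrame  # n_ind x n_traits
    true_residuals: pd.DataFrame
    g0: TraitCovariance
    r0: TraitCovariance
    seed: int


@dataclass(frozen=True)
class Scenario:
    """A replicate-study configuration: trait covariances plus mating design."""

    name: str
    g0: TraitCovariance
    r0: TraitCovariance
    n_seed: int = 25
    n_pollen: int = 25
    n_replicates: int = 50
    base_seed: int = 2015

    @property
    def trait_names(self) -> tuple[str, ...]:
        return tuple(f"trait{i + 1}" for i in range(self.g0.n_traits))

    def pedigree(self) -> Pedigree:
        return make_factorial_pedigree(self.n_seed, self.n_pollen)

    @classmethod
    def from_dict(cls, cfg: dict) -> "Scenario":
        return cls(
            name=str(cfg["name"]),
            g0=TraitCovariance(np.asarray(cfg["g0"], dtype=float), "genetic"),
            r0=TraitCovariance(np.asarray(cfg["r0"], dtype=float), "residual"),
            n_seed=int(cfg.get("n_seed", 25)),
            n_pollen=int(cfg.get("n_pollen", 25)),
            n_replicates=int(cfg.get("n_replicates", 50)),
            base_seed=int(cfg.get("base_seed", 2015)),
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "g0": self.g0.values.tolist(),
            "r0": self.r0.values.tolist(),
            "n_seed": self.n_seed,
            "n_pollen": self.n_pollen,
            "n_replicates": self.n_replicates,
            "base_seed": self.base_seed,
        }


def load_scenario(name_or_path: str | Path) -> Scenario:
    """Load a scenario by bundled name (``high_heritability``,
    ``low_heritability``) or from a YAML file path."""
    candidate = Path(str(name_or_path))
    if candidate.suffix in (".yaml", ".yml") and candidate.exists():
        cfg = yaml.safe_load(candidate.read_text())
    else:
        ref = resources.files("multitrait") / "scenarios" / f"{name_or_path}.yaml"
        try:
            cfg = yaml.safe_load(ref.read_text())
        except FileNotFoundError:
            raise FileNotFoundError(
                f"no bundled scenario or YAML file named {name_or_path!r}"
            ) from None
    return Scenario.from_dict(cfg)


def make_factorial_pedigree(n_seed: int, n_pollen: int) -> Pedigree:
    """Factorial mating design: every seed parent crossed with every pollen donor.

    Returns n_seed + n_pollen unrelated founders followed by
    n_seed * n_pollen offspring (one per cross) in deterministic order.
    """
    if n_seed < 1 or n_pollen < 1:
        raise DomainError("n_seed and n_pollen must be >= 1")
    records: list[tuple[str, str | None, str | None]] = []
    seeds = [f"S{i + 1}" for i in range(n_seed)]
    pollens = [f"P{j + 1}" for j in range(n_pollen)]
    for ind in seeds + pollens:
        records.append((ind, None, None))
    for i, s in enumerate(seeds):
        for j, p in enumerate(pollens):
            records.append((f"O{i + 1}_{j + 1}", s, p))
    return Pedigree.from_records(records)


def _psd_cholesky(K: np.ndarray) -> np.ndarray:
    """Cholesky-like factor of a PSD matrix (eigen fallback for singular K)."""
    try:
        return np.linalg.cholesky(K)
    except np.linalg.LinAlgError:
        w, Q = np.linalg.eigh(K)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise DomainError("relationship matrix is not PSD") from None
        return Q * np.sqrt(np.clip(w, 0.0, None))


def simulate_traits(
    K: RelationshipMatrix,
    g0: TraitCovariance,
    r0: TraitCovariance,
    seed: int,
    fixed_effects: np.ndarray | None = None,
    trait_names: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Draw one replicate of correlated phenotypes ``y = a + e``.

    ``fixed_effects`` (n_ind × n_traits, optional) is added to the phenotype
    to exercise fixed-effect estimation; the published designs use none.
    Fully reproducible given ``seed``.
    """
    if g0.n_traits != r0.n_traits:
        raise DomainError("g0 and r0 have different numbers of traits")
    n, t = K.n_ind, g0.n_traits
    names = trait_names or tuple(f"trait{i + 1}" for i in range(t))
    rng = np.random.default_rng(seed)
    Lk = _psd_cholesky(K.values)
    Lg = np.linalg.cholesky(g0.values)
    Lr = np.linalg.cholesky(r0.values)
    # a = (chol(G0) ⊗ chol(K)) z_a, written columnwise: A = Lk Z Lgᵀ gives
    # Cov(vec(A)) = G0 ⊗ K for trait-major stacking.
    z_a = rng.standard_normal((n, t))
    z_e = rng.standard_normal((n, t))
    a = Lk @ z_a @ Lg.T
    e = z_e @ Lr.T
    y = a + e
    if fixed_effects is not None:
        fixed = np.asarray(fixed_effects, dtype=float)
        if fixed.shape != (n, t):
            raise DomainError("fixed_effects must be n_ind x n_traits")
        y = y + fixed
    ids = list(K.ids)
    phenotypes = pd.DataFrame(y, index=ids, columns=list(names))
    phenotypes.index.name = "id"
    truth = SimTruth(
        true_breeding_values=pd.DataFrame(a, index=ids, columns=list(names)),
        true_residuals=pd.DataFrame(e, index=ids, columns=list(names)),
        g0=g0,
        r0=r0,
        seed=int(seed),
    )
    return phenotypes, truth


def implied_heritability(g0: TraitCovariance, r0: TraitCovariance) -> np.ndarray:
    """Per-trait narrow-sense heritability h²_i = g_ii / (g_ii + r_ii)."""
    if g0.n_traits != r0.n_traits:
        raise DomainError("g0 and r0 have different numbers of traits")
    va = np.diag(g0.values)
    ve = np.diag(r0.values)
    return va / (va + ve)


def implied_correlations(cov: TraitCovariance | np.ndarray) -> np.ndarray:
    """Correlation matrix r_ij = c_ij / sqrt(c_ii c_jj) of a PD covariance."""
    values = cov.values if isinstance(cov, TraitCovariance) else np.asarray(cov, float)
    sd = np.sqrt(np.diag(values))
    corr = values / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return corr
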