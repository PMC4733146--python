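"""Relationship matrices for the animal model.

The genetic covariance of a multi-trait animal model is ``G0 ⊗ K`` where
``K`` is an individual-by-individual relatedness matrix: either the
pedigree-derived additive (numerator) relationship matrix ``A`` or a
marker-derived genomic relationship matrix ``M``.  This module builds both
and provides plain-text (CSV) round-tripping for pedigrees, marker matrices
and the relationship matrices themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, DomainError, StructuralError

__all__ = [
    "Pedigree",
    "RelationshipMatrix",
    "MarkerMatrix",
    "build_a_matrix",
    "build_grm",
]

#: tokens treated as "parent unknown" in pedigree files
_MISSING_TOKENS = {"", "0", "na", "nan", "none", ".", "-"}

_PSD_TOL = 1e-8


def _normalize_parent(token) -> str | None:
    if token is None:
        return None
    if isinstance(token, float) and np.isnan(token):
        return None
    s = str(token).strip()
    if s.lower() in _MISSING_TOKENS:
        return None
    return s


@dataclass(frozen=True)
class Pedigree:
    """An ordered pedigree: (id, sire, dam) with parents listed before offspring.

    Construct through :meth:`from_records` (or :meth:`from_csv`), which
    normalizes missing-parent tokens, topologically sorts the records and
    rejects cycles and unknown parent ids.
    """

    records: tuple[tuple[str, str | None, str | None], ...]

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        for idx, (ind, sire, dam) in enumerate(self.records):
            if ind in seen:
                raise StructuralError(f"duplicate individual id {ind!r}")
            for parent in (sire, dam):
                if parent is not None and parent not in seen:
                    raise StructuralError(
                        f"parent {parent!r} of {ind!r} is unknown or listed after its offspring"
                    )
            seen[ind] = idx

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[object, object, object]]
    ) -> "Pedigree":
        """Build a pedigree from (id, sire, dam) triples, reordering if needed.

        Raises
        ------
        StructuralError
            If an individual appears twice, a parent id never appears as an
            individual, or the parent relation is cyclic.
        """
        raw = [
            (str(i).strip(), _normalize_parent(s), _normalize_parent(d))
            for i, s, d in records
        ]
        ids = [r[0] for r in raw]
        id_set = set(ids)
        if len(id_set) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise StructuralError(f"duplicate individual id {dup!r}")
        for ind, sire, dam in raw:
            for parent in (sire, dam):
                if parent is not None and parent not in id_set:
                    raise StructuralError(
                        f"unknown parent id {parent!r} (offspring {ind!r})"
                    )
        # Kahn's algorithm, stable in input order, detects cycles.
        by_id = {r[0]: r for r in raw}
        n_parents_pending = {
            ind: sum(p is not None for p in (s, d)) for ind, s, d in raw
        }
        children: dict[str, list[str]] = {i: [] for i in ids}
        for ind, sire, dam in raw:
            for parent in {p for p in (sire, dam) if p is not None}:
                children[parent].append(ind)
        ready = [i for i in ids if n_parents_pending[i] == 0]
        ordered: list[tuple[str, str | None, str | None]] = []
        placed: set[str] = set()
        while ready:
            ind = ready.pop(0)
            ordered.append(by_id[ind])
            placed.add(ind)
            for child in children[ind]:
                sire, dam = by_id[child][1], by_id[child][2]
                if all(p is None or p in placed for p in (sire, dam)) and child not in placed:
                    if child not in ready:
                        ready.append(child)
        if len(ordered) != len(raw):
            cyclic = sorted(id_set - placed)
            raise StructuralError(f"cyclic pedigree involving ids {cyclic}")
        return cls(tuple(ordered))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Pedigree":
        """Read a pedigree CSV with columns id, sire, dam (0/empty = unknown)."""
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        required = {"id", "sire", "dam"}
        if not required.issubset(df.columns):
            raise StructuralError(
                f"pedigree file must have columns id,sire,dam; got {list(df.columns)}"
            )
        return cls.from_records(df[["id", "sire", "dam"]].itertuples(index=False))

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.records, columns=["id", "sire", "dam"])
        df = df.fillna("0").replace({None: "0"})
        df.to_csv(path, index=False)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r[0] for r in self.records)

    @property
    def founders(self) -> tuple[str, ...]:
        return tuple(r[0] for r in self.records if r[1] is None and r[2] is None)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class RelationshipMatrix:
    """Symmetric PSD relatedness matrix with individual labels.

    ``kind`` is ``"pedigree"`` for the additive relationship matrix A
    (diagonal entries 1 + inbreeding coefficient, hence >= 1) or
    ``"genomic"`` for a marker-derived realized relationship matrix.
    """

    values: np.ndarray
    ids: tuple[str, ...]
    kind: str = "pedigree"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        n = len(self.ids)
        if values.shape != (n, n):
            raise StructuralError(
                f"matrix shape {values.shape} does not match {n} ids"
            )
        if self.kind not in ("pedigree", "genomic"):
            raise StructuralError(f"unknown relationship-matrix kind {self.kind!r}")
        if not np.allclose(values, values.T, atol=1e-8):
            raise DomainError("relationship matrix is not symmetric")
        min_eig = float(np.linalg.eigvalsh(values)[0])
        if min_eig < -_PSD_TOL:
            raise DomainError(
                f"relationship matrix is not PSD (min eigenvalue {min_eig:.3e})"
            )
        if self.kind == "pedigree" and np.any(np.diag(values) < 1.0 - 1e-10):
            raise DomainError("pedigree relationship matrix has a diagonal entry < 1")

    @property
    def n_ind(self) -> int:
        return len(self.ids)

    def subset(self, ids: Sequence[str]) -> "RelationshipMatrix":
        """Restrict (and reorder) to the given individual ids."""
        index = {ind: i for i, ind in enumerate(self.ids)}
        try:
            idx = np.array([index[str(i)] for i in ids], dtype=int)
        except KeyError as err:
            raise StructuralError(f"id {err.args[0]!r} not in relationship matrix") from None
        return RelationshipMatrix(self.values[np.ix_(idx, idx)], tuple(ids), self.kind)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids)).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, kind: str = "pedigree") -> "RelationshipMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), tuple(str(i) for i in df.index), kind)


@dataclass(frozen=True)
class MarkerMatrix:
    """Biallelic genotypes coded -1/0/1 (copies of the minor allele minus one).

    Missing genotypes are NaN and are mean-imputed per marker before the
    genomic relationship matrix is formed.
    """

    values: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        if values.ndim != 2 or values.shape[0] != len(self.ids):
            raise StructuralError("marker matrix must be n_ind x n_markers")
        observed = values[~np.isnan(values)]
        if not np.isin(observed, (-1.0, 0.0, 1.0)).all():
            raise DomainError("marker codes must be -1, 0 or 1")
        if np.isnan(values).all(axis=0).any():
            raise DegenerateInputError("marker column with no observed genotypes")

    @classmethod
    def from_csv(cls, path: str | Path) -> "MarkerMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), tuple(str(i) for i in df.index))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=list(self.ids)).to_csv(path)


def build_a_matrix(pedigree: Pedigree) -> RelationshipMatrix:
    """Additive relationship matrix by the tabular method.

    Processing individuals parents-first,

    * ``A[i, j] = 0.5 * (A[j, sire(i)] + A[j, dam(i)])`` for earlier ``j``
      (a missing parent contributes 0), and
    * ``A[i, i] = 1 + 0.5 * A[sire(i), dam(i)]`` (0 if either parent missing),

    so founders are mutually unrelated with diagonal 1 and the diagonal of an
    inbred individual is 1 + F.
    """
    records = pedigree.records
    index = {ind: i for i, (ind, _, _) in enumerate(records)}
    n = len(records)
    A = np.zeros((n, n))
    for i, (_, sire, dam) in enumerate(records):
        si = index[sire] if sire is not None else None
        di = index[dam] if dam is not None else None
        row = np.zeros(i)
        if si is not None:
            row += A[:i, si]
        if di is not None:
            row += A[:i, di]
        A[:i, i] = A[i, :i] = 0.5 * row
        A[i, i] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
    return RelationshipMatrix(A, pedigree.ids, kind="pedigree")


def build_grm(markers: MarkerMatrix, jitter: float = 0.0) -> RelationshipMatrix:
    """Genomic relationship matrix: centered cross-product over 2*sum p(1-p).

    ``M = C Cᵀ / d`` with ``C`` the column-centered genotype matrix and
    ``d = 2 Σ_k p_k (1 - p_k)``, allele frequencies estimated from the sample
    (VanRaden's first method).  Missing genotypes are mean-imputed per marker
    before centering.  ``jitter`` adds the given constant to the diagonal for
    near-singular matrices; default 0 (no silent regularization).
    """
    X = markers.values.copy()
    if X.shape[0] < 2:
        raise DegenerateInputError("GRM needs at least two individuals")
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    p = (col_mean + 1.0) / 2.0  # allele frequency per marker
    d = 2.0 * np.sum(p * (1.0 - p))
    if d <= 0.0:
        raise DegenerateInputError("all markers are monomorphic; GRM denominator is 0")
    C = X - col_mean
    M = C @ C.T / d
    if jitter:
        M = M + jitter * np.eye(M.shape[0])
    return RelationshipMatrix(M, markers.ids, kind="genomic")
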