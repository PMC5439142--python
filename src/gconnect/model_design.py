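"""Design matrices for the animal model.

The fixed-effect design is split into X1, the pure 0/1 incidence of
contemporary group (the intercept is absorbed into it, so no level is
dropped), and X2, every other fixed effect: categorical factors in drop-first
(treatment) coding against the absorbed intercept, plus continuous covariates,
optionally centred and/or standardised on the dataset-wide mean.  Z is the
record-to-animal incidence over the full ordered pedigree.  Keeping X1 a pure
incidence matrix is what makes (X1'X1)^-1 X1'Z the record-weighted
group-averaging operator that the PEVMean identities rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pedigree import Pedigree


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class Covariate:
    name: str
    centre: bool = False
    standardise: bool = False


@dataclass(frozen=True)
class ModelSpec:
    """Model formula: the CG column, other factors, and covariates."""

    cg: str = "cg"
    factors: tuple[str, ...] = ()
    covariates: tuple[Covariate, ...] = ()

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        covs = []
        for c in d.get("covariates", []):
            if isinstance(c, str):
                covs.append(Covariate(c))
            else:
                covs.append(Covariate(c["name"], bool(c.get("centre", False)),
                                      bool(c.get("standardise", False))))
        return cls(cg=d.get("cg", "cg"), factors=tuple(d.get("factors", [])),
                   covariates=tuple(covs))


@dataclass(frozen=True)
class DesignMatrices:
    X1: np.ndarray
    X2: np.ndarray
    Z: sp.csr_matrix = field(repr=False)
    cg_labels: tuple[str, ...]
    n_per_cg: np.ndarray
    x2_names: tuple[str, ...]
    animal_ids: tuple[str, ...]

    @property
    def p1(self) -> int:
        return self.X1.shape[1]

    @property
    def p2(self) -> int:
        return self.X2.shape[1]

    @property
    def n_records(self) -> int:
        return self.X1.shape[0]

    @property
    def X(self) -> np.ndarray:
        """Concatenated fixed-effect design [X1 X2]."""
        return np.hstack([self.X1, self.X2]) if self.p2 else self.X1


def validate_records(records: pd.DataFrame, spec: ModelSpec, ped: Pedigree) -> None:
    for col in ("animal", spec.cg, "y"):
        if col not in records.columns:
            raise DesignError(f"records table missing column {col!r}")
    missing = [a for a in records["animal"].astype(str) if a not in ped.index]
    if missing:
        raise DesignError(
            f"{len(missing)} record animals absent from pedigree (e.g. {missing[:5]}); "
            "add them to the pedigree explicitly")
    if records[spec.cg].isna().any() or records["y"].isna().any():
        raise DesignError("records with missing cg or y are not allowed")


def build_design(records: pd.DataFrame, spec: ModelSpec, ped: Pedigree) -> DesignMatrices:
    """Construct X1, X2 and Z from a record table.

    CG labels are ordered lexicographically, once, and that order propagates
    to every downstream matrix and report.  Raises on rank deficiency of
    [X1 X2], naming the confounded columns.
    """
    validate_records(records, spec, ped)
    n = len(records)
    cg_raw = records[spec.cg].astype(str).to_numpy()
    cg_labels = tuple(sorted(set(cg_raw)))
    cg_pos = {c: k for k, c in enumerate(cg_labels)}
    X1 = np.zeros((n, len(cg_labels)))
    X1[np.arange(n), [cg_pos[c] for c in cg_raw]] = 1.0
    n_per_cg = X1.sum(axis=0)

    cols: list[np.ndarray] = []
    names: list[str] = []
    for f in spec.factors:
        if f not in records.columns:
            raise DesignError(f"factor column {f!r} not in records")
        levels = sorted(records[f].astype(str).unique())
        for lev in levels[1:]:  # drop-first coding against the absorbed intercept
            cols.append((records[f].astype(str).to_numpy() == lev).astype(float))
            names.append(f"{f}[{lev}]")
    for cov in spec.covariates:
        if cov.name not in records.columns:
            raise DesignError(f"covariate column {cov.name!r} not in records")
        v = records[cov.name].to_numpy(dtype=float)
        if cov.centre or cov.standardise:
            v = v - v.mean()
        if cov.standardise:
            sd = v.std(ddof=0)
            if sd == 0:
                raise DesignError(f"covariate {cov.name!r} is constant")
            v = v / sd
        cols.append(v)
        names.append(cov.name)
    X2 = np.column_stack(cols) if cols else np.zeros((n, 0))

    _check_rank(X1, X2, cg_labels, names)

    animal_idx = ped.indices_of(records["animal"].astype(str).tolist())
    Z = sp.csr_matrix(
        (np.ones(n), (np.arange(n), animal_idx)), shape=(n, ped.n))
    return DesignMatrices(X1=X1, X2=X2, Z=Z, cg_labels=cg_labels,
                          n_per_cg=n_per_cg, x2_names=tuple(names),
                          animal_ids=tuple(ped.ids))


def _check_rank(X1, X2, cg_labels, x2_names) -> None:
    X = np.hstack([X1, X2]) if X2.shape[1] else X1
    p = X.shape[1]
    rank = np.linalg.matrix_rank(X)
    if rank == p:
        return
    # name the confounded columns via the near-null right singular vectors
    _, sv, vt = np.linalg.svd(X, full_matrices=False)
    tol = sv.max() * max(X.shape) * np.finfo(float).eps
    bad = vt[sv < tol]
    all_names = [f"cg[{c}]" for c in cg_labels] + list(x2_names)
    involved = sorted({all_names[j] for row in bad for j in np.where(np.abs(row) > 1e-8)[0]})
    raise DesignError(
        f"design matrix [X1 X2] is rank deficient (rank {rank} < {p}); "
        f"confounded columns: {', '.join(involved)}")


def check_orthogonality(X1: np.ndarray, X2: np.ndarray,
                        tol: float = 1e-10) -> tuple[bool, np.ndarray]:
    """Whether X1'X2 = 0, i.e. no correction for other fixed effects is needed.

    Entry (i, j) of X1'X2 is the count (factor column) or covariate sum of
    effect j within contemporary group i; all-zero means the other effects are
    centred and balanced across groups.
    """
    if X1.shape[0] != X2.shape[0]:
        raise DesignError("X1 and X2 must have equal row counts")
    cross = X1.T @ X2
    return (cross.size == 0 or np.abs(cross).max() < tol), cross


def cg_average_operator(dm: DesignMatrices) -> np.ndarray:
    """(X1'X1)^-1 X1'Z: record-weighted CG averaging of animal effects."""
    return (dm.X1.T @ dm.Z.toarray()) / dm.n_per_cg[:, None]
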