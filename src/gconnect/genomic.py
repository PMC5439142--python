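"""Genomic relationships: VanRaden's G and the single-step H inverse.

G is VanRaden's first estimator, G = M M' / (2 * sum_j p_j (1 - p_j)) with M
the allele-dosage matrix centred by twice the allele frequency.  When only a
subset of animals is genotyped, pedigree and genomic information are combined
in the single-step matrix H, whose inverse (Aguilar et al.) is A^-1 plus the
increment G^-1 - A22^-1 confined to the genotyped block — the only form ever
needed by the mixed model equations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pedigree import Pedigree

logger = logging.getLogger(__name__)


class GenomicError(ValueError):
    pass


@dataclass(frozen=True)
class GenotypeMatrix:
    """SNP dosages (0/1/2) for a set of genotyped animals.

    ``allele_freqs`` default to the observed sample frequencies; markers with
    frequency 0 or 1 carry no variance and are flagged in ``monomorphic``.
    """

    animal_ids: tuple[str, ...]
    dosages: np.ndarray
    allele_freqs: np.ndarray
    monomorphic: np.ndarray

    @classmethod
    def from_dosages(cls, animal_ids, dosages, allele_freqs=None) -> "GenotypeMatrix":
        dosages = np.asarray(dosages, dtype=float)
        if not np.isin(dosages, (0.0, 1.0, 2.0)).all():
            raise GenomicError("dosages must be coded 0/1/2")
        if allele_freqs is None:
            allele_freqs = (dosages.mean(axis=0) / 2.0 if dosages.shape[0]
                            else np.zeros(dosages.shape[1]))
        allele_freqs = np.asarray(allele_freqs, dtype=float)
        mono = (allele_freqs <= 0.0) | (allele_freqs >= 1.0)
        if mono.any():
            logger.info("%d monomorphic markers flagged", int(mono.sum()))
        return cls(tuple(str(a) for a in animal_ids), dosages, allele_freqs, mono)

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]


def build_G(geno: GenotypeMatrix) -> np.ndarray:
    """Genomic relationship matrix, VanRaden method 1.

    Monomorphic markers are dropped (with a logged count); an error is raised
    only if no polymorphic marker remains, since the scaling denominator
    2 * sum p(1-p) would then be zero.
    """
    keep = ~geno.monomorphic
    if not keep.any():
        raise GenomicError("all markers monomorphic: G denominator is zero")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d monomorphic markers from G", n_dropped)
    p = geno.allele_freqs[keep]
    M = geno.dosages[:, keep] - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    return (M @ M.T) / denom


def subset_A22(A: np.ndarray, genotyped_index: np.ndarray) -> np.ndarray:
    """Pedigree relationships among the genotyped animals (A22 block)."""
    idx = np.asarray(genotyped_index)
    return A[np.ix_(idx, idx)]


def blend_G(G: np.ndarray, A22: np.ndarray, weight: float = 0.95) -> np.ndarray:
    """weight * G + (1 - weight) * A22; guarantees invertibility at weight < 1."""
    if not 0.0 < weight <= 1.0:
        raise GenomicError(f"blending weight must be in (0, 1], got {weight}")
    if G.shape != A22.shape:
        raise GenomicError(f"shape mismatch: G {G.shape} vs A22 {A22.shape}")
    return weight * G + (1.0 - weight) * A22


def build_H_inverse(A_inv: sp.spmatrix, A22: np.ndarray, G_blended: np.ndarray,
                    genotyped_index: np.ndarray) -> sp.csr_matrix:
    """Single-step H^-1: A^-1 plus (G^-1 - A22^-1) scattered into the genotyped block.

    ``genotyped_index`` maps rows of G/A22 into pedigree order.  With no
    genotyped animals, or with G_blended equal to A22, this reduces to A^-1.
    """
    idx = np.asarray(genotyped_index, dtype=np.int64)
    if idx.size == 0:
        return sp.csr_matrix(A_inv)
    for name, mat in (("G_blended", G_blended), ("A22", A22)):
        try:
            c = np.linalg.cond(mat)
        except np.linalg.LinAlgError:  # pragma: no cover
            c = np.inf
        if not np.isfinite(c) or c > 1e12:
            raise GenomicError(
                f"{name} is singular or near-singular (cond ~ {c:.2e}); "
                "blend G with A22 (weight < 1) before building H^-1")
    delta = np.linalg.inv(G_blended) - np.linalg.inv(A22)
    n = A_inv.shape[0]
    scatter = sp.coo_matrix(
        (delta.ravel(), (np.repeat(idx, idx.size), np.tile(idx, idx.size))),
        shape=(n, n))
    return (sp.csr_matrix(A_inv) + scatter.tocsr()).tocsr()


def build_H_dense(A: np.ndarray, G_blended: np.ndarray,
                  genotyped_index: np.ndarray) -> np.ndarray:
    """Dense H from its partitioned definition (small-instance oracle only).

    H modifies A by projecting the genomic deviation G - A22 through the
    pedigree regression of non-genotyped on genotyped animals.
    """
    idx = np.asarray(genotyped_index, dtype=np.int64)
    n = A.shape[0]
    rest = np.setdiff1d(np.arange(n), idx)
    A22 = A[np.ix_(idx, idx)]
    A12 = A[np.ix_(rest, idx)]
    A22inv = np.linalg.inv(A22)
    D = G_blended - A22
    H = A.copy()
    B = A12 @ A22inv
    H[np.ix_(rest, rest)] += B @ D @ B.T
    H[np.ix_(rest, idx)] += B @ D
    H[np.ix_(idx, rest)] += D @ B.T
    H[np.ix_(idx, idx)] += D
    return H


def read_genotypes_csv(path) -> GenotypeMatrix:
    """Read genotypes from plain CSV (``animal,snp...``) or PLINK RAW.

    PLINK RAW is whitespace-delimited with header ``FID IID PAT MAT SEX
    PHENOTYPE SNP1 ...``; IID is used as the animal id.
    """
    with open(path) as fh:
        header = fh.readline()
    if header.split()[:6] == ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]:
        df = pd.read_csv(path, sep=r"\s+")
        ids = df["IID"].astype(str)
        dosages = df.iloc[:, 6:].to_numpy(dtype=float)
    else:
        df = pd.read_csv(path)
        if df.columns[0] != "animal":
            raise GenomicError("genotype CSV must start with an 'animal' column")
        ids = df["animal"].astype(str)
        dosages = df.iloc[:, 1:].to_numpy(dtype=float)
    return GenotypeMatrix.from_dosages(ids.tolist(), dosages)


def write_genotypes_csv(geno: GenotypeMatrix, path) -> None:
    cols = {"animal": list(geno.animal_ids)}
    for j in range(geno.n_markers):
        cols[f"snp{j + 1}"] = geno.dosages[:, j].astype(int)
    pd.DataFrame(cols).to_csv(path, index=False)


def check_genotyped_in_pedigree(geno: GenotypeMatrix, ped: Pedigree) -> np.ndarray:
    """Pedigree indices of the genotyped animals; error if any id is missing."""
    missing = [a for a in geno.animal_ids if a not in ped.index]
    if missing:
        raise GenomicError(f"genotyped animals absent from pedigree: {missing[:5]}")
    return ped.indices_of(geno.animal_ids)
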