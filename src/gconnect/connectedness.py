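"""Connectedness statistics from the group-averaged prediction error matrix.

Genetic connectedness between contemporary groups is measured on PEVMean, the
prediction error variance-covariance matrix of breeding values averaged by
contemporary group,

    PEVMean = (X1'X1)^-1 X1'Z . PEV . Z'X1 (X1'X1)^-1 .

Forming PEV itself is quadratic in the number of animals, so the central
result implemented here recovers PEVMean exactly from the fixed-effect
variance block of the mixed model equations alone:

* function 1 — the classical approximation Var(beta1_hat) itself;
* function 2 — Var(beta_hat) - sigma_e^2 (X'X)^-1, exact when contemporary
  group is the only fixed effect (the correction is the record-count term);
* function 3 — exact in the presence of other fixed effects:
  Var(beta1_hat) + W Var(beta2_hat) W' + W Var(beta2_hat, beta1_hat)
  + Var(beta1_hat, beta2_hat) W' - sigma_e^2 (X1'X1)^-1,
  with W = (X1'X1)^-1 X1'X2.

From any PEVMean source the pairwise statistics follow: PEVD, the flock
correlation, VED and its record-count-corrected form, CR, and the coefficient
of determination CD of the group-mean contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .mme import VarBeta
from .model_design import DesignMatrices, cg_average_operator

#: guard for near-zero PEVMean diagonals in correlation denominators
EPS_VAR = 1e-12

Source = Literal["direct", "function1", "function2", "function3"]


@dataclass(frozen=True)
class PEVMeanMatrix:
    """p1 x p1 CG-averaged prediction error (co)variance matrix, trait units^2."""

    values: np.ndarray
    cg_labels: tuple[str, ...]
    source: Source

    def __post_init__(self):
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.cg_labels):
            raise ValueError("PEVMean must be square over the CG labels")
        asym = np.abs(v - v.T).max() if v.size else 0.0
        if asym > 1e-8:
            raise ValueError(f"PEVMean asymmetry {asym:.2e} exceeds 1e-8")

    @property
    def p1(self) -> int:
        return len(self.cg_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cg_labels, columns=self.cg_labels)


def _symmetrise(M: np.ndarray) -> np.ndarray:
    return 0.5 * (M + M.T)


def pevmean_direct(pev: np.ndarray, dm: DesignMatrices) -> PEVMeanMatrix:
    """PEVMean by averaging the full PEV over contemporary groups (oracle path)."""
    T = cg_average_operator(dm)
    return PEVMeanMatrix(_symmetrise(T @ pev @ T.T), dm.cg_labels, "direct")


def function1(var_beta: VarBeta, dm: DesignMatrices) -> PEVMeanMatrix:
    """The uncorrected approximation: Var(beta1_hat) itself."""
    return PEVMeanMatrix(var_beta.v11.copy(), dm.cg_labels, "function1")


def function2(var_beta: VarBeta, dm: DesignMatrices, sigma_e2: float) -> PEVMeanMatrix:
    """Record-count correction: Var(beta1_hat) - sigma_e^2 diag(1/n_i).

    Exact PEVMean when contemporary group is the only fixed effect; the
    correction touches the diagonal only, so off-diagonals always agree with
    function 1.
    """
    out = var_beta.v11.copy()
    out[np.diag_indices_from(out)] -= sigma_e2 / dm.n_per_cg
    return PEVMeanMatrix(_symmetrise(out), dm.cg_labels, "function2")


def cg_mean_of_x2(dm: DesignMatrices) -> np.ndarray:
    """W = (X1'X1)^-1 X1'X2: row i holds the within-CG-i means of the X2 columns."""
    return (dm.X1.T @ dm.X2) / dm.n_per_cg[:, None]


def correction_factor(var_beta: VarBeta, dm: DesignMatrices) -> np.ndarray:
    """The other-fixed-effects correction: W V22 W' + W V21 + V12 W'.

    Zero when X1'X2 = 0.  Adding it to the function-2 output gives function 3.
    """
    if dm.p2 == 0:
        return np.zeros((dm.p1, dm.p1))
    if var_beta.full.shape[0] != dm.p1 + dm.p2:
        raise ValueError(
            f"var_beta is {var_beta.full.shape[0]}-dimensional but the design "
            f"has p1 + p2 = {dm.p1 + dm.p2} fixed effects")
    W = cg_mean_of_x2(dm)
    corr = W @ var_beta.v22 @ W.T + W @ var_beta.v21 + var_beta.v12 @ W.T
    return _symmetrise(corr)


def function3(var_beta: VarBeta, dm: DesignMatrices, sigma_e2: float) -> PEVMeanMatrix:
    """Exact PEVMean from the full fixed-effect variance block.

    With no other fixed effects this defers to function 2, to which it is
    identical in that case.
    """
    if dm.p2 == 0:
        out = function2(var_beta, dm, sigma_e2)
        return PEVMeanMatrix(out.values, out.cg_labels, "function3")
    base = function2(var_beta, dm, sigma_e2)
    return PEVMeanMatrix(_symmetrise(base.values + correction_factor(var_beta, dm)),
                         dm.cg_labels, "function3")


def prior_cg_variance(K: np.ndarray, dm: DesignMatrices, sigma_g2: float) -> np.ndarray:
    """Kbar: prior variance of CG mean breeding values, sigma_g^2 averaged over K."""
    T = cg_average_operator(dm)
    return _symmetrise(sigma_g2 * (T @ K @ T.T))


# ---------------------------------------------------------------------------
# pairwise statistics


def _check_pair(i: int, j: int) -> None:
    if i == j:
        raise ValueError("statistics of differences need two distinct groups")


def pevd(pm: PEVMeanMatrix, i: int, j: int) -> float:
    """Prediction error variance of the difference in CG mean breeding values."""
    _check_pair(i, j)
    v = pm.values
    return float(v[i, i] + v[j, j] - 2.0 * v[i, j])


def flock_correlation(pm: PEVMeanMatrix, i: int, j: int) -> float:
    """Correlation form of PEVMean; NaN when a diagonal hits the variance guard."""
    if i == j:
        return 1.0
    v = pm.values
    if v[i, i] <= EPS_VAR or v[j, j] <= EPS_VAR:
        return float("nan")
    return float(v[i, j] / np.sqrt(v[i, i] * v[j, j]))


def ved(var_beta: VarBeta, i: int, j: int) -> float:
    """Variance of the difference of estimated CG fixed effects."""
    _check_pair(i, j)
    v = var_beta.v11
    return float(v[i, i] + v[j, j] - 2.0 * v[i, j])


def corrected_ved(var_beta: VarBeta, n_per_cg: np.ndarray, sigma_e2: float,
                  i: int, j: int) -> float:
    """VED minus the record-count terms sigma_e^2 (1/n_i + 1/n_j).

    Identical to PEVD in CG-only models, and in multi-effect models whenever
    the other effects are balanced across groups (the rank-deficient part of
    the correction cancels in differences).
    """
    _check_pair(i, j)
    return ved(var_beta, i, j) - sigma_e2 * (1.0 / n_per_cg[i] + 1.0 / n_per_cg[j])


def cr(var_beta: VarBeta, i: int, j: int) -> float:
    """Connectedness rating: correlation form of Var(beta1_hat)."""
    if i == j:
        return 1.0
    v = var_beta.v11
    if v[i, i] <= EPS_VAR or v[j, j] <= EPS_VAR:
        return float("nan")
    return float(v[i, j] / np.sqrt(v[i, i] * v[j, j]))


def cd_contrast(pm: PEVMeanMatrix, kbar: np.ndarray, i: int, j: int) -> float:
    """Coefficient of determination of the CG mean-difference contrast.

    CD = 1 - PEVD / prior contrast variance, the prior read off Kbar.  NaN
    when the groups have identical prior genetic means (zero denominator).
    """
    _check_pair(i, j)
    prior = float(kbar[i, i] + kbar[j, j] - 2.0 * kbar[i, j])
    if prior <= EPS_VAR:
        return float("nan")
    return 1.0 - pevd(pm, i, j) / prior


# ---------------------------------------------------------------------------
# report


def build_report(pm: PEVMeanMatrix, var_beta: VarBeta, dm: DesignMatrices,
                 sigma_e2: float, kbar: np.ndarray | None = None,
                 pm_direct: PEVMeanMatrix | None = None) -> pd.DataFrame:
    """Pairwise connectedness table over all p1(p1-1)/2 CG pairs.

    Columns: ``cg_i, cg_j, n_i, n_j, harmonic_mean_n, pevd, flock_r, ved,
    corrected_ved, cr, cd, flagged`` plus ``max_dev_direct`` when a directly
    computed PEVMean is supplied (making the exactness claim user-visible).
    ``flagged`` marks pairs whose correlation denominators hit the variance
    guard.
    """
    rows = []
    v = pm.values
    n = dm.n_per_cg
    for i in range(pm.p1):
        for j in range(i + 1, pm.p1):
            flagged = bool(v[i, i] <= EPS_VAR or v[j, j] <= EPS_VAR)
            row = {
                "cg_i": pm.cg_labels[i],
                "cg_j": pm.cg_labels[j],
                "n_i": int(n[i]),
                "n_j": int(n[j]),
                "harmonic_mean_n": 2.0 / (1.0 / n[i] + 1.0 / n[j]),
                "pevd": pevd(pm, i, j),
                "flock_r": flock_correlation(pm, i, j),
                "ved": ved(var_beta, i, j),
                "corrected_ved": corrected_ved(var_beta, n, sigma_e2, i, j),
                "cr": cr(var_beta, i, j),
                "cd": cd_contrast(pm, kbar, i, j) if kbar is not None else float("nan"),
                "flagged": flagged,
            }
            if pm_direct is not None:
                row["max_dev_direct"] = float(
                    np.abs(pm.values - pm_direct.values).max())
            rows.append(row)
    return pd.DataFrame(rows)
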