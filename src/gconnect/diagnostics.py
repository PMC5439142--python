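"""Decision aids: is the other-fixed-effects correction worth computing?

The correction trace summarises the magnitude of the other-fixed-effects
correction without forming the full matrix; the covariance ratio compares
Var(beta1_hat) between nested models; two mixed-model r^2 statistics describe
fixed-effect fit (they carry no information about the correction — they are
reported for model comparison only); and the operation count predicts the
post-solve cost of recovering PEVMean from Var(beta_hat).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .connectedness import cg_mean_of_x2
from .mme import MMEFit, VarBeta, VarianceComponents
from .model_design import DesignMatrices


@dataclass(frozen=True)
class DiagnosticsBundle:
    correction_trace: float
    r2_marginal: float
    r2_beta: float
    op_count: int
    covariance_ratio: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def correction_trace(var_beta: VarBeta, dm: DesignMatrices) -> float:
    """Trace of the other-fixed-effects correction, computed without the matrix.

    Uses the rearrangement 2 Tr(V21 W) + Tr(V22 W' W) with
    W = (X1'X1)^-1 X1'X2, which costs O(p1 p2^2 + p1^2 p2) instead of the
    O(p1^2 p2) full-matrix assembly followed by a trace; both agree to 1e-8
    and the full-matrix form is the test oracle.
    """
    if dm.p2 == 0:
        return 0.0
    W = cg_mean_of_x2(dm)
    return float(2.0 * np.trace(var_beta.v21 @ W) + np.trace(var_beta.v22 @ (W.T @ W)))


def covariance_ratio(var_beta1_a: np.ndarray, var_beta1_b: np.ndarray) -> float:
    """det(Var(beta1_hat)_A Var(beta1_hat)_B^-1) via log-determinants.

    Both matrices must cover the same CG set in the same order.  A value of 1
    means the CG-effect variances are untouched by the extra fixed effects of
    the fuller model; drift from 1 flags confounding with contemporary group.
    """
    if var_beta1_a.shape != var_beta1_b.shape:
        raise ValueError("CG blocks must have matching shape and ordering")
    sign_a, logdet_a = np.linalg.slogdet(var_beta1_a)
    sign_b, logdet_b = np.linalg.slogdet(var_beta1_b)
    if sign_a <= 0 or sign_b <= 0:
        raise np.linalg.LinAlgError("Var(beta1_hat) block is not positive definite")
    return float(np.exp(logdet_a - logdet_b))


def r2_marginal(fit: MMEFit, dm: DesignMatrices, vc: VarianceComponents) -> float:
    """Marginal r^2: Var(y_hat) / (Var(y_hat) + sigma_e^2 + sigma_g^2).

    Var(y_hat) is the population (divide-by-n) variance of the fixed-effect
    fitted values X beta_hat over the records.
    """
    y_hat = dm.X @ fit.beta_hat
    var_fit = float(np.var(y_hat))
    return var_fit / (var_fit + vc.sigma_e2 + vc.sigma_g2)


def r2_beta(fit: MMEFit, dm: DesignMatrices) -> float:
    """Wald-statistic r^2 for the fixed effects.

    F = beta_hat' Var(beta_hat)^-1 beta_hat / q and
    r^2 = (q-1)F / (nu + (q-1)F) with nu = n - p.  The dimension q is taken
    as the total number of estimated fixed effects (q = p), the convention
    that matches the Wald construction dimensionally; whether nu should also
    subtract random-effect degrees of freedom is an open modelling question
    and is deliberately not attempted.
    """
    n, p = dm.n_records, dm.p1 + dm.p2
    nu = n - p
    if nu <= 0:
        raise ValueError(f"need n > p for r2_beta (n={n}, p={p})")
    b = fit.beta_hat
    wald = float(b @ np.linalg.solve(fit.var_beta.full, b))
    f_stat = wald / p
    num = (p - 1) * f_stat
    return num / (nu + num)


def op_count(p1: int, p2: int) -> int:
    """Predicted operations to recover PEVMean once Var(beta_hat) is in hand.

    Closed form 2 p1 + 6 p1^2 + p1 p2 (2 p1 + p2); quadratic in the number of
    contemporary groups and independent of the number of animals.
    """
    if p1 < 1 or p2 < 0:
        raise ValueError("need p1 >= 1 and p2 >= 0")
    return int(2 * p1 + 6 * p1 ** 2 + p1 * p2 * (2 * p1 + p2))


def diagnose(fit: MMEFit, dm: DesignMatrices, vc: VarianceComponents,
             var_beta1_reduced: np.ndarray | None = None) -> DiagnosticsBundle:
    """Assemble the diagnostics bundle for one fitted model.

    ``var_beta1_reduced`` is the CG block of a nested (reduced) model, if a
    covariance ratio against it is wanted.
    """
    ratio = None
    if var_beta1_reduced is not None:
        ratio = covariance_ratio(fit.var_beta.v11, var_beta1_reduced)
    return DiagnosticsBundle(
        correction_trace=correction_trace(fit.var_beta, dm),
        r2_marginal=r2_marginal(fit, dm, vc),
        r2_beta=r2_beta(fit, dm),
        op_count=op_count(dm.p1, dm.p2),
        covariance_ratio=ratio,
    )
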