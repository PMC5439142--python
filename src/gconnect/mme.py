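"""Henderson's mixed model equations and their variance blocks.

For the animal model y = X beta + Z u + e with Var(u) = sigma_g^2 K (K the
pedigree, genomic or combined relationship matrix) and Var(e) = sigma_e^2 I,
the coefficient matrix is assembled on the variance-ratio scale

    C = [[X'X,  X'Z          ],
         [Z'X,  Z'Z + lambda K^-1]],    lambda = sigma_e^2 / sigma_g^2,

with right-hand side [X'y, Z'y].  Multiplying the relevant blocks of C^-1 by
sigma_e^2 yields Var(beta_hat) (fixed block) and the prediction error
variance-covariance matrix PEV = Var(u_hat - u) (random block).  The fixed
block is obtained by solving C W = E_p for the first p identity columns —
never by inverting C — which is the computational point of the whole package:
Var(beta_hat) is p x p where PEV is q x q with q >> p.

Scaling convention (easy to get silently wrong): C is assembled WITHOUT the
1/sigma_e^2 factor, so every block of C^-1 must be multiplied by sigma_e^2 to
be a variance.  All variance outputs here have that factor applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .model_design import DesignMatrices

_DENSE_PEV_LIMIT = 5000
_DENSE_SOLVE_LIMIT = 10000
_COND_LIMIT = 1e12


class SingularSystemError(np.linalg.LinAlgError):
    pass


@dataclass(frozen=True)
class VarianceComponents:
    """Additive genetic and residual variances, in squared trait units."""

    sigma_g2: float
    sigma_e2: float

    def __post_init__(self):
        if self.sigma_g2 <= 0 or self.sigma_e2 <= 0:
            raise ValueError("variance components must be positive")

    @property
    def lambda_(self) -> float:
        """Variance ratio sigma_e^2 / sigma_g^2 entering the MME."""
        return self.sigma_e2 / self.sigma_g2

    @property
    def heritability(self) -> float:
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)


@dataclass(frozen=True)
class MMESystem:
    C: sp.csr_matrix = field(repr=False)
    rhs: np.ndarray = field(repr=False)
    p1: int
    p2: int
    q: int

    @property
    def p(self) -> int:
        return self.p1 + self.p2

    @property
    def dim(self) -> int:
        return self.p + self.q


@dataclass(frozen=True)
class VarBeta:
    """sigma_e^2-scaled fixed block of the MME inverse, partitioned by CG."""

    full: np.ndarray
    p1: int

    @property
    def v11(self) -> np.ndarray:
        """Var(beta1_hat): contemporary-group block."""
        return self.full[: self.p1, : self.p1]

    @property
    def v22(self) -> np.ndarray:
        return self.full[self.p1:, self.p1:]

    @property
    def v12(self) -> np.ndarray:
        """Var(beta1_hat, beta2_hat)."""
        return self.full[: self.p1, self.p1:]

    @property
    def v21(self) -> np.ndarray:
        return self.full[self.p1:, : self.p1]


@dataclass(frozen=True)
class MMEFit:
    beta_hat: np.ndarray
    u_hat: np.ndarray
    var_beta: VarBeta
    vc: VarianceComponents
    pev: np.ndarray | None = field(default=None, repr=False)


def assemble_mme(dm: DesignMatrices, K_inv: sp.spmatrix,
                 vc: VarianceComponents, y: np.ndarray) -> MMESystem:
    """Assemble the coefficient matrix and right-hand side on the lambda scale."""
    q = dm.Z.shape[1]
    if K_inv.shape != (q, q):
        raise ValueError(f"K^-1 is {K_inv.shape}, expected ({q}, {q})")
    X = sp.csr_matrix(dm.X)
    Z = dm.Z
    lam = vc.lambda_
    C = sp.bmat([[X.T @ X, X.T @ Z],
                 [Z.T @ X, Z.T @ Z + lam * sp.csr_matrix(K_inv)]], format="csr")
    y = np.asarray(y, dtype=float)
    rhs = np.concatenate([dm.X.T @ y, Z.T @ y])
    return MMESystem(C=C, rhs=rhs, p1=dm.p1, p2=dm.p2, q=q)


def _factorize(system: MMESystem):
    try:
        return spla.splu(system.C.tocsc())
    except RuntimeError as exc:  # SuperLU signals exact singularity this way
        raise SingularSystemError(
            "mixed model equations are singular; check the design rank "
            f"({exc})") from exc


def _check_condition(system: MMESystem) -> None:
    if system.dim <= 2000:
        cond = np.linalg.cond(system.C.toarray())
        if cond > _COND_LIMIT:
            raise SingularSystemError(
                f"coefficient matrix condition estimate {cond:.2e} exceeds "
                f"{_COND_LIMIT:.0e}; the design is confounded or badly scaled")


def solve_mme(system: MMESystem) -> tuple[np.ndarray, np.ndarray]:
    """Solutions (beta_hat, u_hat) by direct sparse factorisation."""
    _check_condition(system)
    lu = _factorize(system)
    sol = lu.solve(system.rhs)
    return sol[: system.p], sol[system.p:]


def solve_fixed_block(system: MMESystem, vc: VarianceComponents) -> VarBeta:
    """Var(beta_hat) from the first p columns of the MME inverse.

    Solves C W = E_p (E_p the first p identity columns), keeps the top p rows
    and multiplies by sigma_e^2.  Equals the generalised-least-squares
    expression (X' V^-1 X)^-1 with V = Z K sigma_g^2 Z' + sigma_e^2 I.
    """
    _check_condition(system)
    lu = _factorize(system)
    p = system.p
    E = np.zeros((system.dim, p))
    E[np.arange(p), np.arange(p)] = 1.0
    W = lu.solve(E)
    full = vc.sigma_e2 * W[:p, :]
    full = 0.5 * (full + full.T)
    return VarBeta(full=full, p1=system.p1)


def extract_pev(system: MMESystem, vc: VarianceComponents,
                dense_limit: int = _DENSE_PEV_LIMIT) -> np.ndarray:
    """PEV = sigma_e^2 x random-effect diagonal block of the MME inverse.

    Only feasible on small instances: q^2 storage.  Larger evaluations should
    use the fixed-block path (function 3) instead, which is the point of the
    method.
    """
    if system.q > dense_limit:
        raise ValueError(
            f"q = {system.q} exceeds the dense PEV limit ({dense_limit}); "
            "use the fixed-effect block and function 3 instead")
    _check_condition(system)
    lu = _factorize(system)
    E = np.zeros((system.dim, system.q))
    E[system.p + np.arange(system.q), np.arange(system.q)] = 1.0
    W = lu.solve(E)
    pev = vc.sigma_e2 * W[system.p:, :]
    return 0.5 * (pev + pev.T)


def fit_mme(dm: DesignMatrices, K_inv: sp.spmatrix, vc: VarianceComponents,
            y: np.ndarray, extract_pev_block: bool = False,
            dense_limit: int = _DENSE_PEV_LIMIT) -> MMEFit:
    """Assemble, solve and extract the variance blocks in one call."""
    system = assemble_mme(dm, K_inv, vc, y)
    beta_hat, u_hat = solve_mme(system)
    var_beta = solve_fixed_block(system, vc)
    pev = extract_pev(system, vc, dense_limit) if extract_pev_block else None
    return MMEFit(beta_hat=beta_hat, u_hat=u_hat, var_beta=var_beta,
                  vc=vc, pev=pev)


def gls_var_beta(dm: DesignMatrices, K: np.ndarray,
                 vc: VarianceComponents) -> np.ndarray:
    """Brute-force (X' V^-1 X)^-1 with dense V; small-instance oracle."""
    Z = dm.Z.toarray()
    V = vc.sigma_g2 * (Z @ K @ Z.T) + vc.sigma_e2 * np.eye(dm.n_records)
    Vinv = np.linalg.inv(V)
    X = dm.X
    return np.linalg.inv(X.T @ Vinv @ X)


def gls_pev(dm: DesignMatrices, K: np.ndarray, vc: VarianceComponents) -> np.ndarray:
    """Brute-force PEV = sigma_g^2 K - sigma_g^4 K Z' P Z K; small-instance oracle."""
    Z = dm.Z.toarray()
    X = dm.X
    V = vc.sigma_g2 * (Z @ K @ Z.T) + vc.sigma_e2 * np.eye(dm.n_records)
    Vinv = np.linalg.inv(V)
    P = Vinv - Vinv @ X @ np.linalg.inv(X.T @ Vinv @ X) @ X.T @ Vinv
    return vc.sigma_g2 * K - vc.sigma_g2 ** 2 * (K @ Z.T @ P @ Z @ K)
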