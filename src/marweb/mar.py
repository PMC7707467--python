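"""First-order multivariate autoregressive (MAR) model with covariates.

The model for the de-seasoned, z-scored community state x_t (p series)
forced by covariates u_t (q series) is

    x_t = B x_{t-1} + a + C u_{t-1} + w_t,   w_t ~ N(0, S)

where b_ij measures the effect of the density of taxon j at t-1 on the
per-capita growth of taxon i, a holds intrinsic rates, C the covariate
effects (entering at the same one-month lag as the variates), and S the
process-error covariance.  Estimation is conditional maximum likelihood
(conditioning on the first observation): sparsity constraints are
expressed as boolean masks over B and C, and the masked likelihood is
maximized by iterated generalized least squares — exact coordinate
ascent over the coefficient block given S and the S block given the
coefficients, which for the default diagonal S converges in a couple of
iterations to the closed-form row-wise solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = [
    "MARStructure",
    "MARParams",
    "FitResult",
    "conditional_loglik",
    "fit_ols",
    "fit_ml",
    "predict_one_step",
    "aicc",
]

S_FORMS = ("diagonal", "unconstrained", "diagonal-and-equal")

# floor applied to the diagonal of S during fitting so the Gaussian
# likelihood stays defined on (near-)noiseless data
_S_FLOOR = 1e-12


@dataclass
class MARStructure:
    """Free/zero pattern over (B, C, a) plus the form of S.

    ``True`` in a mask marks a freely estimated entry; ``False`` pins the
    entry to exactly zero.  ``S_form`` is one of ``"diagonal"``
    (independent process errors, the default downstream),
    ``"unconstrained"`` (full symmetric S) or ``"diagonal-and-equal"``
    (one shared error variance).
    """

    B_mask: np.ndarray
    C_mask: np.ndarray
    a_free: np.ndarray
    S_form: str = "diagonal"

    def __post_init__(self) -> None:
        self.B_mask = np.asarray(self.B_mask, dtype=bool)
        self.C_mask = np.asarray(self.C_mask, dtype=bool).reshape(self.B_mask.shape[0], -1)
        self.a_free = np.asarray(self.a_free, dtype=bool)
        p = self.B_mask.shape[0]
        if self.B_mask.shape != (p, p):
            raise ValueError("B_mask must be square")
        if self.C_mask.shape[0] != p or self.a_free.shape != (p,):
            raise ValueError("C_mask/a_free dimensions inconsistent with B_mask")
        if self.S_form not in S_FORMS:
            raise ValueError(f"S_form must be one of {S_FORMS}")
        if not (self.B_mask.any() or self.C_mask.any() or self.a_free.any()):
            raise ValueError("structure has no free parameters")

    @classmethod
    def full(cls, p: int, q: int, S_form: str = "diagonal") -> "MARStructure":
        """All B, C and a entries free."""
        return cls(
            B_mask=np.ones((p, p), dtype=bool),
            C_mask=np.ones((p, q), dtype=bool),
            a_free=np.ones(p, dtype=bool),
            S_form=S_form,
        )

    @property
    def p(self) -> int:
        return self.B_mask.shape[0]

    @property
    def q(self) -> int:
        return self.C_mask.shape[1]

    @property
    def k_mean(self) -> int:
        """Number of free coefficients in (B, C, a)."""
        return int(self.B_mask.sum() + self.C_mask.sum() + self.a_free.sum())

    @property
    def k_free(self) -> int:
        """Total free parameters including the variance parameters of S."""
        p = self.p
        k_s = {"diagonal": p, "unconstrained": p * (p + 1) // 2, "diagonal-and-equal": 1}
        return self.k_mean + k_s[self.S_form]

    def coefficient_mask(self) -> np.ndarray:
        """p x (p+q+1) mask over the stacked coefficient matrix [B C a]."""
        return np.hstack([self.B_mask, self.C_mask, self.a_free[:, None]])

    def with_entry(self, matrix: str, i: int, j: int, free: bool) -> "MARStructure":
        """Copy of the structure with one B or C entry toggled."""
        if matrix == "B":
            mask = self.B_mask.copy()
            mask[i, j] = free
            return replace(self, B_mask=mask, C_mask=self.C_mask.copy(), a_free=self.a_free.copy())
        if matrix == "C":
            mask = self.C_mask.copy()
            mask[i, j] = free
            return replace(self, B_mask=self.B_mask.copy(), C_mask=mask, a_free=self.a_free.copy())
        raise ValueError("matrix must be 'B' or 'C'")


@dataclass
class MARParams:
    """Fitted (or true) MAR quantities B, C, a, S."""

    B: np.ndarray
    C: np.ndarray
    a: np.ndarray
    S: np.ndarray

    def __post_init__(self) -> None:
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        p = self.B.shape[0]
        self.C = np.asarray(self.C, dtype=float).reshape(p, -1)
        self.a = np.asarray(self.a, dtype=float).reshape(p)
        self.S = np.atleast_2d(np.asarray(self.S, dtype=float))
        if self.B.shape != (p, p) or self.S.shape != (p, p):
            raise ValueError("B and S must be p x p")
        if not np.allclose(self.S, self.S.T, atol=1e-10):
            raise ValueError("S must be symmetric")

    @property
    def p(self) -> int:
        return self.B.shape[0]

    @property
    def q(self) -> int:
        return self.C.shape[1]


@dataclass
class FitResult:
    """One fitted structure: parameters, fit quality and convergence record."""

    params: MARParams
    structure: MARStructure
    loglik: float
    n_transitions: int
    k_free: int
    aicc: float
    convergence: dict = field(default_factory=dict)
    var_names: list[str] = field(default_factory=list)
    cov_names: list[str] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return bool(self.convergence.get("converged", False))


def _as_array(M, names_attr="columns"):
    if isinstance(M, pd.DataFrame):
        return M.to_numpy(dtype=float), [str(c) for c in M.columns]
    arr = np.asarray(M, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"x{i+1}" for i in range(arr.shape[1])]


def _transition_arrays(X, U):
    """Stack regressand Y = x_t and regressors Z = [x_{t-1}, u_{t-1}, 1].

    Transitions touching a missing value anywhere in (x_t, x_{t-1},
    u_{t-1}) are dropped; only the retained transitions enter the
    likelihood and the count n_transitions.
    """
    Xa, var_names = _as_array(X)
    if U is None or (hasattr(U, "shape") and np.size(U) == 0):
        Ua = np.zeros((Xa.shape[0], 0))
        cov_names: list[str] = []
    else:
        Ua, cov_names = _as_array(U)
        cov_names = [f"u{i+1}" for i in range(Ua.shape[1])] if not isinstance(U, pd.DataFrame) else cov_names
    if Ua.shape[0] != Xa.shape[0]:
        raise ValueError("X and U must have the same number of rows")
    Y = Xa[1:]
    Z = np.hstack([Xa[:-1], Ua[:-1], np.ones((Xa.shape[0] - 1, 1))])
    ok = np.isfinite(Y).all(axis=1) & np.isfinite(Z).all(axis=1)
    return Y[ok], Z[ok], var_names, cov_names


def conditional_loglik(params: MARParams, X, U=None) -> float:
    """Gaussian log-likelihood of the observed transitions given x_1.

    Sums, over every usable transition t-1 -> t, the multivariate normal
    log-density of the innovation x_t − (B x_{t-1} + a + C u_{t-1})
    under covariance S.  No stationary prior on x_1 is included.
    """
    Y, Z, _, _ = _transition_arrays(X, U)
    if Y.shape[0] < 1:
        raise ValueError("need at least one complete transition (T >= 2)")
    S = params.S
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"S is singular or near-singular (condition number {cond:.3g})"
        )
    chol = linalg.cholesky(S, lower=True)
    Theta = np.hstack([params.B, params.C, params.a[:, None]])
    R = Y - Z @ Theta.T
    sol = linalg.solve_triangular(chol, R.T, lower=True)
    n, p = R.shape
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return float(-0.5 * (n * p * np.log(2 * np.pi) + n * logdet + np.sum(sol**2)))


def fit_ols(X, U=None) -> MARParams:
    """Closed-form least-squares fit of the fully free model.

    Solves each row's regression of x_t on [x_{t-1}, u_{t-1}, 1] and sets
    S to the maximum-likelihood residual covariance (divisor n).  This is
    the exact maximizer of :func:`conditional_loglik` when every entry of
    B, C and a is free, and serves as the oracle the iterative fitter is
    checked against.
    """
    Y, Z, _, _ = _transition_arrays(X, U)
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        raise ValueError(
            f"regressor matrix is rank deficient (rank {rank} < {Z.shape[1]} columns)"
        )
    Theta, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    Theta = Theta.T  # p x (p+q+1)
    R = Y - Z @ Theta.T
    S = R.T @ R / Y.shape[0]
    p = Y.shape[1]
    q = Z.shape[1] - p - 1
    return MARParams(B=Theta[:, :p], C=Theta[:, p : p + q], a=Theta[:, -1], S=S)


def _project_S(S_raw: np.ndarray, form: str) -> np.ndarray:
    if form == "unconstrained":
        S = 0.5 * (S_raw + S_raw.T)
    elif form == "diagonal":
        S = np.diag(np.diag(S_raw))
    else:  # diagonal-and-equal
        S = np.eye(S_raw.shape[0]) * float(np.mean(np.diag(S_raw)))
    d = np.arange(S.shape[0])
    S[d, d] = np.maximum(S[d, d], _S_FLOOR)
    return S


def _solve_masked_gls(Y, Z, S_inv, mask):
    """Exact minimizer of the S-weighted residual over masked coefficients.

    Normal equations for free entries (i, j) of Theta:
    (S^-1 Y' Z)_ij = (S^-1 Theta G)_ij with G = Z'Z, a linear system in
    the free entries, solved via the kron(S^-1, G) sub-block.
    """
    p = Y.shape[1]
    m = Z.shape[1]
    G = Z.T @ Z
    free = np.flatnonzero(mask.ravel())
    A = np.kron(S_inv, G)[np.ix_(free, free)]
    b = (S_inv @ (Y.T @ Z)).ravel()[free]
    theta = np.linalg.solve(A, b)
    Theta = np.zeros((p, m))
    Theta.ravel()[free] = theta
    return Theta


def fit_ml(
    X,
    U=None,
    structure: MARStructure | None = None,
    *,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> FitResult:
    """Maximize the conditional likelihood under a sparsity structure.

    Initialization is deterministic: the masked least-squares solution
    with identity error weighting, with S set to the implied residual
    covariance.  Iteration alternates the exact masked GLS update of
    (B, C, a) given S with the exact update of S given the coefficients,
    stopping when the relative log-likelihood change falls below ``tol``.
    Entries masked out by the structure are exactly zero in the result.
    """
    Y, Z, var_names, cov_names = _transition_arrays(X, U)
    n, p = Y.shape
    if structure is None:
        structure = MARStructure.full(p, Z.shape[1] - p - 1)
    if structure.p != p or structure.q != Z.shape[1] - p - 1:
        raise ValueError("structure dimensions do not match the data")
    mask = structure.coefficient_mask()

    Theta = _solve_masked_gls(Y, Z, np.eye(p), mask)
    R = Y - Z @ Theta.T
    S = _project_S(R.T @ R / n, structure.S_form)

    def params_of(Theta, S):
        q = structure.q
        return MARParams(B=Theta[:, :p], C=Theta[:, p : p + q], a=Theta[:, -1], S=S)

    ll = conditional_loglik(params_of(Theta, S), X, U)
    converged = False
    it = 0
    rel_change = np.inf
    for it in range(1, max_iter + 1):
        Theta = _solve_masked_gls(Y, Z, np.linalg.inv(S), mask)
        R = Y - Z @ Theta.T
        S = _project_S(R.T @ R / n, structure.S_form)
        ll_new = conditional_loglik(params_of(Theta, S), X, U)
        rel_change = abs(ll_new - ll) / (abs(ll) + 1.0)
        ll = ll_new
        if rel_change < tol:
            converged = True
            break

    params = params_of(Theta, S)
    k = structure.k_free
    crit = aicc(ll, k, n) if n - k - 1 > 0 else np.inf
    return FitResult(
        params=params,
        structure=structure,
        loglik=ll,
        n_transitions=n,
        k_free=k,
        aicc=crit,
        convergence={"iterations": it, "rel_change": rel_change, "converged": converged},
        var_names=var_names,
        cov_names=cov_names,
    )


def predict_one_step(params: MARParams, x_prev, u_prev=None) -> np.ndarray:
    """Deterministic one-step forecast B x_prev + a + C u_prev."""
    x_prev = np.asarray(x_prev, dtype=float).reshape(params.p)
    out = params.B @ x_prev + params.a
    if params.q:
        if u_prev is None:
            raise ValueError("model has covariates; u_prev required")
        out = out + params.C @ np.asarray(u_prev, dtype=float).reshape(params.q)
    return out


def aicc(loglik: float, k_free: int, n_transitions: int) -> float:
    """Small-sample corrected Akaike criterion.

    AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1), with n the number of
    transitions actually used in the likelihood.
    """
    n, k = n_transitions, k_free
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n_transitions={n} <= k_free+1={k + 1}")
    return float(-2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1))
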