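"""Confidence intervals and significance labels for MAR coefficients.

An interaction is called significant when its 95% confidence interval
excludes zero — the criterion behind the red/blue/gray classification of
interaction-web plots.  Two interval constructions are provided: the
default curvature-based (Hessian) intervals from the observed
information at the optimum, and a parametric bootstrap that simulates
from the fitted model and refits, serving as the cross-check.  No
multiple-testing correction is applied across the coefficient table;
the intervals are per-coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .mar import FitResult, MARParams, MARStructure, conditional_loglik, fit_ml

__all__ = [
    "IntervalEstimate",
    "hessian_ci",
    "parametric_bootstrap_ci",
    "classify_interactions",
]


@dataclass
class IntervalEstimate:
    """Point estimate and CI for one coefficient of B, C or a.

    ``row`` / ``col`` are positional indices into the fit's variate and
    covariate orderings; ``row_name`` / ``col_name`` carry the taxon
    labels for reporting.  ``flag`` is empty for a clean interval and
    explains why bounds are absent otherwise (e.g. singular information
    matrix).
    """

    matrix: str
    row: int
    col: int
    row_name: str
    col_name: str
    estimate: float
    lower: float
    upper: float
    alpha: float
    method: str
    flag: str = ""

    def __post_init__(self) -> None:
        if not self.flag and not (self.lower <= self.estimate <= self.upper):
            raise ValueError(
                f"interval bounds do not bracket the estimate: "
                f"({self.lower}, {self.estimate}, {self.upper})"
            )

    @property
    def significant(self) -> bool:
        if self.flag or not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            return False
        return self.lower > 0 or self.upper < 0


def _free_addresses(structure: MARStructure, var_names, cov_names):
    """Free (B, C, a) coefficients in row-major order."""
    out = []
    for i in range(structure.p):
        for j in range(structure.p):
            if structure.B_mask[i, j]:
                out.append(("B", i, j, var_names[i], var_names[j]))
        for j in range(structure.q):
            if structure.C_mask[i, j]:
                out.append(("C", i, j, var_names[i], cov_names[j]))
        if structure.a_free[i]:
            out.append(("a", i, 0, var_names[i], ""))
    return out


def _pack(params: MARParams, structure: MARStructure) -> np.ndarray:
    pieces = []
    for matrix, i, j, _, _ in _free_addresses(
        structure, [""] * structure.p, [""] * max(structure.q, 1)
    ):
        source = {"B": params.B, "C": params.C}.get(matrix)
        pieces.append(source[i, j] if source is not None else params.a[i])
    return np.array(pieces)


def _unpack(theta: np.ndarray, structure: MARStructure, S: np.ndarray) -> MARParams:
    p, q = structure.p, structure.q
    B = np.zeros((p, p))
    C = np.zeros((p, q))
    a = np.zeros(p)
    k = 0
    for matrix, i, j, _, _ in _free_addresses(structure, [""] * p, [""] * max(q, 1)):
        if matrix == "B":
            B[i, j] = theta[k]
        elif matrix == "C":
            C[i, j] = theta[k]
        else:
            a[i] = theta[k]
        k += 1
    return MARParams(B=B, C=C, a=a, S=S)


def _numerical_hessian(f, theta0: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian with per-coordinate relative steps."""
    k = theta0.size
    h = rel_step * np.maximum(np.abs(theta0), 1.0)
    H = np.empty((k, k))
    f0 = f(theta0)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (f(theta0 + ei) - 2.0 * f0 + f(theta0 - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(theta0 + ei + ej) - f(theta0 + ei - ej)
                - f(theta0 - ei + ej) + f(theta0 - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def hessian_ci(fit: FitResult, X, U=None, alpha: float = 0.05) -> list[IntervalEstimate]:
    """Normal intervals from the observed information at the optimum.

    The Hessian of the conditional log-likelihood with respect to the
    free (B, C, a) coefficients is computed by central finite
    differences (relative step 1e-5) with S held at its maximum
    likelihood value; standard errors are the square roots of the
    diagonal of the inverse negative Hessian and intervals are
    estimate ± z_{1-alpha/2} * se.  Coefficients whose curvature cannot
    be inverted are flagged rather than given fabricated bounds.
    """
    if not fit.converged:
        raise ValueError("confidence intervals require a converged fit")
    structure = fit.structure
    addresses = _free_addresses(structure, fit.var_names, fit.cov_names)
    theta0 = _pack(fit.params, structure)
    S = fit.params.S

    def negfree_loglik(theta):
        return conditional_loglik(_unpack(theta, structure, S), X, U)

    H = _numerical_hessian(negfree_loglik, theta0)
    info = -H
    variances = np.full(theta0.size, np.nan)
    flag = ""
    try:
        cov = np.linalg.inv(info)
        diag = np.diag(cov)
        if np.all(diag > 0):
            variances = diag
        else:
            flag = "non-positive curvature"
    except np.linalg.LinAlgError:
        flag = "singular information matrix"

    z = stats.norm.ppf(1.0 - alpha / 2.0)
    out = []
    for k, (matrix, i, j, rname, cname) in enumerate(addresses):
        se = np.sqrt(variances[k]) if np.isfinite(variances[k]) else np.nan
        if np.isfinite(se):
            lo, hi = theta0[k] - z * se, theta0[k] + z * se
            this_flag = ""
        else:
            lo = hi = np.nan
            this_flag = flag or "no standard error"
        out.append(IntervalEstimate(
            matrix=matrix, row=i, col=j, row_name=rname, col_name=cname,
            estimate=float(theta0[k]), lower=float(lo), upper=float(hi),
            alpha=alpha, method="hessian", flag=this_flag,
        ))
    return out


def parametric_bootstrap_ci(
    fit: FitResult, X, U=None, n_boot: int = 1000, seed: int = 0,
    alpha: float = 0.05,
) -> list[IntervalEstimate]:
    """Percentile intervals from refits of model-simulated series.

    ``n_boot`` series are simulated from the fitted parameters
    (conditioning on the observed covariates and the first observed
    state), each refit under the same structure; interval bounds are the
    order statistics of the replicate draws at ranks floor(n*alpha/2)
    and n-1-floor(n*alpha/2) of the sorted values.  Replicates that fail
    to converge are dropped and counted; losing more than 10% of them
    flags every interval.
    """
    if not fit.converged:
        raise ValueError("bootstrap requires a converged fit")
    rng = np.random.default_rng(seed)
    Xa = np.asarray(X, dtype=float) if not hasattr(X, "to_numpy") else X.to_numpy(dtype=float)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    if U is None:
        Ua = np.zeros((Xa.shape[0], 0))
    else:
        Ua = np.asarray(U, dtype=float) if not hasattr(U, "to_numpy") else U.to_numpy(dtype=float)
        if Ua.ndim == 1:
            Ua = Ua[:, None]
    T = Xa.shape[0]
    first_valid = np.flatnonzero(np.isfinite(Xa).all(axis=1))[0]
    x1 = Xa[first_valid]

    structure = fit.structure
    addresses = _free_addresses(structure, fit.var_names, fit.cov_names)
    draws = np.full((n_boot, len(addresses)), np.nan)
    dropped = 0
    params = fit.params
    vals, vecs = np.linalg.eigh(0.5 * (params.S + params.S.T))
    chol = vecs * np.sqrt(np.clip(vals, 0.0, None))
    for b in range(n_boot):
        Xb = np.zeros((T, structure.p))
        Xb[0] = x1
        noise = rng.standard_normal((T, structure.p))
        for t in range(1, T):
            drive = params.C @ Ua[t - 1] if params.q else 0.0
            Xb[t] = params.B @ Xb[t - 1] + params.a + drive + chol @ noise[t]
        refit = fit_ml(Xb, Ua if params.q else None, structure)
        if not refit.converged:
            dropped += 1
            continue
        draws[b] = _pack(refit.params, structure)

    ok = np.isfinite(draws).all(axis=1)
    kept = draws[ok]
    n_kept = kept.shape[0]
    flag = ""
    if n_kept == 0:
        raise RuntimeError("all bootstrap replicates failed to converge")
    if dropped > 0.10 * n_boot:
        flag = f"{dropped}/{n_boot} bootstrap replicates dropped"

    theta0 = _pack(fit.params, structure)
    k_lo = int(np.floor(n_kept * alpha / 2.0))
    out = []
    for k, (matrix, i, j, rname, cname) in enumerate(addresses):
        srt = np.sort(kept[:, k])
        lo, hi = srt[k_lo], srt[n_kept - 1 - k_lo]
        # degenerate generators can put the point estimate at the boundary
        lo, hi = min(lo, theta0[k]), max(hi, theta0[k])
        out.append(IntervalEstimate(
            matrix=matrix, row=i, col=j, row_name=rname, col_name=cname,
            estimate=float(theta0[k]), lower=float(lo), upper=float(hi),
            alpha=alpha, method="bootstrap", flag=flag,
        ))
    return out


def classify_interactions(estimates: list[IntervalEstimate]):
    """Label each coefficient by the sign test of its interval.

    Returns a table with one row per coefficient: significant-positive
    when the whole interval is above zero, significant-negative when
    below, not-significant otherwise.  Diagonal B entries are marked as
    density dependence — the self-limitation term of each taxon's
    growth.
    """
    import pandas as pd

    rows = []
    for e in estimates:
        if e.significant and e.lower > 0:
            label = "significant-positive"
        elif e.significant:
            label = "significant-negative"
        else:
            label = "not-significant"
        rows.append({
            "matrix": e.matrix,
            "predictor": e.col_name if e.matrix != "a" else "(intercept)",
            "response": e.row_name,
            "estimate": e.estimate,
            "lower": e.lower,
            "upper": e.upper,
            "alpha": e.alpha,
            "method": e.method,
            "significant": e.significant,
            "label": label,
            "density_dependence": e.matrix == "B" and e.row == e.col,
            "flag": e.flag,
        })
    return pd.DataFrame(rows)
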