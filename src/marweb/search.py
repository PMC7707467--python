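"""Structure search, residual diagnostics and stability metrics.

The robustness of a fitted interaction web is probed by permuting the
model structure: starting from the fully parameterized model, free
off-diagonal interaction terms and covariate effects are pruned one at a
time, greedily accepting the single removal that most decreases AICc
until no removal helps.  Diagonal B entries (density dependence) and the
intercepts are never pruned — every taxon keeps self-limitation and an
intrinsic rate — and focal covariates can be locked in so the question
the model was built for stays answerable.

Diagnostics quantify what a residual plot would show (per-taxon moments,
lag-1 autocorrelation, a Ljung-Box portmanteau over lags 1-12) and
summarize the stability of the fitted dynamics (spectral radius of B,
stationary covariance from the discrete Lyapunov equation when the
process is stable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from statsmodels.stats.diagnostic import acorr_ljungbox

from .mar import FitResult, MARParams, MARStructure, fit_ml

__all__ = [
    "SearchSettings",
    "SearchReport",
    "DiagnosticsReport",
    "candidate_structures",
    "search_best",
    "residual_diagnostics",
    "stability_metrics",
]


@dataclass
class SearchSettings:
    """Knobs of the greedy backward search."""

    locked_covariates: tuple[int, ...] = ()  # C columns never pruned
    max_steps: int = 10_000
    S_form: str = "diagonal"


@dataclass
class SearchReport:
    """Scored candidates and the selected structure."""

    records: pd.DataFrame
    selected: MARStructure
    selected_fit: FitResult
    criterion: str = "AICc"
    tie_break: str = "fewer free parameters, then lexicographic coefficient address"


@dataclass
class DiagnosticsReport:
    """Residual summaries plus the stability block."""

    residual_table: pd.DataFrame
    spectral_radius: float
    stationary_cov: np.ndarray | None = None
    portmanteau_lags: int = 12


def candidate_structures(
    base: MARStructure,
    mode: str = "prune-one",
    locked_covariates: tuple[int, ...] = (),
) -> list[tuple[tuple[str, int, int], MARStructure]]:
    """Neighbors of a structure, keyed by the toggled coefficient address.

    ``prune-one`` masks exactly one currently free off-diagonal B entry
    or free C entry; ``grow-one`` frees one currently masked such entry.
    Diagonal B entries and the intercepts are never touched; C columns
    listed in ``locked_covariates`` are exempt from pruning.
    """
    if mode not in ("prune-one", "grow-one"):
        raise ValueError("mode must be 'prune-one' or 'grow-one'")
    target = mode == "grow-one"
    out = []
    for i in range(base.p):
        for j in range(base.p):
            if i != j and base.B_mask[i, j] != target:
                out.append((("B", i, j), base.with_entry("B", i, j, target)))
        for j in range(base.q):
            if j in locked_covariates and not target:
                continue
            if base.C_mask[i, j] != target:
                out.append((("C", i, j), base.with_entry("C", i, j, target)))
    return out


def search_best(
    X,
    U=None,
    base: MARStructure | None = None,
    settings: SearchSettings | None = None,
) -> SearchReport:
    """Greedy backward AICc pruning from the fully parameterized model.

    At each step every prune-one candidate is refit; the candidate with
    the lowest AICc is accepted if it improves on the current model, with
    ties broken toward the lexicographically smallest pruned coefficient
    address.  Candidates that fail to converge are skipped and logged.
    Deterministic given data and settings.
    """
    settings = settings or SearchSettings()
    current_fit = fit_ml(X, U, base) if base is not None else None
    if current_fit is None:
        probe = fit_ml(X, U, None)
        base = MARStructure.full(probe.structure.p, probe.structure.q, settings.S_form)
        current_fit = fit_ml(X, U, base)
    if not current_fit.converged:
        raise RuntimeError("base structure fit did not converge")

    records = [{
        "step": 0, "pruned": "(full)", "k_free": current_fit.k_free,
        "loglik": current_fit.loglik, "aicc": current_fit.aicc,
        "converged": current_fit.converged, "accepted": True,
    }]
    step = 0
    while step < settings.max_steps:
        step += 1
        candidates = candidate_structures(
            current_fit.structure, "prune-one", settings.locked_covariates
        )
        if not candidates:
            break
        best = None  # (aicc, address, fit)
        best_rec = None
        for address, cand in sorted(candidates, key=lambda c: c[0]):
            fit = fit_ml(X, U, cand)
            records.append({
                "step": step, "pruned": f"{address[0]}[{address[1]},{address[2]}]",
                "k_free": fit.k_free, "loglik": fit.loglik, "aicc": fit.aicc,
                "converged": fit.converged, "accepted": False,
            })
            if not fit.converged:
                continue
            # strict improvement keeps the lexicographically smallest
            # address on ties (candidates are visited in sorted order)
            if best is None or fit.aicc < best[0] - 1e-12:
                best = (fit.aicc, address, fit)
                best_rec = len(records) - 1
        if best is None or best[0] >= current_fit.aicc:
            break
        current_fit = best[2]
        records[best_rec]["accepted"] = True
    table = pd.DataFrame(records)
    return SearchReport(records=table, selected=current_fit.structure,
                        selected_fit=current_fit)


def residual_diagnostics(fit: FitResult, X, U=None, lags: int = 12) -> DiagnosticsReport:
    """One-step-ahead residual summaries and stability of the fitted B.

    Residuals are r_t = x_t − (B x_{t-1} + a + C u_{t-1}) over complete
    transitions.  The portmanteau statistic is the Ljung-Box Q over lags
    1..``lags``; under a correctly specified model the residuals are
    white and Q is approximately chi-square.
    """
    Xa = X.to_numpy(dtype=float) if hasattr(X, "to_numpy") else np.asarray(X, dtype=float)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    if U is None:
        Ua = np.zeros((Xa.shape[0], 0))
    else:
        Ua = U.to_numpy(dtype=float) if hasattr(U, "to_numpy") else np.asarray(U, dtype=float)
        if Ua.ndim == 1:
            Ua = Ua[:, None]
    params = fit.params
    names = fit.var_names or [f"x{i+1}" for i in range(params.p)]
    preds = Xa[:-1] @ params.B.T + params.a
    if params.q:
        preds = preds + Ua[:-1] @ params.C.T
    resid = Xa[1:] - preds
    ok = np.isfinite(resid).all(axis=1)
    resid = resid[ok]

    rows = []
    for i, name in enumerate(names):
        r = resid[:, i]
        n = r.size
        rc = r - r.mean()
        denom = np.sum(rc**2)
        acf1 = float(np.sum(rc[:-1] * rc[1:]) / denom) if denom > 0 else np.nan
        use_lags = min(lags, n - 1)
        if denom > 0 and use_lags >= 1:
            lb = acorr_ljungbox(r, lags=[use_lags], return_df=True)
            q_stat = float(lb["lb_stat"].iloc[0])
            q_pvalue = float(lb["lb_pvalue"].iloc[0])
        else:
            q_stat = q_pvalue = np.nan
        rows.append({
            "taxon": name,
            "resid_mean": float(r.mean()),
            "resid_sd": float(r.std(ddof=1)) if n > 1 else 0.0,
            "lag1_acf": acf1,
            "portmanteau_q": q_stat,
            "portmanteau_pvalue": q_pvalue,
            "n": n,
        })
    radius, V = stability_metrics(params)
    return DiagnosticsReport(
        residual_table=pd.DataFrame(rows),
        spectral_radius=radius,
        stationary_cov=V,
        portmanteau_lags=lags,
    )


def stability_metrics(params: MARParams) -> tuple[float, np.ndarray | None]:
    """Spectral radius of B and, when stable, the stationary covariance.

    The stationary covariance V of a stable MAR process solves the
    discrete Lyapunov equation V = B V B' + S; it is reported only when
    the spectral radius is below one (no stationary distribution exists
    otherwise).
    """
    radius = float(np.max(np.abs(np.linalg.eigvals(params.B))))
    if radius >= 1.0:
        return radius, None
    V = linalg.solve_discrete_lyapunov(params.B, params.S)
    return radius, V
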