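"""File formats, configuration and the end-to-end pipeline.

Input data travel as long CSV (date, taxon, replicate, value, unit);
results are written as commented CSV so every file names its units and
conventions.  :func:`run_pipeline` ties the stages together — simulate
or load, preprocess, fit/search, confidence intervals, diagnostics,
reports — and records a machine-readable manifest so a run can be
reproduced byte for byte from its configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .mar import MARStructure, fit_ml
from .preprocess import CommunityTimeSeries, aggregate_taxa, build_design_matrices
from .search import SearchSettings, residual_diagnostics, search_best
from .synthetic import (
    INVADER_COVARIATES,
    default_scenario,
    embed_in_abundance,
    invader_share,
    recovery_metrics,
    simulate_anomalies,
)
from .uncertainty import classify_interactions, hessian_ci, parametric_bootstrap_ci

logger = logging.getLogger("marweb")

__all__ = [
    "PipelineConfig",
    "read_long_csv",
    "write_long_csv",
    "write_interaction_report",
    "run_pipeline",
]

_LONG_COLUMNS = ["date", "taxon", "replicate", "value", "unit"]


def read_long_csv(path) -> pd.DataFrame:
    """Read and validate a long-format monthly abundance/covariate table.

    Expected header: date (ISO year-month), taxon, replicate, value,
    unit.  Malformed rows (unparseable dates, non-numeric or negative
    abundance values, duplicate date/taxon/replicate keys) are collected
    and reported together with their line numbers.
    """
    tbl = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    missing = [c for c in _LONG_COLUMNS[:4] if c not in tbl.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if "unit" not in tbl.columns:
        tbl["unit"] = ""
    errors = []
    # line numbers are 1-based and account for the header row
    lines = tbl.index + 2

    dates = pd.PeriodIndex([pd.NaT] * len(tbl), freq="M")
    try:
        dates = pd.PeriodIndex(tbl["date"], freq="M")
    except Exception:
        parsed = []
        for line, raw in zip(lines, tbl["date"]):
            try:
                parsed.append(pd.Period(raw, freq="M"))
            except Exception:
                parsed.append(pd.NaT)
                errors.append(f"line {line}: unparseable date {raw!r}")
        dates = pd.PeriodIndex(parsed, freq="M")

    values = pd.to_numeric(tbl["value"], errors="coerce")
    for line, raw, val in zip(lines, tbl["value"], values):
        if pd.isna(val) and str(raw).strip() not in ("", "nan", "NA"):
            errors.append(f"line {line}: non-numeric value {raw!r}")
        elif pd.notna(val) and val < 0:
            errors.append(f"line {line}: negative abundance {val}")

    dup = tbl.duplicated(subset=["date", "taxon", "replicate"], keep=False)
    if dup.any():
        for line, row in zip(lines[dup], tbl.loc[dup, ["date", "taxon", "replicate"]].itertuples(index=False)):
            errors.append(f"line {line}: duplicate key {tuple(row)}")
    if errors:
        raise ValueError(f"{path}: malformed rows:\n" + "\n".join(errors))

    out = pd.DataFrame({
        "date": dates,
        "taxon": tbl["taxon"],
        "replicate": tbl["replicate"],
        "value": values,
        "unit": tbl["unit"].fillna(""),
    })
    return out


def write_long_csv(series: CommunityTimeSeries, path) -> None:
    """Write a community panel in the long CSV dialect (one replicate)."""
    records = []
    for taxon in series.taxa:
        col = series.data[taxon]
        for when, val in col.items():
            records.append({
                "date": str(when),
                "taxon": taxon,
                "replicate": 1,
                "value": "" if pd.isna(val) else repr(float(val)),
                "unit": series.units.get(taxon, ""),
            })
    out = pd.DataFrame(records, columns=_LONG_COLUMNS)
    with open(path, "w") as fh:
        fh.write("# long-format monthly series: date=ISO year-month, empty value=missing\n")
        out.to_csv(fh, index=False)


def _write_commented_csv(df: pd.DataFrame, path, comment: str, index=True) -> None:
    with open(path, "w") as fh:
        for line in comment.splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=index)


def write_interaction_report(estimates, path_prefix) -> dict[str, Path]:
    """Write the coefficient table and the signed-magnitude matrix.

    ``<prefix>_table.csv`` mirrors the layout of a per-coefficient
    report: predictor, response, estimate, CI bounds, significance.
    ``<prefix>_matrix.csv`` is the p x (p+q) effect matrix (columns act
    on rows); structurally zero entries appear as exact literal 0,
    distinguishing them from estimated-near-zero coefficients which keep
    full precision.
    """
    if not estimates:
        raise ValueError("no interval estimates to report")
    prefix = Path(path_prefix)
    table = classify_interactions(estimates)
    table_path = prefix.with_name(prefix.name + "_table.csv")
    _write_commented_csv(
        table,
        table_path,
        "MAR coefficient report: estimates in z-score units, per-coefficient "
        f"{100 * (1 - estimates[0].alpha):.0f}% confidence intervals "
        f"(method={estimates[0].method}); columns act on rows",
        index=False,
    )

    b_est = {(e.row_name, e.col_name): e.estimate for e in estimates if e.matrix == "B"}
    c_est = {(e.row_name, e.col_name): e.estimate for e in estimates if e.matrix == "C"}
    rows = sorted({e.row_name for e in estimates})
    rows = list(dict.fromkeys([e.row_name for e in estimates]))
    b_cols = list(dict.fromkeys([e.col_name for e in estimates if e.matrix == "B"]))
    c_cols = list(dict.fromkeys([e.col_name for e in estimates if e.matrix == "C"]))
    matrix = pd.DataFrame(0.0, index=rows, columns=b_cols + c_cols)
    for (r, c), v in {**b_est, **c_est}.items():
        matrix.loc[r, c] = v
    formatted = matrix.map(lambda v: "0" if v == 0.0 else repr(v))
    matrix_path = prefix.with_name(prefix.name + "_matrix.csv")
    _write_commented_csv(
        formatted,
        matrix_path,
        "signed effect matrix (z-score units): column taxon acts on row taxon;\n"
        "literal 0 = structurally excluded coefficient",
    )
    return {"table": table_path, "matrix": matrix_path}


@dataclass
class PipelineConfig:
    """Validated configuration of one full analysis run."""

    outdir: str
    seed: int = 0
    # input: either a synthetic scenario or a long CSV + grouping map
    synthetic: bool = True
    n_years: int = 12
    abundance_csv: str | None = None
    grouping: dict[str, str] = field(default_factory=dict)
    variates: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)
    locked_covariates: list[str] = field(default_factory=lambda: list(INVADER_COVARIATES))
    categories: dict[str, str] = field(default_factory=dict)
    run_search: bool = True
    S_form: str = "diagonal"
    ci_method: str = "hessian"
    alpha: float = 0.05
    n_boot: int = 1000
    max_gap: int = 1

    def __post_init__(self) -> None:
        overlap = set(self.variates) & set(self.covariates)
        if overlap:
            raise ValueError(f"taxa cannot be both variate and covariate: {sorted(overlap)}")
        if self.ci_method not in ("hessian", "bootstrap"):
            raise ValueError("ci_method must be 'hessian' or 'bootstrap'")
        if not self.synthetic and not self.abundance_csv:
            raise ValueError("non-synthetic runs need abundance_csv")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def canonical(self) -> str:
        payload = {k: v for k, v in sorted(self.__dict__.items())}
        return json.dumps(payload, sort_keys=True, default=str)

    def sha256(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()


def _load_series(config: PipelineConfig):
    """Stage 1: obtain the community panel (synthetic or from disk)."""
    if config.synthetic:
        scenario = default_scenario(seed=config.seed, n_years=config.n_years)
        X_true, U_true = simulate_anomalies(scenario)
        series = embed_in_abundance(X_true, scenario, covariates=U_true)
        return series, scenario, X_true
    long_tbl = read_long_csv(config.abundance_csv)
    grouping = config.grouping or {t: t for t in long_tbl["taxon"].unique()}
    roles = {t: "variate" for t in config.variates}
    roles.update({t: "covariate" for t in config.covariates})
    units = dict(zip(long_tbl["taxon"], long_tbl["unit"]))
    series = aggregate_taxa(
        long_tbl, grouping, roles=roles, units=units, categories=config.categories
    )
    known = set(series.taxa)
    unknown = [t for t in config.variates + config.covariates if t not in known]
    if unknown:
        raise ValueError(f"configured taxa absent after grouping: {unknown}")
    return series, None, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute preprocess -> fit/search -> CIs -> diagnostics -> reports.

    Writes all artifacts plus ``manifest.json`` into ``config.outdir``
    and returns a dict of artifact paths.  On stage failure a FAILED
    marker naming the stage is left next to any partial artifacts and
    the exception is re-raised.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    artifacts: dict[str, Path] = {"log": log_path}
    stage = "setup"
    stage_log = []

    def _log(stage, t0, **info):
        rec = {"stage": stage, "wall_s": round(time.perf_counter() - t0, 3), **info}
        stage_log.append(rec)
        logger.info("%s", rec)

    try:
        stage = "load"
        t0 = time.perf_counter()
        series, scenario, true_anomalies = _load_series(config)
        if config.synthetic:
            input_path = outdir / "abundance_long.csv"
            write_long_csv(series, input_path)
            artifacts["abundance"] = input_path
        _log(stage, t0, rows=len(series.data), taxa=len(series.taxa))

        stage = "preprocess"
        t0 = time.perf_counter()
        design = build_design_matrices(series, max_gap=config.max_gap)
        _write_commented_csv(
            pd.concat([design.X, design.U], axis=1),
            outdir / "design_matrices.csv",
            "de-seasoned z-scores (dimensionless); one row per month; "
            "variates then covariates",
        )
        _write_commented_csv(
            design.scale,
            outdir / "scale_record.csv",
            "per-series mean and sample sd (ddof=1) removed by standardization",
        )
        artifacts["design"] = outdir / "design_matrices.csv"
        artifacts["scale"] = outdir / "scale_record.csv"
        _log(stage, t0, variates=design.X.shape[1], covariates=design.U.shape[1])

        stage = "fit"
        t0 = time.perf_counter()
        p, q = design.X.shape[1], design.U.shape[1]
        base = MARStructure.full(p, q, config.S_form)
        if config.run_search:
            locked = tuple(
                j for j, name in enumerate(design.U.columns)
                if name in set(config.locked_covariates)
            )
            report = search_best(
                design.X, design.U, base,
                SearchSettings(locked_covariates=locked, S_form=config.S_form),
            )
            fit = report.selected_fit
            _write_commented_csv(
                report.records, outdir / "search_report.csv",
                f"greedy backward structure search, criterion={report.criterion}; "
                f"tie break: {report.tie_break}", index=False,
            )
            artifacts["search"] = outdir / "search_report.csv"
        else:
            fit = fit_ml(design.X, design.U, base)
        _log(stage, t0, k_free=fit.k_free, aicc=round(fit.aicc, 3),
             converged=fit.converged)

        stage = "ci"
        t0 = time.perf_counter()
        if config.ci_method == "hessian":
            estimates = hessian_ci(fit, design.X, design.U, alpha=config.alpha)
        else:
            estimates = parametric_bootstrap_ci(
                fit, design.X, design.U, n_boot=config.n_boot,
                seed=config.seed, alpha=config.alpha,
            )
        paths = write_interaction_report(estimates, outdir / "interactions")
        artifacts.update(paths)
        _log(stage, t0, n_coefficients=len(estimates),
             n_significant=sum(e.significant for e in estimates))

        stage = "diagnostics"
        t0 = time.perf_counter()
        diag = residual_diagnostics(fit, design.X, design.U)
        _write_commented_csv(
            diag.residual_table, outdir / "diagnostics.csv",
            "one-step residual summaries; portmanteau = Ljung-Box Q over "
            f"lags 1..{diag.portmanteau_lags}; spectral radius of fitted B = "
            f"{diag.spectral_radius:.6f}", index=False,
        )
        artifacts["diagnostics"] = outdir / "diagnostics.csv"
        _log(stage, t0, spectral_radius=round(diag.spectral_radius, 4))

        if config.synthetic and scenario is not None:
            stage = "recovery"
            t0 = time.perf_counter()
            truth_structure = MARStructure(
                B_mask=scenario.true_B != 0,
                C_mask=scenario.true_C != 0,
                a_free=np.ones(len(scenario.variate_names), dtype=bool),
                S_form=config.S_form,
            )
            truth_fit = fit_ml(design.X, design.U, truth_structure)
            metrics = recovery_metrics(truth_fit, scenario)
            _write_commented_csv(
                metrics, outdir / "recovery_metrics.csv",
                "estimates of the generating coefficients when refitting the "
                "true structure on this realization (z-score units)", index=False,
            )
            share = invader_share(series, [n for n in INVADER_COVARIATES if n in series.taxa])
            _write_commented_csv(
                share.rename("invader_share").to_frame(),
                outdir / "invader_share.csv",
                "monthly fraction of zooplankton abundance from invader taxa",
            )
            artifacts["recovery"] = outdir / "recovery_metrics.csv"
            artifacts["invader_share"] = outdir / "invader_share.csv"
            _log(stage, t0, max_share=round(float(share.max()), 4))

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "config_sha256": config.sha256(),
            "seed": config.seed,
            "config": json.loads(config.canonical()),
            "stages": stage_log,
            "artifacts": {k: str(v) for k, v in artifacts.items()},
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        artifacts["manifest"] = outdir / "manifest.json"
        with open(log_path, "w") as fh:
            for rec in stage_log:
                fh.write(json.dumps(rec) + "\n")
        return artifacts
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise
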