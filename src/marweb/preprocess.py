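"""De-seasoning and standardization of monthly plankton time series.

Raw monitoring data arrive as per-taxon counts or densities on a monthly
grid.  Before they can feed a first-order multivariate autoregressive
(MAR) model the series are reduced to dimensionless anomalies:

    counts -> density -> functional-group aggregation -> log(x+1)
           -> gap interpolation -> monthly climatology -> de-seasoning
           -> z-scores

Each stage is a standalone function; :func:`build_design_matrices` runs
the chain from a :class:`CommunityTimeSeries` to the matrices the fitter
consumes.  Missing values are carried as NaN together with an explicit
boolean mask; no sentinel numbers are ever used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CommunityTimeSeries",
    "Climatology",
    "DesignMatrices",
    "counts_to_density",
    "aggregate_taxa",
    "log1p_transform",
    "monthly_climatology",
    "deseason",
    "standardize",
    "interpolate_gaps",
    "build_design_matrices",
]

VALID_ROLES = ("variate", "covariate", "excluded")


@dataclass
class CommunityTimeSeries:
    """Monthly abundance/covariate panel with taxon metadata.

    Parameters
    ----------
    data
        Wide table, one row per calendar month (monotone monthly
        :class:`pandas.PeriodIndex`), one column per taxon.  NaN marks a
        missing observation.  Abundances are non-negative; environmental
        series (e.g. temperature) may take any value.
    roles
        Map taxon -> role in the MAR model: ``"variate"`` (modeled
        dynamically), ``"covariate"`` (external forcing) or
        ``"excluded"``.
    units
        Map taxon -> unit string (carried as metadata, never
        interpreted).
    categories
        Map taxon -> community category, e.g. ``"zooplankton"``,
        ``"microplankton"`` or ``"environmental"``.  Used by the
        invader-share statistic and to decide which series are log
        transformed.
    """

    data: pd.DataFrame
    roles: dict[str, str] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.data.index
        if not isinstance(idx, pd.PeriodIndex) or idx.freqstr not in ("M", "ME"):
            raise ValueError("time index must be a monthly PeriodIndex")
        if len(idx) > 1:
            steps = np.diff(idx.asi8)
            if not np.all(steps == 1):
                raise ValueError("time index must be consecutive calendar months")
        for taxon, role in self.roles.items():
            if role not in VALID_ROLES:
                raise ValueError(f"invalid role {role!r} for taxon {taxon!r}")
        for taxon in self.data.columns:
            self.roles.setdefault(taxon, "variate")
            if self.categories.get(taxon) != "environmental":
                col = self.data[taxon]
                if (col.dropna() < 0).any():
                    raise ValueError(f"negative abundance in taxon {taxon!r}")

    @property
    def missing(self) -> pd.DataFrame:
        """Boolean mask, True where an observation is missing."""
        return self.data.isna()

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    def taxa_with_role(self, role: str) -> list[str]:
        return [t for t in self.data.columns if self.roles.get(t) == role]


@dataclass
class Climatology:
    """Long-term monthly means per taxon, on the (log) scale supplied.

    ``means`` and ``counts`` are 12-row frames indexed by calendar month
    (1..12); ``counts`` records how many years contributed to each mean.
    """

    means: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        expected = pd.Index(range(1, 13), name="month")
        if not self.means.index.equals(expected):
            raise ValueError("climatology must have one row per calendar month 1..12")
        bad = self.means.notna() & ~np.isfinite(self.means.fillna(0.0))
        if bad.any().any():
            raise ValueError("non-finite climatology mean")


@dataclass
class DesignMatrices:
    """Z-scored variate (X) and covariate (U) matrices ready for fitting.

    Row t of U is the covariate value at the same calendar month as row t
    of X; the one-month lag of the MAR model is applied inside the
    fitter, not here.  ``scale`` records the mean and standard deviation
    (sample sd, ddof=1) removed from every series so the transform is
    auditable and invertible.
    """

    X: pd.DataFrame
    U: pd.DataFrame
    scale: pd.DataFrame  # rows: mean, sd; columns: all series


def counts_to_density(count, sample_volume, subsample_volume, filtered_volume):
    """Convert a microscopy count to a density in individuals per m^3.

    The subsample count is scaled up by the ratio of sample volume to
    subsample volume and divided by the total volume of water filtered
    through the net.

    ``density = count * (sample_volume / subsample_volume) / filtered_volume``
    """
    for name, vol in (
        ("sample_volume", sample_volume),
        ("subsample_volume", subsample_volume),
        ("filtered_volume", filtered_volume),
    ):
        if np.any(np.asarray(vol) <= 0):
            raise ValueError(f"{name} must be positive")
    if np.any(np.asarray(subsample_volume) > np.asarray(sample_volume)):
        raise ValueError("subsample_volume cannot exceed sample_volume")
    count = np.asarray(count, dtype=float)
    if np.any(count[~np.isnan(count)] < 0):
        raise ValueError("count must be non-negative")
    out = count * (np.asarray(sample_volume, float) / np.asarray(subsample_volume, float))
    out = out / np.asarray(filtered_volume, float)
    return out if out.ndim else float(out)


def aggregate_taxa(
    long_table: pd.DataFrame,
    grouping: dict[str, str],
    *,
    roles: dict[str, str] | None = None,
    units: dict[str, str] | None = None,
    categories: dict[str, str] | None = None,
) -> CommunityTimeSeries:
    """Collapse a long (date, taxon, replicate, value) table into groups.

    Replicate samples from the same date are averaged per taxon before
    taxa are summed into their functional / higher-level groups.  Taxa
    mapped to ``"excluded"`` are dropped (the route used for rare taxa
    and for irregular invaders kept out of the model).

    Raises ``ValueError`` listing unmapped taxa, and rejects duplicate
    (date, taxon, replicate) rows.
    """
    tbl = long_table.copy()
    tbl["date"] = pd.PeriodIndex(tbl["date"], freq="M")

    unmapped = sorted(set(tbl["taxon"]) - set(grouping))
    if unmapped:
        raise ValueError(f"taxa missing from grouping map: {unmapped}")
    dup = tbl.duplicated(subset=["date", "taxon", "replicate"])
    if dup.any():
        rows = tbl.loc[dup, ["date", "taxon", "replicate"]].astype(str).agg(" ".join, axis=1)
        raise ValueError("duplicate (date, taxon, replicate) rows: " + "; ".join(rows))

    # mean over replicates within a sampling date, then sum member taxa
    per_taxon = tbl.groupby(["date", "taxon"], observed=True)["value"].mean().reset_index()
    per_taxon["group"] = per_taxon["taxon"].map(grouping)
    per_taxon = per_taxon[per_taxon["group"] != "excluded"]
    grouped = per_taxon.groupby(["date", "group"], observed=True)["value"].sum().unstack("group")

    full_index = pd.period_range(grouped.index.min(), grouped.index.max(), freq="M")
    full_index.name = "date"
    grouped = grouped.reindex(full_index)
    grouped.columns.name = None
    return CommunityTimeSeries(
        grouped,
        roles=dict(roles or {}),
        units=dict(units or {}),
        categories=dict(categories or {}),
    )


def log1p_transform(values):
    """Apply ln(x+1); NaN (missing) propagates unchanged."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("log1p_transform requires non-negative values")
    out = np.log1p(arr)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def monthly_climatology(log_series: pd.DataFrame) -> Climatology:
    """Per-taxon mean of every calendar month across all observed years.

    Missing entries are omitted from both the numerator and the count; a
    calendar month with no observation at all for some taxon is an
    error (the anomaly of that month would be undefined).
    """
    months = log_series.index.month
    means = log_series.groupby(months).mean()
    counts = log_series.groupby(months).count()
    means.index.name = counts.index.name = "month"
    means = means.reindex(range(1, 13))
    counts = counts.reindex(range(1, 13), fill_value=0)
    means.index.name = counts.index.name = "month"
    empty = counts == 0
    present_months = set(log_series.index.month)
    empty = empty.loc[sorted(present_months)]
    if empty.any().any():
        bad = [
            f"{taxon}/month {month}"
            for taxon in empty.columns
            for month in empty.index[empty[taxon]]
        ]
        raise ValueError("calendar months with no observations: " + ", ".join(bad))
    return Climatology(means=means, counts=counts)


def deseason(log_series: pd.DataFrame, clim: Climatology) -> pd.DataFrame:
    """Subtract each taxon's monthly climatology: anomaly = raw − climatology.

    Positive anomalies therefore mean above the seasonal average, so a
    positive interaction coefficient downstream reads as "more of taxon j
    last month, more of taxon i this month".
    """
    missing_cols = set(log_series.columns) - set(clim.means.columns)
    if missing_cols:
        raise ValueError(f"climatology missing taxa: {sorted(missing_cols)}")
    offsets = clim.means.loc[log_series.index.month, log_series.columns]
    offsets.index = log_series.index
    return log_series - offsets


def standardize(anomaly_series: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convert anomalies to dimensionless z-scores, one global scale per series.

    The mean and sample standard deviation (ddof=1) are taken over the
    whole record of each series, not per calendar month, so that every
    variable carries exactly one scale.  Returns the z-scores and a
    scale record with rows ``mean`` and ``sd``.
    """
    mean = anomaly_series.mean()
    sd = anomaly_series.std(ddof=1)
    flat = sd.index[(sd == 0) | sd.isna()].tolist()
    if flat:
        raise ValueError(
            f"zero-variance series (no dynamical information): {flat}"
        )
    z = (anomaly_series - mean) / sd
    scale = pd.DataFrame({"mean": mean, "sd": sd}).T
    return z, scale


def interpolate_gaps(
    series: pd.DataFrame, max_gap: int = 1
) -> tuple[pd.DataFrame, list[dict]]:
    """Fill short interior gaps linearly; report the rest.

    Runs of at most ``max_gap`` consecutive missing months that are
    flanked by observations on both sides are replaced by linear
    interpolation between the flanking values.  Longer runs and
    leading/trailing gaps are left missing and listed in the returned
    report (taxon, start period, length).
    """
    filled = series.copy()
    report: list[dict] = []
    for taxon in series.columns:
        col = series[taxon].to_numpy(dtype=float)
        isna = np.isnan(col)
        if not isna.any():
            continue
        # run-length encode the missing mask
        boundaries = np.flatnonzero(np.diff(isna.astype(int)))
        starts = [0] + (boundaries + 1).tolist()
        for s, e in zip(starts, starts[1:] + [len(col)]):
            if not isna[s]:
                continue
            length = e - s
            interior = s > 0 and e < len(col)
            if interior and length <= max_gap:
                lo, hi = col[s - 1], col[e]
                frac = np.arange(1, length + 1) / (length + 1)
                col[s:e] = lo + frac * (hi - lo)
            else:
                report.append(
                    {"taxon": taxon, "start": series.index[s], "length": length}
                )
        filled[taxon] = col
    return filled, report


def build_design_matrices(
    series: CommunityTimeSeries, *, max_gap: int = 1
) -> DesignMatrices:
    """Run the full preprocessing chain on a community panel.

    Abundance series are log(x+1) transformed; environmental series
    (category ``"environmental"``, e.g. temperature) stay on their
    native scale but are still de-seasoned — their annual cycle would
    otherwise dominate the covariate signal — and z-scored.
    """
    variates = series.taxa_with_role("variate")
    covariates = series.taxa_with_role("covariate")
    kept = variates + covariates
    if not variates:
        raise ValueError("no variate series present")

    logged = series.data[kept].copy()
    for taxon in kept:
        if series.categories.get(taxon) != "environmental":
            logged[taxon] = log1p_transform(logged[taxon])
    logged, _gap_report = interpolate_gaps(logged, max_gap=max_gap)
    clim = monthly_climatology(logged)
    anomalies = deseason(logged, clim)
    z, scale = standardize(anomalies)
    return DesignMatrices(X=z[variates], U=z[covariates], scale=scale)
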