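"""Raw records to a clean, complete weekly panel.

Stages, in the order they run: read the long-format monitoring tables;
resample each series to weekly bins by the mean; optionally mask outliers
(median +/- k*MAD); drop series below a minimum weekly coverage (default 240
observed weeks out of a 312-week span); and fill the remaining gaps with an
imputation method selected automatically per series.

Method selection works by self-validation: several copies of each series are
made, additional values are hidden artificially in each copy, every candidate
method (with its hyperparameters searched by grid / random / Bayesian
strategies) imputes the copies, and the candidate with the lowest mean RMSE
against the hidden truth wins. Imputed values are treated as data downstream;
the report keeps the imputed fraction per series so users can audit.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import SeriesId, SeriesPanel, WeeklySeries, weekly_index
from .synth import (AreaMeta, ENV_COLUMNS, ENV_UNITS, ENV_VARIABLES,
                    META_COLUMNS, PHYTO_COLUMNS, TOXIN_COLUMNS)

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "ImputationTrial",
    "ImputationReport",
    "PrepConfig",
    "read_records",
    "read_area_metadata",
    "records_to_raw_series",
    "resample_weekly",
    "remove_outliers",
    "coverage_filter",
    "make_missing_copies",
    "rmse",
    "impute",
    "tune_imputer",
    "prepare_panel",
    "IMPUTER_REGISTRY",
]


class SchemaError(ValueError):
    """Input table does not match the expected schema."""


_SCHEMAS: dict[str, tuple[list[str], list[str]]] = {
    # schema -> (required columns, numeric measurement columns)
    "toxins": (TOXIN_COLUMNS, ["DSP Toxins"]),
    "phyto": (PHYTO_COLUMNS, ["DSP Toxins Producers"]),
    "environment": (ENV_COLUMNS, ENV_VARIABLES),
    "metadata": (META_COLUMNS, []),
}


def read_records(path: str | Path, schema: str) -> pd.DataFrame:
    """Read one monitoring CSV, validating and typing its columns.

    Unknown extra columns are ignored with a warning; a missing required
    column raises :class:`SchemaError` naming it. Non-numeric measurement
    cells become NaN; the ``Date`` column is parsed to datetimes.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(_SCHEMAS)}")
    required, numeric = _SCHEMAS[schema]
    table = pd.read_csv(path)
    for col in required:
        if col not in table.columns:
            raise SchemaError(f"{path}: missing required column {col!r} for schema {schema!r}")
    extra = [c for c in table.columns if c not in required]
    if extra:
        logger.warning("%s: ignoring unknown columns %s", path, extra)
        table = table.drop(columns=extra)
    if "Date" in required:
        table["Date"] = pd.to_datetime(table["Date"], format="ISO8601")
    for col in numeric:
        table[col] = pd.to_numeric(table[col], errors="coerce")
    return table


def read_area_metadata(path: str | Path) -> list[AreaMeta]:
    """Area-metadata CSV to :class:`AreaMeta` records (neighbors ';'-joined)."""
    table = read_records(path, "metadata")
    out = []
    for row in table.itertuples(index=False):
        neigh = tuple(str(row.neighbors).split(";")) if isinstance(row.neighbors, str) and row.neighbors else ()
        out.append(AreaMeta(str(row.area_id), str(row.coast), int(row.ns_rank), str(row.region), neigh))
    return out


def records_to_raw_series(table: pd.DataFrame, schema: str) -> dict[SeriesId, pd.DataFrame]:
    """Split a long-format table into per-series (Date, value) frames."""
    out: dict[SeriesId, pd.DataFrame] = {}
    if schema == "toxins":
        for (area, species), grp in table.groupby(["Production Area", "Species"], sort=True):
            sid = SeriesId(str(area), "toxicity", str(species))
            out[sid] = grp.rename(columns={"DSP Toxins": "value"})[["Date", "value"]]
    elif schema == "phyto":
        for area, grp in table.groupby("Production Area", sort=True):
            sid = SeriesId(str(area), "phyto")
            out[sid] = grp.rename(columns={"DSP Toxins Producers": "value"})[["Date", "value"]]
    elif schema == "environment":
        for area, grp in table.groupby("Production Area", sort=True):
            for var in ENV_VARIABLES:
                sid = SeriesId(str(area), var)
                out[sid] = grp.rename(columns={var: "value"})[["Date", "value"]]
    else:
        raise ValueError(f"schema {schema!r} does not hold time series")
    return out


# ---------------------------------------------------------------------------
# Resampling, outliers, coverage
# ---------------------------------------------------------------------------

def resample_weekly(records: pd.DataFrame, series_id: SeriesId,
                    start_date: str | pd.Timestamp, end_date: str | pd.Timestamp,
                    units: str = "") -> WeeklySeries:
    """Mean-aggregate one series' observations into anchored 7-day bins.

    The bin of an observation is ``(date - start_date) // 7 days``; weeks
    with no observation are NaN; observations outside the span are dropped
    (and counted in the log).
    """
    index = weekly_index(start_date, end_date)
    start = index[0]
    dates = pd.DatetimeIndex(records["Date"])
    values = pd.to_numeric(records["value"], errors="coerce").to_numpy(dtype=float)
    bins = ((dates - start).days // 7).to_numpy()
    in_span = (bins >= 0) & (bins < len(index))
    dropped = int((~in_span).sum())
    if dropped:
        logger.info("%s: dropped %d observations outside the span", series_id, dropped)
    sums = np.bincount(bins[in_span], weights=np.nan_to_num(values[in_span]), minlength=len(index))
    counts = np.bincount(bins[in_span], weights=(~np.isnan(values[in_span])).astype(float),
                         minlength=len(index))
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return WeeklySeries(series_id, index, means, units=units)


def remove_outliers(series: WeeklySeries, rule: str | tuple[str, float] = "none") -> WeeklySeries:
    """Mask outlying weekly values per the configured rule.

    ``"none"`` is the identity. ``("mad", k)`` masks values with
    ``|x - median| > k * MAD`` (strict, so a constant series is untouched and
    a lone extreme among identical values is caught even when MAD is zero).
    """
    if rule == "none":
        return series
    if not (isinstance(rule, tuple) and len(rule) == 2 and rule[0] == "mad"):
        raise ValueError(f"unknown outlier rule {rule!r}")
    k = float(rule[1])
    if k <= 0:
        raise ValueError(f"mad rule requires k > 0, got {k}")
    obs = series.observed_mask
    if obs.sum() == 0:
        return series
    med = np.nanmedian(series.values)
    dev = np.abs(series.values - med)
    mad = np.nanmedian(dev)
    flag = obs & (dev > k * mad)
    if flag.any():
        logger.info("%s: masked %d outliers (median %.4g, MAD %.4g, k=%g)",
                    series.series_id, int(flag.sum()), med, mad, k)
    vals = series.values.copy()
    vals[flag] = np.nan
    return series.with_values(vals)


def coverage_filter(panel: SeriesPanel, min_weeks: int = 240,
                    total_weeks: int | None = None) -> SeriesPanel:
    """Keep only series with at least ``min_weeks`` observed weekly values."""
    total = total_weeks if total_weeks is not None else len(panel.index)
    if min_weeks > total:
        raise ValueError(f"min_weeks {min_weeks} exceeds total_weeks {total}")
    out = SeriesPanel(panel.index)
    for s in panel:
        if s.n_observed >= min_weeks:
            out.add(s)
        else:
            logger.info("%s: dropped (coverage %d < %d)", s.series_id, s.n_observed, min_weeks)
    return out


# ---------------------------------------------------------------------------
# Imputation: RMSE-on-masked-copies model selection
# ---------------------------------------------------------------------------

@dataclass
class ImputationTrial:
    """One artificially-masked copy of a series."""

    copy_id: int
    mask: np.ndarray  # True at positions hidden in this copy
    imputed: np.ndarray | None = None  # imputed values at masked positions
    rmse: float | None = None


@dataclass
class ImputationReport:
    """Outcome of imputer selection for one series."""

    series_id: SeriesId
    candidates: list[dict] = field(default_factory=list)  # method, params, mean_rmse
    selected_method: str | None = None
    selected_params: dict = field(default_factory=dict)
    selected_rmse: float | None = None
    evaluations: int = 0
    imputed_fraction: float = 0.0

    def to_dict(self) -> dict:
        return {
            "series_id": str(self.series_id),
            "candidates": self.candidates,
            "selected_method": self.selected_method,
            "selected_params": self.selected_params,
            "selected_rmse": self.selected_rmse,
            "evaluations": self.evaluations,
            "imputed_fraction": self.imputed_fraction,
        }


def rmse(truth: Sequence[float], estimate: Sequence[float]) -> float:
    """Root mean squared error ``sqrt(sum((x_i - xhat_i)^2) / N)``."""
    x = np.asarray(truth, dtype=float)
    xhat = np.asarray(estimate, dtype=float)
    if x.shape != xhat.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {xhat.shape}")
    if x.size == 0:
        raise ValueError("rmse of empty vectors is undefined")
    if np.isnan(x).any() or np.isnan(xhat).any():
        raise ValueError("rmse inputs must not contain missing values")
    return float(np.sqrt(np.mean((x - xhat) ** 2)))


def make_missing_copies(series: WeeklySeries, n_copies: int = 5, hide_frac: float = 0.1,
                        seed: int = 0) -> list[ImputationTrial]:
    """Copies of a series with disjoint random subsets of observed values hidden.

    Hidden positions are drawn without replacement across all copies, so no
    position is hidden twice and originally-missing positions are never
    hidden. Reproducible from ``seed``.
    """
    if not (0.0 < hide_frac < 1.0):
        raise ValueError(f"hide_frac must be in (0, 1), got {hide_frac}")
    observed = np.flatnonzero(series.observed_mask)
    if observed.size < 10:
        raise ValueError(
            f"{series.series_id}: only {observed.size} observed values; need >= 10 to validate imputers")
    n_hide = max(1, int(round(hide_frac * observed.size)))
    if n_copies * n_hide > observed.size:
        raise ValueError(
            f"{series.series_id}: cannot hide {n_copies} disjoint subsets of {n_hide} "
            f"from {observed.size} observed values")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(observed, size=n_copies * n_hide, replace=False)
    trials = []
    for c in range(n_copies):
        mask = np.zeros(len(series), dtype=bool)
        mask[chosen[c * n_hide:(c + 1) * n_hide]] = True
        trials.append(ImputationTrial(copy_id=c, mask=mask))
    return trials


# -- candidate imputers ------------------------------------------------------

def _edge_fill(filled: pd.Series, series_id: SeriesId) -> pd.Series:
    """Nearest-observed extension for leading/trailing gaps a method left."""
    if filled.isna().any():
        logger.info("%s: filled %d edge gaps by nearest-observed extension",
                    series_id, int(filled.isna().sum()))
        filled = filled.ffill().bfill()
    return filled


def _fill_mean(s: pd.Series) -> pd.Series:
    return s.fillna(s.mean())


def _fill_median(s: pd.Series) -> pd.Series:
    return s.fillna(s.median())


def _fill_linear(s: pd.Series) -> pd.Series:
    return s.interpolate(method="linear", limit_direction="both", limit_area=None)


def _fill_spline(s: pd.Series, order: int = 3) -> pd.Series:
    from scipy.interpolate import make_interp_spline

    if s.notna().sum() <= order:
        return _fill_linear(s)
    x = np.arange(len(s), dtype=float)
    obs = s.notna().to_numpy()
    spl = make_interp_spline(x[obs], s.to_numpy()[obs], k=order)
    vals = s.to_numpy().copy()
    # interior gaps only; extrapolated edges are handled by _edge_fill
    inner = ~obs & (x >= x[obs][0]) & (x <= x[obs][-1])
    vals[inner] = spl(x[inner])
    return pd.Series(vals, index=s.index)


def _fill_moving_average(s: pd.Series, window: int = 5) -> pd.Series:
    smooth = s.rolling(window, center=True, min_periods=1).mean()
    return s.fillna(smooth)


def _fill_seasonal_naive(s: pd.Series, period: int = 52) -> pd.Series:
    vals = s.to_numpy().copy()
    n = len(vals)
    pos = np.arange(n)
    for i in np.flatnonzero(np.isnan(vals)):
        same_phase = pos[(pos % period == i % period) & ~np.isnan(s.to_numpy())]
        if same_phase.size:
            vals[i] = float(np.mean(s.to_numpy()[same_phase]))
    return pd.Series(vals, index=s.index)


# method -> (fill function, hyperparameter grid); registry order is the
# final tie-break in selection.
IMPUTER_REGISTRY: dict[str, tuple[Callable, dict[str, list]]] = {
    "mean_fill": (_fill_mean, {}),
    "median_fill": (_fill_median, {}),
    "linear_interp": (_fill_linear, {}),
    "spline_interp": (_fill_spline, {"order": [2, 3]}),
    "moving_average": (_fill_moving_average, {"window": [3, 5, 7, 9, 11, 13]}),
    "seasonal_naive": (_fill_seasonal_naive, {"period": [13, 26, 52]}),
}


def impute(series: WeeklySeries, method: str, params: Mapping | None = None) -> WeeklySeries:
    """Fill every missing value with the named method; observed values untouched."""
    if method not in IMPUTER_REGISTRY:
        raise ValueError(f"unknown imputation method {method!r}; known: {sorted(IMPUTER_REGISTRY)}")
    if series.n_observed == 0:
        raise ValueError(f"{series.series_id}: cannot impute an all-missing series")
    if series.is_complete():
        return series
    fn, _grid = IMPUTER_REGISTRY[method]
    s = pd.Series(series.values.copy(), index=series.index)
    filled = fn(s, **dict(params or {}))
    filled = _edge_fill(filled, series.series_id)
    vals = filled.to_numpy(dtype=float)
    vals[series.observed_mask] = series.values[series.observed_mask]
    return series.with_values(vals)


# -- hyperparameter search ---------------------------------------------------

def _grid_points(grid: Mapping[str, list]) -> list[dict]:
    if not grid:
        return [{}]
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def _mean_trial_rmse(series: WeeklySeries, trials: list[ImputationTrial],
                     method: str, params: dict) -> float:
    scores = []
    for trial in trials:
        vals = series.values.copy()
        vals[trial.mask] = np.nan
        hidden = series.with_values(vals)
        filled = impute(hidden, method, params)
        scores.append(rmse(series.values[trial.mask], filled.values[trial.mask]))
    return float(np.mean(scores))


def _bayesian_order(points: list[dict], evaluate: Callable[[dict], float],
                    budget: int, rng: np.random.Generator) -> list[tuple[dict, float]]:
    """Sequential model-based search over a discrete grid.

    Seeds with a few random points, then repeatedly fits a Gaussian process
    to (encoded point, score) and evaluates the unevaluated point with the
    best expected improvement. On a one-dimensional small grid this behaves
    like a guided grid search but stays within the evaluation budget.
    """
    import warnings

    from scipy.stats import norm
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern

    encoded = np.array([[float(v) for v in p.values()] for p in points])
    span = encoded.max(axis=0) - encoded.min(axis=0)
    span[span == 0] = 1.0
    encoded = (encoded - encoded.min(axis=0)) / span
    n_init = min(3, budget, len(points))
    order = rng.permutation(len(points))
    tried: list[int] = list(order[:n_init])
    results: list[tuple[dict, float]] = [(points[i], evaluate(points[i])) for i in tried]
    while len(results) < min(budget, len(points)):
        y = np.array([r[1] for r in results])
        gp = GaussianProcessRegressor(kernel=Matern(nu=2.5), normalize_y=True,
                                      random_state=0, alpha=1e-8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(encoded[tried], y)
        remaining = [i for i in range(len(points)) if i not in tried]
        mu, sd = gp.predict(encoded[remaining], return_std=True)
        best = y.min()
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, (best - mu) / sd, 0.0)
            ei = np.where(sd > 0, (best - mu) * norm.cdf(z) + sd * norm.pdf(z), 0.0)
        pick = remaining[int(np.argmax(ei))]
        tried.append(pick)
        results.append((points[pick], evaluate(points[pick])))
    return results


def tune_imputer(series: WeeklySeries, candidates: Sequence[str] | None = None,
                 n_copies: int = 5, hide_frac: float = 0.1, budget: int = 25,
                 seed: int = 0, strategy: str = "bayesian") -> ImputationReport:
    """Select the imputation method (and hyperparameters) minimising mean RMSE.

    ``budget`` caps hyperparameter evaluations per method; ``strategy`` is
    ``bayesian`` (sequential model-based), ``random`` or ``grid``
    (exhaustive). Ties are broken toward the simpler method (fewer
    hyperparameters), then registry order. Deterministic given ``seed``.
    """
    if candidates is None:
        candidates = list(IMPUTER_REGISTRY)
    if not candidates:
        raise ValueError("candidate list is empty")
    unknown = [m for m in candidates if m not in IMPUTER_REGISTRY]
    if unknown:
        raise ValueError(f"unknown candidate methods {unknown}")
    if budget < 1:
        raise ValueError("budget must allow at least one evaluation per method")
    if strategy not in ("bayesian", "random", "grid"):
        raise ValueError(f"unknown search strategy {strategy!r}")

    trials = make_missing_copies(series, n_copies=n_copies, hide_frac=hide_frac, seed=seed)
    report = ImputationReport(series_id=series.series_id,
                              imputed_fraction=1.0 - series.n_observed / len(series))
    registry_order = list(IMPUTER_REGISTRY)
    for method in candidates:
        _fn, grid = IMPUTER_REGISTRY[method]
        points = _grid_points(grid)
        evaluate = lambda p, m=method: _mean_trial_rmse(series, trials, m, p)
        rng = np.random.default_rng([seed, registry_order.index(method)])
        if strategy == "grid" or len(points) <= min(budget, 3):
            evaluated = [(p, evaluate(p)) for p in points[:budget]]
        elif strategy == "random":
            idx = rng.choice(len(points), size=min(budget, len(points)), replace=False)
            evaluated = [(points[i], evaluate(points[i])) for i in idx]
        else:
            evaluated = _bayesian_order(points, evaluate, budget, rng)
        best_params, best_score = min(evaluated, key=lambda pr: pr[1])
        report.candidates.append({"method": method, "params": best_params,
                                  "mean_rmse": best_score})
        report.evaluations += len(evaluated)

    def rank(entry: dict) -> tuple:
        return (entry["mean_rmse"], len(entry["params"]), registry_order.index(entry["method"]))

    winner = min(report.candidates, key=rank)
    report.selected_method = winner["method"]
    report.selected_params = winner["params"]
    report.selected_rmse = winner["mean_rmse"]
    return report


# ---------------------------------------------------------------------------
# Whole-chain driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrepConfig:
    """Settings for the raw-records-to-complete-panel chain."""

    start_date: str = "2015-01-05"
    end_date: str = "2020-12-29"
    min_weeks: int = 240
    outlier_rule: str | tuple[str, float] = "none"
    n_copies: int = 5
    hide_frac: float = 0.1
    budget: int = 25
    strategy: str = "bayesian"
    candidates: tuple[str, ...] | None = None
    seed: int = 0


def prepare_panel(paths: Mapping[str, str | Path],
                  config: PrepConfig = PrepConfig()) -> tuple[SeriesPanel, list[ImputationReport]]:
    """Read, resample, clean, filter and impute every series in the inputs.

    ``paths`` maps any of ``toxins``, ``phyto``, ``environment`` to CSV
    files. Returns the complete panel and one report per imputed series.
    """
    index = weekly_index(config.start_date, config.end_date)
    raw = SeriesPanel(index)
    units_by_schema = {"toxins": "ug OA eq./kg", "phyto": "cells/L"}
    for schema in ("toxins", "phyto", "environment"):
        if schema not in paths:
            continue
        table = read_records(paths[schema], schema)
        for sid, records in records_to_raw_series(table, schema).items():
            unit = units_by_schema.get(schema) or ENV_UNITS.get(sid.variable, "")
            series = resample_weekly(records, sid, config.start_date, config.end_date, units=unit)
            series = remove_outliers(series, config.outlier_rule)
            raw.add(series)
    kept = coverage_filter(raw, min_weeks=config.min_weeks)
    panel = SeriesPanel(index)
    reports: list[ImputationReport] = []
    for pos, s in enumerate(kept):
        if s.is_complete():
            panel.add(s)
            continue
        report = tune_imputer(s, candidates=list(config.candidates) if config.candidates else None,
                              n_copies=config.n_copies, hide_frac=config.hide_frac,
                              budget=config.budget,
                              seed=np.random.SeedSequence([config.seed, pos]).generate_state(1)[0] % (2**31),
                              strategy=config.strategy)
        panel.add(impute(s, report.selected_method, report.selected_params))
        reports.append(report)
    return panel, reports
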