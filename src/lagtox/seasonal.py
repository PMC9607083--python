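"""Seasonality and trend profiles of weekly series.

Seasonality here means the monthly climatology (mean of all weekly values
falling in each calendar month, pooled across years) and trend the yearly
means — deliberately simple summaries rather than a formal decomposition,
because the goal is to read off when toxicity peaks and how levels drift,
not to separate interacting components.

A week is assigned to the month/year of its bin-start date; weeks straddling
a boundary are not split. Confidence intervals are the normal approximation
``mean +/- z * sd / sqrt(n)`` (95% by default); a single observation yields
an undefined (NaN) half-width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import SeriesId, SeriesPanel, WeeklySeries
from .synth import AreaMeta

__all__ = [
    "SeasonalProfile",
    "TrendProfile",
    "monthly_profile",
    "yearly_profile",
    "monthly_by_year",
    "regional_profile",
    "profiles_to_frame",
]


@dataclass
class SeasonalProfile:
    """Monthly climatology: 12 means, CI half-widths and sample counts."""

    label: str
    means: np.ndarray  # length 12, month 1..12; NaN where no data
    ci_half: np.ndarray  # length 12
    counts: np.ndarray  # length 12, ints

    def top_months(self, k: int = 2) -> list[int]:
        """The k calendar months (1..12) with the largest means."""
        order = np.argsort(np.nan_to_num(self.means, nan=-np.inf))[::-1]
        return [int(m) + 1 for m in order[:k]]


@dataclass
class TrendProfile:
    """Per-calendar-year means with CI half-widths and counts."""

    label: str
    years: np.ndarray
    means: np.ndarray
    ci_half: np.ndarray
    counts: np.ndarray


def _group_stats(values: np.ndarray, groups: np.ndarray, levels: np.ndarray,
                 ci_level: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    means = np.full(len(levels), np.nan)
    half = np.full(len(levels), np.nan)
    counts = np.zeros(len(levels), dtype=int)
    for i, lev in enumerate(levels):
        vals = values[(groups == lev) & ~np.isnan(values)]
        counts[i] = vals.size
        if vals.size:
            means[i] = vals.mean()
        if vals.size > 1:
            half[i] = z * vals.std(ddof=1) / np.sqrt(vals.size)
        elif vals.size == 1:
            half[i] = np.nan
    return means, half, counts


def _check_nonempty(series: WeeklySeries) -> None:
    if series.n_observed == 0:
        raise ValueError(f"{series.series_id}: cannot profile an empty series")


def monthly_profile(series: WeeklySeries, ci_level: float = 0.95) -> SeasonalProfile:
    """Mean per calendar month, pooled across years."""
    _check_nonempty(series)
    months = series.index.month.to_numpy()
    means, half, counts = _group_stats(series.values, months, np.arange(1, 13), ci_level)
    return SeasonalProfile(str(series.series_id), means, half, counts)


def yearly_profile(series: WeeklySeries, ci_level: float = 0.95) -> TrendProfile:
    """Mean per calendar year."""
    _check_nonempty(series)
    years = series.index.year.to_numpy()
    levels = np.unique(years)
    means, half, counts = _group_stats(series.values, years, levels, ci_level)
    return TrendProfile(str(series.series_id), levels, means, half, counts)


def monthly_by_year(series: WeeklySeries) -> pd.DataFrame:
    """Month (rows 1..12) x year mean matrix; NaN where no data."""
    _check_nonempty(series)
    frame = pd.DataFrame({
        "value": series.values,
        "month": series.index.month,
        "year": series.index.year,
    })
    years = np.unique(frame["year"].to_numpy())
    table = frame.pivot_table(index="month", columns="year", values="value", aggfunc="mean")
    return table.reindex(index=np.arange(1, 13), columns=years)


def _pool_region_values(panel: SeriesPanel, metadata: list[AreaMeta],
                        ) -> dict[str, tuple[pd.DatetimeIndex, np.ndarray]]:
    """Concatenate weekly values of each region's member series (pooled weeks)."""
    by_area = {a.area_id: a.region for a in metadata}
    pooled: dict[str, list[WeeklySeries]] = {}
    for s in panel:
        if s.series_id.area not in by_area:
            raise ValueError(f"area {s.series_id.area!r} missing from metadata")
        pooled.setdefault(by_area[s.series_id.area], []).append(s)
    out = {}
    for region, members in pooled.items():
        idx = members[0].index
        dates = np.concatenate([m.index.to_numpy() for m in members])
        vals = np.concatenate([m.values for m in members])
        out[region] = (pd.DatetimeIndex(dates), vals)
        del idx
    return out


def regional_profile(panel: SeriesPanel, metadata: list[AreaMeta], kind: str = "seasonal",
                     ci_level: float = 0.95, mode: str = "pooled"):
    """Profiles per geographic region.

    ``mode='pooled'`` (default) pools the weekly values of all member series
    before averaging, so sample counts drive the CI; ``mode='mean_of_series'``
    averages the member series' own profiles instead.
    """
    if kind not in ("seasonal", "trend"):
        raise ValueError(f"kind must be 'seasonal' or 'trend', got {kind!r}")
    if mode not in ("pooled", "mean_of_series"):
        raise ValueError(f"unknown mode {mode!r}")

    if mode == "mean_of_series":
        by_area = {a.area_id: a.region for a in metadata}
        out: dict[str, SeasonalProfile | TrendProfile] = {}
        groups: dict[str, list[WeeklySeries]] = {}
        for s in panel:
            if s.series_id.area not in by_area:
                raise ValueError(f"area {s.series_id.area!r} missing from metadata")
            groups.setdefault(by_area[s.series_id.area], []).append(s)
        for region, members in sorted(groups.items()):
            if kind == "seasonal":
                profs = [monthly_profile(m, ci_level) for m in members]
                means = np.nanmean(np.stack([p.means for p in profs]), axis=0)
                half = np.nanmean(np.stack([p.ci_half for p in profs]), axis=0)
                counts = np.sum(np.stack([p.counts for p in profs]), axis=0)
                out[region] = SeasonalProfile(region, means, half, counts)
            else:
                profs = [yearly_profile(m, ci_level) for m in members]
                years = profs[0].years
                means = np.nanmean(np.stack([p.means for p in profs]), axis=0)
                half = np.nanmean(np.stack([p.ci_half for p in profs]), axis=0)
                counts = np.sum(np.stack([p.counts for p in profs]), axis=0)
                out[region] = TrendProfile(region, years, means, half, counts)
        return out

    pooled = _pool_region_values(panel, metadata)
    out = {}
    for region, (dates, vals) in sorted(pooled.items()):
        if kind == "seasonal":
            means, half, counts = _group_stats(vals, dates.month.to_numpy(),
                                               np.arange(1, 13), ci_level)
            out[region] = SeasonalProfile(region, means, half, counts)
        else:
            years = dates.year.to_numpy()
            levels = np.unique(years)
            means, half, counts = _group_stats(vals, years, levels, ci_level)
            out[region] = TrendProfile(region, levels, means, half, counts)
    return out


def profiles_to_frame(profiles) -> pd.DataFrame:
    """Tidy (entity, period, mean, ci_low, ci_high, n) table for export."""
    rows = []
    items = profiles.items() if isinstance(profiles, dict) else [(p.label, p) for p in profiles]
    for label, p in items:
        if isinstance(p, SeasonalProfile):
            periods = np.arange(1, 13)
        else:
            periods = p.years
        for per, mean, half, n in zip(periods, p.means, p.ci_half, p.counts):
            rows.append({"entity": p.label, "period": int(per), "mean": mean,
                         "ci_low": mean - half, "ci_high": mean + half, "n": int(n)})
    return pd.DataFrame(rows, columns=["entity", "period", "mean", "ci_low", "ci_high", "n"])
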