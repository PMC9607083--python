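"""Core containers: weekly time series and aligned panels.

Every stage of the pipeline works on :class:`WeeklySeries` objects — one
variable measured in one production area (optionally for one shellfish
species) on a regular 7-day grid — collected into a :class:`SeriesPanel`
that shares a single weekly index. Missing values are encoded as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = ["SeriesId", "WeeklySeries", "SeriesPanel", "weekly_index"]


@dataclass(frozen=True)
class SeriesId:
    """Identifies one series: production area, variable, optional species."""

    area: str
    variable: str
    species: str | None = None

    def __str__(self) -> str:
        parts = [self.area, self.variable]
        if self.species is not None:
            parts.append(self.species)
        return "/".join(parts)


def weekly_index(start_date: str | pd.Timestamp, end_date: str | pd.Timestamp) -> pd.DatetimeIndex:
    """Regular 7-day grid from ``start_date`` to ``end_date`` inclusive.

    Bins are anchored at the start date, not at ISO calendar weeks, so the
    grid is uniform regardless of which weekday the span begins on.
    """
    start = pd.Timestamp(start_date)
    end = pd.Timestamp(end_date)
    if end < start:
        raise ValueError(f"end_date {end.date()} precedes start_date {start.date()}")
    return pd.date_range(start, end, freq="7D")


@dataclass
class WeeklySeries:
    """One variable's weekly values on a regular 7-day date grid.

    ``values`` has the same length as ``index``; NaN marks a missing week.
    """

    series_id: SeriesId
    index: pd.DatetimeIndex
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.index):
            raise ValueError(
                f"{self.series_id}: values length {len(self.values)} "
                f"!= index length {len(self.index)}"
            )
        if len(self.index) > 1:
            steps = np.diff(self.index.values).astype("timedelta64[D]")
            if not (steps == np.timedelta64(7, "D")).all():
                raise ValueError(f"{self.series_id}: index is not a strict 7-day grid")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def n_observed(self) -> int:
        return int(self.observed_mask.sum())

    def is_complete(self) -> bool:
        return bool(self.observed_mask.all())

    def with_values(self, values: np.ndarray) -> "WeeklySeries":
        return replace(self, values=np.asarray(values, dtype=float).copy())

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=self.index, name=str(self.series_id))


@dataclass
class SeriesPanel:
    """Aligned collection of :class:`WeeklySeries` sharing one weekly index."""

    index: pd.DatetimeIndex
    series: dict[SeriesId, WeeklySeries] = field(default_factory=dict)

    def add(self, s: WeeklySeries) -> None:
        if not s.index.equals(self.index):
            raise ValueError(f"{s.series_id}: index differs from the panel index")
        if s.series_id in self.series:
            raise ValueError(f"duplicate series id {s.series_id}")
        self.series[s.series_id] = s

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self) -> Iterator[WeeklySeries]:
        return iter(self.series.values())

    def __getitem__(self, key: SeriesId) -> WeeklySeries:
        return self.series[key]

    def __contains__(self, key: SeriesId) -> bool:
        return key in self.series

    def ids(self) -> list[SeriesId]:
        return list(self.series.keys())

    def subset(self, ids: Iterable[SeriesId]) -> "SeriesPanel":
        out = SeriesPanel(self.index)
        for sid in ids:
            out.add(self.series[sid])
        return out

    def to_frame(self) -> pd.DataFrame:
        """Wide date x series_id frame (columns as string ids, sorted)."""
        cols = {str(sid): s.values for sid, s in sorted(self.series.items(), key=lambda kv: str(kv[0]))}
        return pd.DataFrame(cols, index=self.index)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, units: Mapping[str, str] | None = None) -> "SeriesPanel":
        """Inverse of :meth:`to_frame`; column names are ``area/variable[/species]``."""
        index = pd.DatetimeIndex(frame.index)
        panel = cls(index)
        for col in frame.columns:
            parts = str(col).split("/")
            if len(parts) == 2:
                sid = SeriesId(parts[0], parts[1])
            elif len(parts) == 3:
                sid = SeriesId(parts[0], parts[1], parts[2])
            else:
                raise ValueError(f"cannot parse series id from column {col!r}")
            unit = (units or {}).get(str(col), "")
            panel.add(WeeklySeries(sid, index, frame[col].to_numpy(dtype=float), units=unit))
        return panel
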