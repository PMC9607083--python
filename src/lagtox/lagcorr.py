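"""Time-lagged Pearson and multi-scale DCCA/DPCCA correlation analysis.

Two complementary views of the association between weekly series:

* **Lagged Pearson** — the classical product-moment correlation computed at
  every integer lag in ``[-L, +L]``. At positive lag ``k`` the first series'
  present is paired with the second series' value ``k`` weeks earlier, so a
  peak at ``k > 0`` means the second series leads (its past predicts the
  first series' present).

* **DCCA / DPCCA** — scale-dependent detrended (partial) cross-correlation.
  Each series is turned into a profile ``X_t = sum_{i<=t} (x_i - xbar)``;
  within every overlapping window of ``s`` weeks a straight line is fitted
  to the profile and the residual covariance/variances define the detrended
  fluctuation functions ``F2_DCCA`` and ``F2_DFA``. Their ratio

      rho(s) = F2_DCCA(s) / (F_DFA,x(s) * F_DFA,y(s))

  is a correlation in [-1, 1] at time scale ``s``. The partial (DPCCA)
  coefficient removes the linear influence of a conditioning set by
  inverting the matrix of DCCA coefficients ``rho(s)`` into ``C(s)`` and
  reading off

      rho_DPCCA(x, y; s) = -C_xy(s) / sqrt(C_xx(s) * C_yy(s)).

  With the conditioning set equal to the pair itself this reduces exactly
  to the DCCA coefficient.

The defining equations write the detrended variance with an unsquared
residual sum, which cannot be a variance; the standard DFA form (squared
residuals) is used here. The window aggregate sums the ``N - s + 1``
overlapping windows and divides by ``N - s``, exactly as the fluctuation
functions are conventionally printed; the constant cancels in every
coefficient ratio.

For lagged DPCCA, all series are truncated to the lag overlap and profiles
and means are recomputed on that overlap, so each lag is a self-contained
computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .panel import SeriesId, WeeklySeries

__all__ = [
    "LagCorrCurve",
    "Profile",
    "FluctuationSet",
    "DpccaResult",
    "DpccaCurve",
    "DEFAULT_SCALES",
    "COND_NUMBER_LIMIT",
    "shift_pair",
    "pearson",
    "lagged_pearson",
    "build_profile",
    "window_residuals",
    "detrended_moments",
    "dcca_coefficient",
    "dcca_matrix",
    "dpcca",
    "lagged_dpcca",
]

DEFAULT_SCALES: tuple[int, ...] = (4, 12, 26, 52)
COND_NUMBER_LIMIT = 1e10


# ---------------------------------------------------------------------------
# Lagged Pearson
# ---------------------------------------------------------------------------

def _values(x) -> np.ndarray:
    return x.values if isinstance(x, WeeklySeries) else np.asarray(x, dtype=float)


def shift_pair(x, y, lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Align two equal-length series at an integer lag (weeks).

    Positive ``lag`` pairs ``x_t`` with ``y_{t-lag}`` (y's past against x's
    present); negative ``lag`` pairs ``x_t`` with ``y_{t+|lag|}``. The
    overlap is truncated — no wrap-around — and has length ``N - |lag|``.
    """
    xv, yv = _values(x), _values(y)
    if len(xv) != len(yv):
        raise ValueError(f"series lengths differ: {len(xv)} vs {len(yv)}")
    n = len(xv)
    if abs(lag) >= n:
        raise ValueError(f"|lag| = {abs(lag)} leaves no overlap for series of length {n}")
    if lag >= 0:
        return xv[lag:], yv[: n - lag]
    return xv[: n + lag], yv[-lag:]


def pearson(xs, ys) -> tuple[float, float, int]:
    """Pearson r with two-sided p-value (t transform, n-2 df) and n.

    A constant input yields the undefined marker (NaN, NaN, n) rather than
    a number, since the correlation does not exist there.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape:
        raise ValueError("length mismatch")
    n = len(xs)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if np.ptp(xs) == 0.0 or np.ptp(ys) == 0.0:
        return (np.nan, np.nan, n)
    res = stats.pearsonr(xs, ys)
    return (float(res.statistic), float(res.pvalue), n)


@dataclass
class LagCorrCurve:
    """Correlation value, p-value and sample count per integer lag."""

    pair: tuple[SeriesId | str, SeriesId | str]
    lags: np.ndarray
    r: np.ndarray
    p: np.ndarray
    n: np.ndarray

    def at(self, lag: int) -> float:
        return float(self.r[int(np.flatnonzero(self.lags == lag)[0])])


def lagged_pearson(x, y, max_lag: int = 10,
                   pair: tuple | None = None) -> LagCorrCurve:
    """Pearson correlation at every lag in ``[-max_lag, +max_lag]``.

    Returns exactly ``2 * max_lag + 1`` entries; the default window of 10
    weeks gives 21 correlation values per pair.
    """
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    if pair is None:
        pair = (
            x.series_id if isinstance(x, WeeklySeries) else "x",
            y.series_id if isinstance(y, WeeklySeries) else "y",
        )
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.empty(len(lags))
    p = np.empty(len(lags))
    n = np.empty(len(lags), dtype=int)
    for i, lag in enumerate(lags):
        xs, ys = shift_pair(x, y, int(lag))
        r[i], p[i], n[i] = pearson(xs, ys)
    return LagCorrCurve(pair, lags, r, p, n)


# ---------------------------------------------------------------------------
# Profiles and windowed detrending
# ---------------------------------------------------------------------------

@dataclass
class Profile:
    """Cumulative sum of deviations from the series mean."""

    source: SeriesId | str
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


def build_profile(x) -> Profile:
    """``X_t = sum_{i=1..t} (x_i - xbar)``; the final value telescopes to ~0."""
    xv = _values(x)
    if np.isnan(xv).any():
        raise ValueError("profile requires a complete series; impute first")
    source = x.series_id if isinstance(x, WeeklySeries) else "x"
    return Profile(source, np.cumsum(xv - xv.mean()))


def _residual_projector(s: int) -> np.ndarray:
    """Symmetric idempotent M with ``W @ M`` = OLS line residuals per window."""
    k = np.arange(s, dtype=float)
    a = np.column_stack([np.ones(s), k])
    return np.eye(s) - a @ np.linalg.inv(a.T @ a) @ a.T


def window_residuals(profile: Profile, s: int, j: int) -> np.ndarray:
    """Residuals of the OLS line fitted to profile positions j..j+s-1 (1-based j)."""
    n = len(profile)
    if s < 3:
        raise ValueError("scale s must be >= 3")
    if s > n:
        raise ValueError(f"scale s = {s} exceeds profile length {n}")
    if not (1 <= j <= n - s + 1):
        raise ValueError(f"window start j = {j} outside 1..{n - s + 1}")
    window = profile.values[j - 1: j - 1 + s]
    return window @ _residual_projector(s)


def _window_residual_matrix(profile_values: np.ndarray, s: int) -> np.ndarray:
    """(N - s + 1, s) matrix of per-window line residuals, step-1 windows."""
    windows = sliding_window_view(profile_values, s)
    return windows @ _residual_projector(s)


@dataclass
class FluctuationSet:
    """Per-window and aggregate detrended moments of a pair at one scale."""

    scale: int
    f2_dcca: np.ndarray  # per window j
    f2_dfa_x: np.ndarray
    f2_dfa_y: np.ndarray
    F2_dcca: float
    F2_dfa_x: float
    F2_dfa_y: float

    @property
    def n_windows(self) -> int:
        return len(self.f2_dcca)


def detrended_moments(x, y, s: int) -> FluctuationSet:
    """Windowed detrended covariance and variances of a pair at scale ``s``.

    Per window ``j`` (overlapping, step 1): ``f2 = sum_k res_x * res_y /
    (s - 1)``; aggregates divide the window sum by ``N - s``.
    """
    xv, yv = _values(x), _values(y)
    if len(xv) != len(yv):
        raise ValueError("series lengths differ")
    n = len(xv)
    if not (3 <= s < n):
        raise ValueError(f"scale s = {s} out of range [3, {n - 1}] for length {n}")
    px = build_profile(xv).values
    py = build_profile(yv).values
    rx = _window_residual_matrix(px, s)
    ry = _window_residual_matrix(py, s)
    f2_dcca = np.einsum("jk,jk->j", rx, ry) / (s - 1)
    f2_dfa_x = np.einsum("jk,jk->j", rx, rx) / (s - 1)
    f2_dfa_y = np.einsum("jk,jk->j", ry, ry) / (s - 1)
    denom = n - s
    return FluctuationSet(
        scale=s,
        f2_dcca=f2_dcca,
        f2_dfa_x=f2_dfa_x,
        f2_dfa_y=f2_dfa_y,
        F2_dcca=float(f2_dcca.sum() / denom),
        F2_dfa_x=float(f2_dfa_x.sum() / denom),
        F2_dfa_y=float(f2_dfa_y.sum() / denom),
    )


def dcca_coefficient(x, y, s: int) -> float:
    """Scale-s DCCA coefficient; NaN (undefined) when a profile has no fluctuation."""
    m = detrended_moments(x, y, s)
    if m.F2_dfa_x <= 0.0 or m.F2_dfa_y <= 0.0:
        return np.nan
    return m.F2_dcca / np.sqrt(m.F2_dfa_x * m.F2_dfa_y)


# ---------------------------------------------------------------------------
# DCCA matrix and the partial (DPCCA) coefficient
# ---------------------------------------------------------------------------

def dcca_matrix(series: list, s: int) -> np.ndarray:
    """Symmetric matrix of pairwise DCCA coefficients with unit diagonal."""
    if len(series) < 2:
        raise ValueError("need at least 2 series")
    vals = [_values(x) for x in series]
    n = len(vals[0])
    if any(len(v) != n for v in vals):
        raise ValueError("series lengths differ")
    if not (3 <= s < n):
        raise ValueError(f"scale s = {s} out of range [3, {n - 1}] for length {n}")
    proj = _residual_projector(s)
    resid = np.stack([sliding_window_view(build_profile(v).values, s) @ proj for v in vals])
    # F2[i, l] proportional to sum over windows and positions of res_i * res_l
    f2 = np.einsum("ajk,bjk->ab", resid, resid)
    diag = np.diag(f2).copy()
    bad = [str(getattr(series[i], "series_id", i)) for i in np.flatnonzero(diag <= 0.0)]
    if bad:
        raise ValueError(f"zero detrended fluctuation (constant profile) for: {bad}")
    rho = f2 / np.sqrt(np.outer(diag, diag))
    np.fill_diagonal(rho, 1.0)
    return rho


@dataclass
class DpccaResult:
    """DPCCA at one scale for a conditioning set: rho(s), C(s), pairwise values."""

    members: list
    scale: int
    rho: np.ndarray
    C: np.ndarray
    lag: int = 0
    value: float = np.nan  # partial coefficient of the target pair

    def partial(self, i: int = 0, j: int = 1) -> float:
        return float(-self.C[i, j] / np.sqrt(self.C[i, i] * self.C[j, j]))


def dpcca(series: list, s: int, target: tuple[int, int] = (0, 1)) -> DpccaResult:
    """Partial detrended cross-correlation of the target pair within a set.

    Inverts the DCCA coefficient matrix ``rho(s)`` into ``C(s)``; a
    condition number above ``COND_NUMBER_LIMIT`` raises, advising to drop
    collinear series.
    """
    rho = dcca_matrix(series, s)
    cond = np.linalg.cond(rho)
    if not np.isfinite(cond) or cond > COND_NUMBER_LIMIT:
        raise ValueError(
            f"DCCA matrix near-singular at scale {s} (condition number {cond:.3g}); "
            "drop collinear series from the conditioning set")
    c = np.linalg.inv(rho)
    members = [getattr(x, "series_id", i) for i, x in enumerate(series)]
    result = DpccaResult(members=members, scale=s, rho=rho, C=c)
    i, j = target
    result.value = result.partial(i, j)
    return result


@dataclass
class DpccaCurve:
    """DPCCA of one pair as a function of lag, at one scale."""

    pair: tuple
    conditioning: list
    scale: int
    lags: np.ndarray
    rho: np.ndarray  # NaN where the overlap is too short for the scale

    def at(self, lag: int) -> float:
        return float(self.rho[int(np.flatnonzero(self.lags == lag)[0])])


def lagged_dpcca(x, y, conditioning: list | None = None, max_lag: int = 10,
                 scales: tuple[int, ...] = DEFAULT_SCALES) -> list[DpccaCurve]:
    """DPCCA curves of the pair (x, y) over lags, one curve per scale.

    The lag convention matches :func:`shift_pair` (positive lag = y's past
    against x's present). At each lag, x, y and every conditioning series
    are truncated to the overlap (conditioning series follow x's window) and
    the whole DPCCA computation runs on that overlap. A (lag, scale) whose
    overlap is not longer than the scale is marked NaN, not an error.
    """
    conditioning = conditioning or []
    xv, yv = _values(x), _values(y)
    cvs = [_values(c) for c in conditioning]
    n = len(xv)
    pair = (getattr(x, "series_id", "x"), getattr(y, "series_id", "y"))
    cond_ids = [getattr(c, "series_id", k) for k, c in enumerate(conditioning)]
    lags = np.arange(-max_lag, max_lag + 1)
    curves = [DpccaCurve(pair, cond_ids, s, lags, np.full(len(lags), np.nan)) for s in scales]
    for i, lag in enumerate(lags):
        xs, ys = shift_pair(xv, yv, int(lag))
        if lag >= 0:
            cs = [c[lag:] for c in cvs]
        else:
            cs = [c[: n + lag] for c in cvs]
        members = [xs, ys] + cs
        for curve in curves:
            if len(xs) <= curve.scale:
                continue
            result = dpcca(members, curve.scale, target=(0, 1))
            curve.rho[i] = result.partial(0, 1)
    return curves
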