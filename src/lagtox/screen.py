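"""Pair screening: thresholds, peak lags, asymmetry, and the full pipeline.

Applies the surveillance screening logic over every pair in a comparison
class — production areas (same species), species (same area), phytoplankton
against toxicity, and environmental conditions against toxicity — computing
lagged correlation curves, discarding non-significant Pearson entries
(raw p >= 0.05 by default; no multiple-testing correction is applied, and
the report carries the number of tests so users can apply their own),
flagging threshold passes (0.65 / 0.7 at any lag for Pearson, 0.9 for
DPCCA), locating peak lags, and quantifying curve asymmetry.

``run_pipeline`` chains everything: synthetic data generation (or reading
an existing export), preprocessing, seasonal profiling, and screening, with
all outputs written as CSV/JSON plus a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import lagcorr, prep, seasonal, synth
from .panel import SeriesId, SeriesPanel
from .synth import AreaMeta

logger = logging.getLogger(__name__)

__all__ = [
    "ScreeningResult",
    "DEFAULT_THRESHOLDS",
    "peak_lag",
    "asymmetry_index",
    "enumerate_pairs",
    "screen_pairs",
    "run_pipeline",
]

DEFAULT_THRESHOLDS = {"pearson_any": 0.65, "pearson_pair": 0.7, "dpcca": 0.9}

COMPARISON_CLASSES = ("area-area", "species-species", "phyto-toxicity", "environment-toxicity")


def _curve_values(curve) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(curve, lagcorr.LagCorrCurve):
        return curve.lags, curve.r
    if isinstance(curve, lagcorr.DpccaCurve):
        return curve.lags, curve.rho
    raise TypeError(f"unsupported curve type {type(curve).__name__}")


def peak_lag(curve) -> tuple[int, float]:
    """Lag maximising the curve value; ties to the smallest |lag|, then negative.

    Accepts a Pearson or DPCCA curve (or a (lags, values) tuple).
    """
    if isinstance(curve, tuple):
        lags, vals = np.asarray(curve[0]), np.asarray(curve[1], dtype=float)
    else:
        lags, vals = _curve_values(curve)
    defined = ~np.isnan(vals)
    if not defined.any():
        raise ValueError("curve has no defined entries")
    order = sorted(np.flatnonzero(defined),
                   key=lambda i: (-vals[i], abs(int(lags[i])), int(lags[i])))
    best = order[0]
    return int(lags[best]), float(vals[best])


def asymmetry_index(curve) -> float:
    """Max over positive lags minus max over negative lags.

    Positive means the second series' past is the better predictor of the
    first series' present (the second series leads). Lag 0 belongs to
    neither side; an even-symmetric curve scores 0.
    """
    if isinstance(curve, tuple):
        lags, vals = np.asarray(curve[0]), np.asarray(curve[1], dtype=float)
    else:
        lags, vals = _curve_values(curve)
    pos = vals[lags > 0]
    neg = vals[lags < 0]

    def side_max(v: np.ndarray) -> float:
        v = v[~np.isnan(v)]
        return float(v.max()) if v.size else np.nan

    return side_max(pos) - side_max(neg)


@dataclass
class ScreeningResult:
    """Outcome of screening one pair."""

    pair: tuple[SeriesId, SeriesId]
    comparison_class: str
    method: str  # "pearson" | "dpcca"
    best_value: float
    best_lag: int
    best_scale: int | None
    passes: dict[str, bool]
    p_at_peak: float | None
    asymmetry: float
    n_tests: int

    def to_dict(self) -> dict:
        return {
            "x": str(self.pair[0]),
            "y": str(self.pair[1]),
            "class": self.comparison_class,
            "method": self.method,
            "best_value": self.best_value,
            "best_lag": self.best_lag,
            "best_scale": self.best_scale,
            **{f"pass_{k}": v for k, v in self.passes.items()},
            "p_at_peak": self.p_at_peak,
            "asymmetry": self.asymmetry,
            "n_tests": self.n_tests,
        }


def enumerate_pairs(panel: SeriesPanel, comparison_class: str,
                    target_species: str = "mussel") -> list[tuple[SeriesId, SeriesId]]:
    """Pairs of series ids for one comparison class.

    Area pairs are unordered (the Pearson curve of the swapped pair is the
    mirrored curve, so ordered duplicates are redundant); species and
    cross-variable pairs are ordered because their curves are asymmetric.
    """
    if comparison_class not in COMPARISON_CLASSES:
        raise ValueError(f"unknown comparison class {comparison_class!r}")
    ids = panel.ids()
    pairs: list[tuple[SeriesId, SeriesId]] = []
    if comparison_class == "area-area":
        tox = sorted([s for s in ids if s.variable == "toxicity" and s.species == target_species],
                     key=str)
        pairs = [(a, b) for i, a in enumerate(tox) for b in tox[i + 1:]]
    elif comparison_class == "species-species":
        by_area: dict[str, list[SeriesId]] = {}
        for s in ids:
            if s.variable == "toxicity":
                by_area.setdefault(s.area, []).append(s)
        for area in sorted(by_area):
            members = sorted(by_area[area], key=str)
            pairs.extend((a, b) for a in members for b in members if a != b)
    elif comparison_class == "phyto-toxicity":
        for s in sorted(ids, key=str):
            if s.variable == "toxicity" and s.species == target_species:
                phyto = SeriesId(s.area, "phyto")
                if phyto in panel:
                    pairs.append((s, phyto))
    else:  # environment-toxicity
        for s in sorted(ids, key=str):
            if s.variable == "toxicity" and s.species == target_species:
                for var in synth.ENV_VARIABLES:
                    env = SeriesId(s.area, var)
                    if env in panel:
                        pairs.append((s, env))
    return pairs


def screen_pairs(panel: SeriesPanel, comparison_class: str, method: str = "pearson",
                 thresholds: dict[str, float] | None = None, p_threshold: float = 0.05,
                 max_lag: int = 10, scales: tuple[int, ...] = lagcorr.DEFAULT_SCALES,
                 target_species: str = "mussel") -> list[ScreeningResult]:
    """Screen every pair of a class; sorted by best value descending.

    For Pearson, lag entries with p >= ``p_threshold`` are discarded before
    thresholding and peak location. DPCCA curves carry no p-values; the 0.9
    coefficient threshold applies to the best value over all lags and scales.
    """
    thresholds = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    if method not in ("pearson", "dpcca"):
        raise ValueError(f"unknown method {method!r}")
    pairs = enumerate_pairs(panel, comparison_class, target_species)
    if not pairs:
        logger.warning("no pairs to screen for class %s", comparison_class)
        return []
    results: list[ScreeningResult] = []
    n_tests = len(pairs) * (2 * max_lag + 1)
    for sid_x, sid_y in pairs:
        x, y = panel[sid_x], panel[sid_y]
        if method == "pearson":
            curve = lagcorr.lagged_pearson(x, y, max_lag)
            r = curve.r.copy()
            r[~(curve.p < p_threshold)] = np.nan
            screened = (curve.lags, r)
            if np.isnan(r).all():
                best_lag_, best_val, p_at = 0, np.nan, None
                asym = np.nan
            else:
                best_lag_, best_val = peak_lag(screened)
                p_at = float(curve.p[np.flatnonzero(curve.lags == best_lag_)[0]])
                asym = asymmetry_index(screened)
            passes = {
                "0.65_any_lag": bool(best_val >= thresholds["pearson_any"]) if np.isfinite(best_val) else False,
                "0.7_any_lag": bool(best_val >= thresholds["pearson_pair"]) if np.isfinite(best_val) else False,
            }
            results.append(ScreeningResult((sid_x, sid_y), comparison_class, method,
                                           float(best_val), best_lag_, None, passes, p_at,
                                           float(asym), n_tests))
        else:
            curves = lagcorr.lagged_dpcca(x, y, max_lag=max_lag, scales=scales)
            stacked = np.stack([c.rho for c in curves])  # scale x lag
            if np.isnan(stacked).all():
                raise ValueError(f"all (lag, scale) entries undefined for {sid_x} vs {sid_y}")
            envelope = np.nanmax(stacked, axis=0)
            best_lag_, best_val = peak_lag((curves[0].lags, envelope))
            scale_idx = int(np.nanargmax(stacked[:, np.flatnonzero(curves[0].lags == best_lag_)[0]]))
            asym = asymmetry_index((curves[0].lags, envelope))
            passes = {"0.9_dpcca": bool(best_val >= thresholds["dpcca"])}
            results.append(ScreeningResult((sid_x, sid_y), comparison_class, method,
                                           float(best_val), best_lag_, int(scales[scale_idx]),
                                           passes, None, float(asym), n_tests))
    results.sort(key=lambda r: (-(r.best_value if np.isfinite(r.best_value) else -np.inf),
                                str(r.pair[0]), str(r.pair[1])))
    return results


# ---------------------------------------------------------------------------
# Whole-pipeline driver
# ---------------------------------------------------------------------------

_SYNTH_KEYS = {f.name for f in synth.SynthConfig.__dataclass_fields__.values()}
_PREP_KEYS = {f.name for f in prep.PrepConfig.__dataclass_fields__.values()}
_SCREEN_KEYS = {"max_lag", "p_threshold", "thresholds", "scales", "target_species",
                "dpcca_classes", "pearson_classes"}
_TOP_KEYS = {"seed", "synth", "prep", "screen"}


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")


def run_pipeline(config: dict | None, out_dir: str | Path) -> dict:
    """Execute generate -> prep -> seasonal -> screen and write all outputs.

    ``config`` is a nested dict with optional sections ``synth``, ``prep``
    and ``screen`` plus a top-level ``seed``; unknown keys raise at startup.
    Returns a summary dict (also written as ``manifest.json``). Reruns with
    the same config produce byte-identical CSV outputs.
    """
    config = config or {}
    _check_keys(config, _TOP_KEYS, "top level")
    seed = int(config.get("seed", 0))
    synth_kw = dict(config.get("synth", {}))
    _check_keys(synth_kw, _SYNTH_KEYS - {"seed"}, "synth")
    prep_kw = dict(config.get("prep", {}))
    _check_keys(prep_kw, _PREP_KEYS - {"seed"}, "prep")
    screen_kw = dict(config.get("screen", {}))
    _check_keys(screen_kw, _SCREEN_KEYS, "screen")

    if "species" in synth_kw:
        synth_kw["species"] = tuple(
            synth.SpeciesKinetics(**sp) if isinstance(sp, dict) else sp
            for sp in synth_kw["species"])
    if "season_peaks" in synth_kw:
        synth_kw["season_peaks"] = tuple(tuple(p) for p in synth_kw["season_peaks"])
    scfg = synth.SynthConfig(seed=seed, **synth_kw)
    prep_kw.setdefault("start_date", scfg.start_date)
    prep_kw.setdefault("end_date", scfg.end_date)
    if "outlier_rule" in prep_kw and isinstance(prep_kw["outlier_rule"], list):
        prep_kw["outlier_rule"] = tuple(prep_kw["outlier_rule"])
    if "candidates" in prep_kw and prep_kw["candidates"] is not None:
        prep_kw["candidates"] = tuple(prep_kw["candidates"])
    pcfg = prep.PrepConfig(seed=seed, **prep_kw)

    max_lag = int(screen_kw.get("max_lag", 10))
    p_threshold = float(screen_kw.get("p_threshold", 0.05))
    thresholds = screen_kw.get("thresholds")
    scales = tuple(screen_kw.get("scales", lagcorr.DEFAULT_SCALES))
    target_species = screen_kw.get("target_species", "mussel")
    pearson_classes = tuple(screen_kw.get("pearson_classes", COMPARISON_CLASSES))
    dpcca_classes = tuple(screen_kw.get("dpcca_classes", ("area-area",)))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data_dir = out / "data"

    logger.info("stage synth: generating datasets (seed %d)", seed)
    sim = synth.simulate_all(scfg, out_dir=data_dir)
    areas: list[AreaMeta] = sim["areas"]

    logger.info("stage prep: building the weekly panel")
    panel, reports = prep.prepare_panel(sim["paths"], pcfg)
    panel.to_frame().to_csv(out / "panel.csv", index_label="Date", lineterminator="\n")
    with open(out / "imputation_report.json", "w") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=1, default=float)

    logger.info("stage seasonal: profiles")
    tox_ids = [sid for sid in panel.ids()
               if sid.variable == "toxicity" and sid.species == target_species]
    profiles = {str(sid): seasonal.monthly_profile(panel[sid]) for sid in tox_ids}
    trends = {str(sid): seasonal.yearly_profile(panel[sid]) for sid in tox_ids}
    seasonal.profiles_to_frame(profiles).to_csv(out / "seasonal_monthly.csv", index=False,
                                                lineterminator="\n")
    seasonal.profiles_to_frame(trends).to_csv(out / "trend_yearly.csv", index=False,
                                              lineterminator="\n")
    tox_panel = panel.subset(tox_ids)
    if tox_panel.ids():
        regional = seasonal.regional_profile(tox_panel, areas, kind="seasonal")
        seasonal.profiles_to_frame(regional).to_csv(out / "seasonal_regional.csv", index=False,
                                                    lineterminator="\n")

    logger.info("stage screen: pair screening")
    all_results: list[ScreeningResult] = []
    for cls in pearson_classes:
        all_results.extend(screen_pairs(panel, cls, "pearson", thresholds, p_threshold,
                                        max_lag, scales, target_species))
    for cls in dpcca_classes:
        all_results.extend(screen_pairs(panel, cls, "dpcca", thresholds, p_threshold,
                                        max_lag, scales, target_species))
    screen_frame = pd.DataFrame([r.to_dict() for r in all_results])
    screen_frame.to_csv(out / "screening.csv", index=False, lineterminator="\n")

    cfg_json = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "seed": seed,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_areas": len(areas),
        "n_series": len(panel),
        "n_imputed_series": len(reports),
        "n_screened_pairs": len(all_results),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return {"manifest": manifest, "panel": panel, "reports": reports,
            "screening": all_results, "areas": areas}
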