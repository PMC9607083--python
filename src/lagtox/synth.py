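"""Synthetic shellfish-monitoring data generator.

Emulates the three long-format monitoring datasets a coastal biotoxin
surveillance programme produces — DSP toxin concentrations per production
area and shellfish species, toxic-phytoplankton cell counts, and
oceanographic/meteorological conditions — together with an area-metadata
table (coast side, north-to-south rank, adjacency, region).

The generator plants the statistical structure the downstream analysis is
designed to detect:

* bimodal within-year seasonality of blooms (defaults: May and September
  peaks), hence of toxicity;
* a north-to-south amplitude gradient (southern areas see weaker blooms);
* spatial coherence that decays geometrically per adjacency step along the
  coastline chain;
* species-specific uptake/elimination kinetics: toxin body burden follows a
  first-order recursion ``T[t+1] = baseline + (1 - e)*(T[t] - baseline) +
  u*P[t]``, so a slowly eliminating species lags a fast one under the same
  bloom forcing, producing asymmetric lagged correlations;
* realistic missingness: i.i.d. thinning plus occasional contiguous gaps.

All randomness flows from ``SynthConfig.seed`` through per-stage child
generators, so identical configs yield byte-identical exports.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import SeriesId, SeriesPanel, WeeklySeries, weekly_index

__all__ = [
    "AreaMeta",
    "SpeciesKinetics",
    "SynthConfig",
    "make_area_metadata",
    "simulate_environment",
    "simulate_blooms",
    "simulate_toxicity",
    "apply_missingness",
    "export_datasets",
    "simulate_all",
    "TOXIN_COLUMNS",
    "PHYTO_COLUMNS",
    "ENV_COLUMNS",
    "META_COLUMNS",
    "ENV_VARIABLES",
]

# Long-format export schemas (column roles of the three monitoring tables).
TOXIN_COLUMNS = ["Date", "Production Area", "Species", "DSP Toxins"]
PHYTO_COLUMNS = ["Date", "Production Area", "DSP Toxins Producers"]
ENV_VARIABLES = ["SST", "Chlorophyll-a", "Air Temperature", "Wind", "Rainfall"]
ENV_COLUMNS = ["Date", "Production Area"] + ENV_VARIABLES
META_COLUMNS = ["area_id", "coast", "ns_rank", "region", "neighbors"]

ENV_UNITS = {
    "SST": "K",
    "Chlorophyll-a": "mg/L",
    "Air Temperature": "degC",
    "Wind": "km/h",
    "Rainfall": "mm",
}


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class AreaMeta:
    """One production area: coast side, north-to-south rank, region, adjacency."""

    area_id: str
    coast: str  # "west" | "south"
    ns_rank: int  # 0 = northernmost
    region: str  # "northwest" | "southwest" | "south"
    neighbors: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.coast not in ("west", "south"):
            raise ConfigError(f"{self.area_id}: coast must be 'west' or 'south'")
        if self.region not in ("northwest", "southwest", "south"):
            raise ConfigError(f"{self.area_id}: unknown region {self.region!r}")
        if self.coast == "south" and self.region != "south":
            raise ConfigError(f"{self.area_id}: south-coast areas belong to the south region")


@dataclass(frozen=True)
class SpeciesKinetics:
    """First-order toxin uptake/elimination parameters for one species.

    ``uptake_rate`` is the fraction of the ambient bloom signal accumulated
    per week; ``elimination_rate`` the weekly fractional loss of body burden;
    ``baseline`` the concentration floor in ug OA eq. per kg.
    """

    species: str
    uptake_rate: float
    elimination_rate: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.elimination_rate <= 1.0):
            raise ConfigError(f"{self.species}: elimination_rate must be in (0, 1]")
        if self.uptake_rate <= 0.0:
            raise ConfigError(f"{self.species}: uptake_rate must be > 0")
        if self.baseline < 0.0:
            raise ConfigError(f"{self.species}: baseline must be >= 0")


def _default_species() -> tuple[SpeciesKinetics, ...]:
    # Mussel accumulates fast and eliminates slowly (the regulatory sentinel);
    # cockle turns over faster, so its toxicity leads mussel's under shared
    # bloom forcing; surf clam is a weak accumulator; Donax clam is slow.
    return (
        SpeciesKinetics("mussel", uptake_rate=0.12, elimination_rate=0.35, baseline=30.0),
        SpeciesKinetics("cockle", uptake_rate=0.10, elimination_rate=0.65, baseline=20.0),
        SpeciesKinetics("surf_clam", uptake_rate=0.04, elimination_rate=0.50, baseline=15.0),
        SpeciesKinetics("donax_clam", uptake_rate=0.13, elimination_rate=0.25, baseline=40.0),
    )


@dataclass(frozen=True)
class SynthConfig:
    """Full description of one synthetic monitoring scenario."""

    seed: int = 0
    n_areas: int = 6
    start_date: str = "2015-01-05"
    end_date: str = "2020-12-29"
    species: tuple[SpeciesKinetics, ...] = field(default_factory=_default_species)
    # (month, relative amplitude) pairs; defaults plant the May / September
    # bimodal bloom season typical of the Iberian upwelling coast.
    season_peaks: tuple[tuple[int, float], ...] = ((5, 1.0), (9, 0.8))
    season_width_months: float = 0.6
    spatial_decay: float = 0.6  # pulse attenuation per adjacency step
    ns_gradient: float = 0.85  # amplitude multiplier per rank step southward
    pulse_rate: float = 0.7  # peak-season weekly bloom-pulse probability
    mark_log_mean: float = 6.5  # log-scale location of pulse magnitudes
    mark_log_sd: float = 0.9  # log-scale spread (heavy right tail)
    noise_sd: float = 1.0  # environmental observation noise scale (1 = default)
    sst_peak_week: int = 33  # week of year when SST peaks
    n_south_areas: int = 2  # trailing ranks assigned to the south coast
    region_pivot_rank: int = 2  # west-coast ranks below this -> northwest
    missing_frac: float = 0.1
    block_gap_rate: float = 2.0  # expected contiguous gap blocks per series
    block_gap_mean_len: float = 4.0

    def __post_init__(self) -> None:
        for name in ("spatial_decay", "ns_gradient", "missing_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.missing_frac >= 1.0:
            raise ConfigError("missing_frac must be < 1")
        if not self.season_peaks:
            raise ConfigError("at least one season peak is required")
        if pd.Timestamp(self.end_date) <= pd.Timestamp(self.start_date):
            raise ConfigError("end_date must be after start_date")
        if len(self.species) == 0:
            raise ConfigError("at least one species is required")

    def rng(self, stream: int) -> np.random.Generator:
        """Child generator for one pipeline stage; streams never collide."""
        return np.random.default_rng([self.seed, stream])

    def index(self) -> pd.DatetimeIndex:
        return weekly_index(self.start_date, self.end_date)

    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# Area metadata
# ---------------------------------------------------------------------------

def make_area_metadata(config: SynthConfig) -> list[AreaMeta]:
    """North-to-south chain of production areas with rank adjacency.

    The last ``n_south_areas`` ranks lie on the south coast (region south);
    west-coast areas split at ``region_pivot_rank`` into northwest (above)
    and southwest (the pivot and below), mirroring how surveillance
    programmes group areas along a coastline that bends eastward.
    """
    if config.n_areas < 2:
        raise ConfigError(f"n_areas must be >= 2, got {config.n_areas}")
    n = config.n_areas
    n_south = min(config.n_south_areas, max(n - 1, 0))
    areas: list[AreaMeta] = []
    ids = [f"A{r:02d}" for r in range(n)]
    for r in range(n):
        coast = "south" if r >= n - n_south else "west"
        if coast == "south":
            region = "south"
        elif r < config.region_pivot_rank:
            region = "northwest"
        else:
            region = "southwest"
        neigh = tuple(ids[j] for j in (r - 1, r + 1) if 0 <= j < n)
        areas.append(AreaMeta(ids[r], coast, r, region, neigh))
    return areas


# ---------------------------------------------------------------------------
# Environmental conditions
# ---------------------------------------------------------------------------

def _season_weight(index: pd.DatetimeIndex, config: SynthConfig) -> np.ndarray:
    """Within-year bloom intensity in [0, 1]: Gaussian bumps at the peak months."""
    month_frac = (index.month.to_numpy(float) - 1) + (index.day.to_numpy(float) - 1) / 30.4375
    w = np.zeros(len(index))
    for month, amp in config.season_peaks:
        d = np.abs(month_frac - (month - 1))
        d = np.minimum(d, 12.0 - d)  # circular month distance
        w = np.maximum(w, amp * np.exp(-0.5 * (d / config.season_width_months) ** 2))
    return w


def simulate_environment(config: SynthConfig, areas: list[AreaMeta]) -> SeriesPanel:
    """Weekly oceanographic/meteorological panel per area.

    SST (Kelvin) and air temperature (Celsius) are annual sinusoids peaking at
    ``sst_peak_week``; chlorophyll-a is positive and bloom-season linked; wind
    and rainfall are non-negative draws. ``noise_sd`` scales all stochastic
    components; at 0 the temperature series are exactly sinusoidal.
    """
    index = config.index()
    rng = config.rng(1)
    nt = len(index)
    phase = np.cos(2.0 * np.pi * (index.isocalendar().week.to_numpy(float) - config.sst_peak_week) / 52.18)
    season = _season_weight(index, config)
    panel = SeriesPanel(index)
    for a in areas:
        south_shift = 0.4 * a.ns_rank  # warmer southward
        sst = 291.0 + south_shift + 3.0 * phase + config.noise_sd * 0.3 * rng.standard_normal(nt)
        air = 16.0 + 0.3 * a.ns_rank + 6.0 * phase + config.noise_sd * 1.0 * rng.standard_normal(nt)
        chl = (0.2 + 2.0 * season) * np.exp(config.noise_sd * 0.3 * rng.standard_normal(nt))
        wind = rng.gamma(2.0, 7.5, nt)
        rain = rng.binomial(1, 0.5, nt) * rng.gamma(1.5, 8.0, nt)
        values = {
            "SST": np.clip(sst, 285.0, 297.0),
            "Chlorophyll-a": chl,
            "Air Temperature": air,
            "Wind": wind,
            "Rainfall": rain,
        }
        for var, vals in values.items():
            panel.add(WeeklySeries(SeriesId(a.area_id, var), index, vals, units=ENV_UNITS[var]))
    return panel


# ---------------------------------------------------------------------------
# Phytoplankton blooms
# ---------------------------------------------------------------------------

def simulate_blooms(config: SynthConfig, areas: list[AreaMeta],
                    environment: SeriesPanel) -> SeriesPanel:
    """Weekly toxic-phytoplankton cell counts (cells/L) per area.

    Each area owns a latent pulse train (seasonally modulated Bernoulli
    occurrences with log-normal marks — the heavy right tail of real cell
    counts); the observed count is a weighted mix of all trains with weight
    ``spatial_decay ** adjacency_distance``, normalised so the marginal scale
    is rank-independent, then scaled by ``ns_gradient ** ns_rank``. Decay 1
    makes adjacent areas identical; decay 0 makes them independent.
    """
    index = environment.index
    if not index.equals(config.index()):
        raise ConfigError("environment panel index does not match the config span")
    rng = config.rng(2)
    nt = len(index)
    season = _season_weight(index, config)
    n = len(areas)
    ranks = np.array([a.ns_rank for a in areas])
    # Latent per-area trains: both pulse occurrence and pulse magnitude are
    # seasonally modulated (blooms are more frequent *and* larger in season).
    floor = np.maximum(season, 0.02)[None, :]
    occur = rng.random((n, nt)) < config.pulse_rate * floor
    marks = rng.lognormal(mean=config.mark_log_mean, sigma=config.mark_log_sd, size=(n, nt))
    trains = occur * marks * floor
    # Geometric attenuation per adjacency (rank-distance) step.
    dist = np.abs(ranks[:, None] - ranks[None, :])
    if config.spatial_decay == 0.0:
        weights = (dist == 0).astype(float)
    else:
        weights = config.spatial_decay ** dist
    weights = weights / weights.sum(axis=1, keepdims=True)
    mixed = weights @ trains
    panel = SeriesPanel(index)
    for i, a in enumerate(areas):
        counts = mixed[i] * (config.ns_gradient ** a.ns_rank)
        panel.add(WeeklySeries(SeriesId(a.area_id, "phyto"), index, counts, units="cells/L"))
    return panel


# ---------------------------------------------------------------------------
# Shellfish toxicity
# ---------------------------------------------------------------------------

def simulate_toxicity(blooms: SeriesPanel, kinetics: SpeciesKinetics,
                      initial: float | None = None) -> SeriesPanel:
    """DSP toxin burden per area for one species (ug OA eq. / kg).

    First-order kinetics driven by the area's bloom series::

        T[0]   = initial (defaults to baseline)
        T[t+1] = baseline + (1 - e) * (T[t] - baseline) + u * P[t]

    With zero forcing the burden relaxes geometrically to the baseline; a
    smaller elimination rate ``e`` integrates the forcing over a longer
    window, which is what displaces the cross-correlation peak between a
    fast and a slow species away from lag zero.
    """
    panel = SeriesPanel(blooms.index)
    for s in blooms:
        p = s.values
        if not np.all(np.isfinite(p)):
            raise ValueError(f"{s.series_id}: bloom input contains non-finite values")
        t = np.empty(len(p))
        t[0] = kinetics.baseline if initial is None else initial
        keep = 1.0 - kinetics.elimination_rate
        for i in range(len(p) - 1):
            t[i + 1] = kinetics.baseline + keep * (t[i] - kinetics.baseline) + kinetics.uptake_rate * p[i]
        sid = SeriesId(s.series_id.area, "toxicity", kinetics.species)
        panel.add(WeeklySeries(sid, blooms.index, t, units="ug OA eq./kg"))
    return panel


def simulate_lead_pair(config: SynthConfig, lead: int = 2, obs_noise: float = 0.02,
                       kinetics: SpeciesKinetics | None = None,
                       n_weeks: int = 312) -> tuple[WeeklySeries, WeeklySeries]:
    """Kinetics-coupled pair with a planted lead of ``lead`` weeks.

    Both members share one bloom pulse train and one species' kinetics, but
    the follower's forcing is the leader's delayed by ``lead`` weeks, so the
    lagged-correlation curve of ``(follower, leader)`` peaks at ``+lead``
    (the leader's past predicts the follower's present). ``obs_noise``
    scales i.i.d. observation noise relative to the signal's standard
    deviation. Returns ``(follower, leader)``.
    """
    if lead < 0:
        raise ConfigError("lead must be >= 0")
    kin = kinetics if kinetics is not None else config.species[0]
    areas = make_area_metadata(config)
    env = simulate_environment(config, areas)
    bloom = simulate_blooms(config, areas, env)[SeriesId(areas[0].area_id, "phyto")]
    index = bloom.index[:n_weeks]
    train = bloom.values[:n_weeks]
    delayed = np.concatenate([np.full(lead, train.mean()), train[: len(train) - lead]])
    forcing = SeriesPanel(index)
    forcing.add(WeeklySeries(SeriesId("LEAD", "phyto"), index, train))
    forcing.add(WeeklySeries(SeriesId("FOLLOW", "phyto"), index, delayed))
    tox = SeriesPanel(index)
    for s in simulate_toxicity(forcing, kin):
        tox.add(s)
    rng = config.rng(6)
    leader = tox[SeriesId("LEAD", "toxicity", kin.species)]
    follower = tox[SeriesId("FOLLOW", "toxicity", kin.species)]
    scale = obs_noise * leader.values.std()
    leader = leader.with_values(leader.values + scale * rng.standard_normal(len(index)))
    follower = follower.with_values(follower.values + scale * rng.standard_normal(len(index)))
    return follower, leader


# ---------------------------------------------------------------------------
# Missingness
# ---------------------------------------------------------------------------

def apply_missingness(panel: SeriesPanel, config: SynthConfig,
                      stream: int = 3) -> tuple[SeriesPanel, dict[SeriesId, np.ndarray]]:
    """Hide entries by i.i.d. thinning plus contiguous gap blocks (MCAR).

    Returns the thinned panel and, per series, the boolean mask of entries
    that were made missing. Observed values are never altered.
    """
    rng = config.rng(stream)
    out = SeriesPanel(panel.index)
    masks: dict[SeriesId, np.ndarray] = {}
    nt = len(panel.index)
    for s in panel:
        mask = rng.random(nt) < config.missing_frac
        n_blocks = rng.poisson(config.block_gap_rate)
        for _ in range(n_blocks):
            length = 1 + rng.poisson(max(config.block_gap_mean_len - 1.0, 0.0))
            start = int(rng.integers(0, nt))
            mask[start:start + length] = True
        vals = s.values.copy()
        vals[mask] = np.nan
        out.add(s.with_values(vals))
        masks[s.series_id] = mask
    return out, masks


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def _date_str(index: pd.DatetimeIndex) -> np.ndarray:
    return index.strftime("%Y-%m-%d").to_numpy()


def export_datasets(toxicity: SeriesPanel, phyto: SeriesPanel, environment: SeriesPanel,
                    areas: list[AreaMeta], out_dir: str | Path) -> dict[str, Path]:
    """Write the three long-format monitoring CSVs plus area metadata.

    Toxin and phytoplankton tables omit missing weeks (that is how gaps
    manifest in real sampling records); the environmental table keeps one row
    per (date, area) with blanks for missing cells. Dates are ISO-8601.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "toxins": out / "toxins.csv",
        "phyto": out / "phytoplankton.csv",
        "environment": out / "environment.csv",
        "metadata": out / "areas.csv",
    }

    rows = []
    for sid, s in sorted(toxicity.series.items(), key=lambda kv: (kv[0].area, kv[0].species or "")):
        dates = _date_str(s.index)
        for i in np.flatnonzero(s.observed_mask):
            rows.append((dates[i], sid.area, sid.species, s.values[i]))
    pd.DataFrame(rows, columns=TOXIN_COLUMNS).to_csv(paths["toxins"], index=False)

    rows = []
    for sid, s in sorted(phyto.series.items(), key=lambda kv: kv[0].area):
        dates = _date_str(s.index)
        for i in np.flatnonzero(s.observed_mask):
            rows.append((dates[i], sid.area, s.values[i]))
    pd.DataFrame(rows, columns=PHYTO_COLUMNS).to_csv(paths["phyto"], index=False)

    env_areas = sorted({sid.area for sid in environment.ids()})
    frames = []
    for area in env_areas:
        cols = {"Date": _date_str(environment.index), "Production Area": area}
        for var in ENV_VARIABLES:
            cols[var] = environment[SeriesId(area, var)].values
        frames.append(pd.DataFrame(cols))
    pd.concat(frames, ignore_index=True).to_csv(paths["environment"], index=False)

    meta = pd.DataFrame(
        [(a.area_id, a.coast, a.ns_rank, a.region, ";".join(a.neighbors)) for a in areas],
        columns=META_COLUMNS,
    )
    meta.to_csv(paths["metadata"], index=False)
    return paths


def simulate_all(config: SynthConfig,
                 out_dir: str | Path | None = None) -> dict[str, object]:
    """Run the whole generator; optionally export the four CSVs.

    Returns a dict with ``areas``, complete panels (``environment``,
    ``blooms``, ``toxicity``), the thinned observation panels
    (``toxicity_obs``, ``phyto_obs``, ``environment_obs``) and, when
    ``out_dir`` is given, the export ``paths``.
    """
    areas = make_area_metadata(config)
    environment = simulate_environment(config, areas)
    blooms = simulate_blooms(config, areas, environment)
    toxicity = SeriesPanel(blooms.index)
    for kin in config.species:
        for s in simulate_toxicity(blooms, kin):
            toxicity.add(s)
    tox_obs, _ = apply_missingness(toxicity, config, stream=3)
    phyto_obs, _ = apply_missingness(blooms, config, stream=4)
    env_obs, _ = apply_missingness(environment, config, stream=5)
    result: dict[str, object] = {
        "areas": areas,
        "environment": environment,
        "blooms": blooms,
        "toxicity": toxicity,
        "toxicity_obs": tox_obs,
        "phyto_obs": phyto_obs,
        "environment_obs": env_obs,
    }
    if out_dir is not None:
        result["paths"] = export_datasets(tox_obs, phyto_obs, env_obs, areas, out_dir)
    return result
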