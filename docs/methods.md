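# Methods

This note documents the models, numerical choices and limitations behind
`lagtox`, in the order the pipeline runs.

## Synthetic monitoring data

The generator emulates three monitoring tables (toxins, phytoplankton cell
counts, environmental conditions) plus area metadata, on a weekly grid of
7-day bins anchored at the configured start Monday (default
2015-01-05 → 2020-12-29; the default span yields 313 grid points — the
number of bins an inclusive span produces depends on the endpoint
convention, so the span is configuration, and no single week count is
asserted as canonical).

**Areas.** `n_areas` production areas form a north→south chain with rank
adjacency. The trailing `n_south_areas` ranks lie on the south coast and
belong to the *south* region; west-coast areas split at
`region_pivot_rank` into *northwest* (above) and *southwest*. This mirrors
how surveillance programmes group areas along a coastline that bends
eastward at its southern end.

**Blooms.** Each area owns a latent pulse train: weekly Bernoulli
occurrences with probability `pulse_rate · w(t)` and log-normal magnitudes
(`mark_log_mean = 6.5`, `mark_log_sd = 0.9`, a heavy right tail like real
cell counts), where `w(t)` is the seasonal weight — the max of Gaussian
bumps centred on the peak months (defaults May amplitude 1.0, September
0.8, width 0.6 months) with a floor of 0.02. Both occurrence *and*
magnitude are modulated by `w(t)`: real blooms are more frequent and larger
in season, and magnitude-only or occurrence-only modulation leaves the
monthly ranking of a 6-year record too noisy to call the planted peaks
reliably. Observed counts mix the latent trains with weight
`spatial_decay^d` per rank distance `d` (normalised), so decay 1 makes
areas identical and decay 0 independent, then scale by
`ns_gradient^rank` (default 0.85) for the southward attenuation.

**Toxicity kinetics.** Species-specific first-order uptake/elimination:

    T[0]   = baseline          (or a supplied initial burden)
    T[t+1] = baseline + (1 − e)·(T[t] − baseline) + u·P[t]

with uptake `u` per week of ambient bloom signal, elimination `e` per week,
and a baseline floor. A species with small `e` integrates forcing over
roughly `1/e` weeks; under shared forcing the fast-eliminating species
(default cockle, e = 0.65) responds promptly and the slow one (mussel,
e = 0.35; Donax clam, e = 0.25) lags, which is what makes the
species-vs-species lagged-correlation curves asymmetric. With white-noise
forcing the cross-correlation argmax of two such filters stays at lag 0 —
only the *tails* are asymmetric — so planted nonzero peak lags are
constructed explicitly (`simulate_lead_pair`) by delaying one member's
forcing by an integer number of weeks.

**Environment.** SST (Kelvin) and air temperature are annual sinusoids
peaking at `sst_peak_week` (default ISO week 33) with Gaussian noise scaled
by `noise_sd`; chlorophyll-a is positive and bloom-season linked; wind and
rainfall are non-negative gamma draws (rainfall zero-inflated). SST is
clipped to a plausible 285–297 K band.

**Missingness.** MCAR thinning at `missing_frac` (default 0.1) plus
Poisson-distributed contiguous gap blocks (`block_gap_rate` = 2 expected
blocks per series, mean length 4). Real monitoring gaps are probably not
completely at random (weather and holidays cluster them); the block
component captures the clustering but not any dependence on the values
themselves.

All stages draw from per-stage child generators of the single config seed,
so identical configs give byte-identical exports.

**What passing tests do and do not show.** The generator reproduces the
qualitative patterns the analysis screens for — seasonality, gradient,
adjacency coherence, kinetic lead–lag — with interpretable mechanisms, not
a calibrated model of any real coast. Recovery rates measured on it
demonstrate that the estimators detect structure *of the planted kind and
strength*; they say nothing about power against weaker or differently
shaped real-world signals, and nothing about informative missingness.

## Preprocessing

Observations are binned by `(date − start) // 7 days` and averaged within
bins; empty bins are missing. The optional outlier rule masks values with
`|x − median| > k·MAD` (default off, k = 5 when on — conservative, because
the downstream correlations are sensitive to removing genuine toxicity
peaks; the strict inequality makes a constant series a no-op while still
catching a lone extreme among identical values, where MAD = 0). Series
with fewer than `min_weeks` (default 240) observed weeks are dropped.

Imputer selection hides `hide_frac` (default 0.1) of each series' observed
values in each of `n_copies` (default 5) copies — disjoint subsets, never
overlapping original gaps — imputes each copy with every candidate, and
scores by mean RMSE, `sqrt(Σ(xᵢ−x̂ᵢ)²/N)`, over the hidden positions. The
candidate registry spans constant (mean, median), interpolating (linear,
spline of order 2–3), smoothing (centred moving average, window 3–13) and
seasonal (same-phase mean at period 13/26/52) families. Hyperparameters are
searched by exhaustive grid, seeded random subset, or a sequential
model-based ("Bayesian") strategy — Gaussian-process regression with
expected improvement over the discretised grid — capped at `budget`
(default 25) evaluations per method. Ties go to the method with fewer
hyperparameters, then registry order, so selection is deterministic given
the seed. Imputed values are treated as data downstream; the report keeps
each series' imputed fraction so users can audit, and p-values computed on
imputed series inherit whatever optimism that implies.

## Seasonality and trend

Seasonality is the monthly climatology (mean of all weekly values whose
bin-start falls in each calendar month, pooled across years) and trend the
per-year means — deliberately *not* a formal decomposition, since the goal
is to read off when peaks occur and how levels drift, not to separate
interacting components. Confidence intervals are the normal approximation
`mean ± z·sd/√n` at 95% (configurable); n = 1 yields an undefined
half-width. Weeks straddling month boundaries are assigned whole to their
bin-start month. Regional profiles pool the member series' weekly values
before averaging (so sample counts drive the CI); a mean-of-series mode is
available because figure conventions differ on this and neither is
canonical.

## Lagged correlations

The lag convention is fixed once and applied to Pearson and DPCCA alike:
at positive lag k, the first series' present is paired with the second
series' value k weeks earlier; a peak at k > 0 means the second series
leads. Overlaps are truncated, never wrapped, and for each lag the means
and profiles are recomputed on the overlap so every lag is a
self-contained computation (the alternative — shifting within full-series
profiles — mixes data from outside the overlap into the detrending and is
not self-consistent).

DCCA/DPCCA follow the standard construction: profile, per-window OLS line
(overlapping windows, step 1), residual moments with an `s − 1`
denominator per window and the window sum divided by `N − s`. Two
numerical notes:

* The defining equation for the detrended variance is sometimes printed
  with an unsquared residual sum, which cannot be a variance; the standard
  DFA form (squared residuals) is used.
* The `N − s` aggregate denominator under `N − s + 1` windows is kept as
  conventionally printed; it cancels in every coefficient ratio, so only
  the raw fluctuation magnitudes (which this package does not report)
  would notice.

The per-window residual operator `M = I − A(AᵀA)⁻¹Aᵀ` is precomputed once
per scale and applied to all windows as a matrix product, which is
algebraically identical to per-window OLS (the design is the same in every
window) and is verified against an explicit-loop reference to 1e-12.

DPCCA inverts the DCCA coefficient matrix; inversion is guarded by a
condition-number threshold of 1e10 with an error advising to drop
collinear series (an exactly redundant conditioning series makes the
matrix singular). For pairwise screening the conditioning set is the pair
itself — the choice is exposed because published pairwise DPCCA figures
rarely state whether extra series are conditioned on — which makes the
pairwise DPCCA equal to the DCCA coefficient; larger sets are supported.
A (lag, scale) whose overlap is not longer than the scale is undefined
(NaN), not an error. p-values are attached to Pearson only; DPCCA
significance would need a bootstrap, which is out of scope.

## Screening

Pearson lag entries with p ≥ 0.05 are discarded before thresholding — a
raw filter, with no multiple-testing correction; the result rows carry the
number of tests so users can apply their own. Thresholds: 0.65 (any lag)
for the broad Pearson screen, 0.7 for the pair figures, 0.9 for DPCCA
(best over lags and scales). Peak-lag ties break to the smallest |lag|,
then the negative one (a convention; ties are measure-zero in practice).
The asymmetry index is max-over-positive minus max-over-negative lags.
Area pairs are enumerated unordered (the swapped curve is the mirror);
species and cross-variable pairs are ordered because their curves are
asymmetric. Cross-variable screens target mussel toxicity by default, the
usual sentinel species.

## Problem sizes and determinism

Default study conditions: 6 areas, 4 species, a 2015–2020 weekly span
(313 bins), lags ±10 (±20 in extended mode), scales {4, 12, 26, 52}.
Recovery properties are stated as rates over 50 seeded repetitions (25 for
the end-to-end screen), with thresholds at 90% (80% for the
smoothness-vs-scale tendency, which is a tendency, not a theorem). The
pipeline driver validates its config strictly (unknown keys are startup
errors) and reruns with the same config and seed produce byte-identical
CSV/JSON outputs.

## Known limitations

* The generator's kinetics are linear; real uptake saturates and depends
  on temperature and feeding rate.
* MCAR missingness understates the difficulty of real gaps.
* Imputed values enter correlations as if observed; effective sample sizes
  and p-values are accordingly optimistic.
* No significance machinery for DPCCA, and no multiple-testing correction
  in the screen (by design, to mirror the raw-threshold practice it
  implements; both are documented in the outputs rather than corrected).
* Weekly binning anchored at the start date is not the ISO calendar; the
  two differ for series whose source cadence is aligned to calendar weeks.
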