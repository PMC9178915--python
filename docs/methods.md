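# Methods

## Problem setting

Mobile monitoring visits each 50 m street segment a handful of times for a
few seconds each, at whatever hour the car happened to pass. Two error
sources dominate a naive per-segment average: sampling-time bias (a street
only visited at rush hour looks dirtier than it is) and sampling noise
(few short passes). The package addresses the first with a
reference-station temporal correction and the second with random-intercept
shrinkage toward a land-use-regression (LUR) surface.

## Pipeline stages and their assumptions

**Plausibility filter.** Records outside [0, 500] µg/m³ are removed
(bounds inclusive: only strictly negative or strictly > 500 values are
implausible for on-road NO₂). Counts removed per bound are reported.

**Snapping.** Each record is assigned to the street segment with minimal
point-to-polyline distance, capped at `max_dist` (default 50 m — generous
enough for urban GPS error, tight enough to drop off-network points).
Exact ties break to the smaller segment id so results are deterministic.
No trajectory context is used; coordinates must be planar metres (no CRS
handling — reproject before use).

**Temporal correction.** For time window *w* (default: hourly bins ×
weekday/weekend) the correction adds `overall_ref_mean − ref_mean(w)` to
every record in *w*. The overall mean is the plain mean of the
fixed-cadence reference series — including nights and weekends the cars
never sampled — which is what makes corrected averages estimate *long-term*
concentrations. The correction is additive by default; a ratio mode
exists behind a flag for campaigns where drift is better described as
multiplicative. Correcting at the 1 Hz record level (before aggregation)
keeps pass means consistent with their member records.

**Aggregation.** One drive-pass = one (segment, calendar day). Pass means
are unweighted by duration when averaged into the per-segment mean of
means; the SEM layer is sd(pass means, ddof=1)/√n and is undefined (NaN)
for single-pass segments.

**LUR.** Supervised forward stepwise OLS on the data-only map. Entry
rules: candidate coefficient must carry its declared expected sign, the
adjusted-R² gain must be ≥ `gain_min` (default 0.01), and no previously
entered coefficient may lose its expected sign. After selection,
covariates with p ≥ 0.10 are pruned iteratively (worst first, refit each
time), followed by a sign-consistency sweep. These thresholds are the
convention in the supervised-LUR literature and are all configurable. OLS
is unweighted across segments. The intercept is always included and
exempt from sign rules. A constant response yields R² = 0 and an
intercept-only model with a warning.

**Mixed model.** `y_ik = x_i'β + b_i + ε_ik` on drive-pass means, fitted
by REML (default; ML behind a flag). Because covariates are constant
within segment, the restricted likelihood is profiled over
λ = σ²_b/σ²_e: per-segment weights `w_i = n_i/(1 + n_i λ)` give closed
GLS forms for β and σ²_e, and a bounded Brent search on log λ ∈
[log 1e−8, log 1e8] (xatol 1e−12) plus an explicit boundary comparison at
λ = 0 finds the optimum. REML rather than ML because unbiased variance
components drive the shrinkage weights. The fixed-effect set is the LUR
selection, re-estimated by GLS inside the mixed fit; `freeze_beta`
reproduces the alternative two-stage reading where the LUR coefficients
are taken as-is and only variances are estimated. Known variance
components can also be plugged in (`fix_variance_components`), which is
useful for studying shrinkage limits. An optional `facade_adjust`
multiplier (e.g. 0.8) scales final maps from on-road toward facade level;
off by default.

Degenerate inputs: a fit needs at least two segments with ≥ 2 passes,
otherwise σ²_e is unidentifiable and fitting raises. If all residuals are
numerically zero (noise-free data) the fit short-circuits to λ = 0 with a
note instead of chasing an unbounded likelihood.

**Validation.** External points match to the nearest segment within 20 m
(the conventional co-location radius for street-level comparisons).
Metrics: Spearman with average ranks on ties, RMSE, mean bias, mean
relative bias (denominator: mean of the external values over matched
pairs), Bland–Altman mean difference, 1.96·sd limits of agreement, and
the slope of difference vs. average. Mean bias is `mean(test − ref)` —
positive means the map sits above the external data — and the convention
string is embedded in every report, since the opposite sign convention is
also in circulation. Quartiles use linear interpolation (type 7).

## Synthetic campaign generator

The generator is the package's test bench and defines the conditions the
test battery runs under. It emulates:

- a connected grid street network cut into exact 50 m segments, with
  street-level road classes (20% major) driving lognormal traffic
  intensities, a decayed major-road proximity load, a smooth population
  field and a port-area indicator — each covariate with a declared
  positive expected sign;
- a truth surface `C_i = x_i'β_true + u_i`, `u_i ~ N(0, σ²_b)` with
  defaults σ²_b = 16 (µg/m³)², redrawing any u that would make C_i ≤ 0,
  over an urban background of 25 µg/m³;
- city-wide drift `d(t)`: a rush-hour-shaped hour-of-day profile (sd
  6 µg/m³), a Mon–Sun weekday pattern (scale 1 µg/m³) and AR(1)
  day-to-day effects (sd 2.5, ρ = 0.6), demeaned to exactly zero over the
  campaign's hourly grid; piecewise-constant per hour;
- a reference station observing `30 + d(t) + N(0, 2²)` hourly around the
  clock for the 180-day campaign;
- drive-passes: `K_i ~ 1 + Poisson(6)` distinct weekdays per segment,
  start times uniform in 08:00–22:00, durations from a discretised
  *two-piece* lognormal hitting median 8 s and quartiles (3, 10) s exactly
  (a single lognormal cannot: its quartiles are geometrically symmetric
  about the median); 1 Hz records along the segment with value
  `C_i + d(t) + ε`, where ε has sd √(σ²_e·s) for a pass of s seconds so
  that every pass *mean* has variance σ²_e = 25 regardless of duration —
  matching the observation unit of the mixed model;
- 0.1% gross outliers, uniform on [−20, 600], to exercise the filter.

What it does **not** emulate: realistic road topology, traffic dynamics,
chemistry (NO/O₃ titration), meteorology, GPS error (records lie exactly
on their segment, so snapping is exercised for correctness, not
robustness), instrument drift between cars, and spatial correlation of
the segment deviations u_i. Passing tests therefore demonstrate the
statistical machinery under the stated model, not robustness to every
pathology of real traces. Two deliberate imperfections keep the test
honest: the weekday/weekend × hour correction cannot see the AR(1) day
effects or the Mon–Fri differences, so corrected data retain realistic
residual temporal error (this is why fitted σ²_e on default campaigns
exceeds the generator's 25); and Gaussian record noise occasionally dips
below 0 µg/m³ where the plausibility filter censors it, a small upward
bias at the noisiest, cleanest-air segments (~2% of records at defaults).

## Numerical choices

- REML optimisation: bounded Brent on log λ with explicit λ = 0 boundary
  check; degenerate zero-residual fits short-circuit.
- Within-segment sums of squares via the `Σy² − n ȳ²` identity, clipped
  at 0 against cancellation.
- OLS by `lstsq`, rank checked first; collinear columns are named in the
  error.
- Tie-breaks (snapping, matching) by smallest segment id on exact float
  distance equality.
- Quantiles: linear interpolation; Spearman: average ranks; SEM: ddof = 1.

## Problem sizes in the test battery

The test battery runs campaign replicates at 5000 segments (50 seeds) for
the map-ordering checks, 2000 segments (20 seeds) for variance-component
recovery, 600 segments (20 seeds, measurement noise off) for
temporal-correction efficacy — the drift scale there is set by an exact
linear rescale from one pilot run so the uncorrected segment bias is
~3 µg/m³, isolating what the correction can and cannot remove — and small
(≤ 50 segment) instances for oracle equivalence against a dense-matrix
restricted-likelihood maximiser and against statsmodels' MixedLM.

## Known limitations

- In-sample fit quality only: the LUR reports no cross-validated R².
- Random effects are independent across segments; no spatial smoothing
  (kriging/CAR) of the BLUPs.
- The two-stage design (stepwise selection, then mixed fit) ignores
  selection uncertainty in the fixed-effect set.
- Nearest-segment snapping without trajectory context can mis-assign
  points near intersections if supplied real GPS traces with large error.
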