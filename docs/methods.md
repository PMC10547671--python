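# Methods

## The measurement model

A dynamic CTmax assay warms a water bath containing up to 10 vials, each
with one individual, while an observer repeatedly checks the vials for
responsiveness. The observer records, for each individual, the clock time
at which it was first seen unresponsive and how many vials were still in
the bath. Because a check takes a roughly constant time `c` (~5 s), the
time since the individual was last seen responsive is the number of vials
spanning its final inter-check gap times `c`. The package treats the
recorded stop time as a hard upper bound — it is the *latest* moment the
individual could have reached its CTmax — and the window extends strictly
backward by `m·c` seconds, clamped at ramp start.

CTmax is the unweighted mean over the three bath sensors of the
time-weighted mean temperature over that window. Between logger samples
the trace is interpolated linearly; the integral of the piecewise-linear
interpolant is evaluated exactly (trapezoids over the knots inside the
window plus interpolated endpoints), so no quadrature tolerance is
involved. A zero-length window (the continuity limit, e.g. fully clamped)
returns the interpolated temperature at the stop time. Sensor disagreement
is never down-weighted; a `sensor_spread` field (max − min of the three
per-sensor means) is carried for quality control only. A missing sensor is
an error rather than a silent two-sensor fallback.

Why this is approximately unbiased: given the gap `[t_stop − m·c, t_stop]`,
the true crossing time is (a priori) uniform over the gap because the check
schedule is independent of the individual's latent CTmax, and over a ≤50 s
window a ramp at ≤0.3 °C/min is linear to well under 0.01 °C. The window
mean therefore equals the expected temperature at the crossing time. The
residual per-individual error is bounded by (max ramp rate × window
duration) plus sensor noise; simulations here measure a mean absolute
error of ~0.03 °C under default conditions.

## Effect sizes

Treatment effects are raw mean differences in °C (group b minus group a;
negative = b lower), with non-parametric bootstrap CIs: both groups are
resampled independently with replacement at their own sizes and the mean
difference recomputed per iterate.

* Default interval: BCa (bias-corrected and accelerated), 5000 resamples,
  95 % level. The bias correction `z0` uses the mid-p fraction of bootstrap
  iterates below the observed statistic; the acceleration is the standard
  jackknife skewness over delete-one influence values of both groups.
  Degenerate cases (zero-variance groups, all iterates tied) fall back to
  the percentile interval with a logged warning.
* Percentile intervals use linear-interpolation empirical quantiles. When
  both groups are small enough that the full resample space
  `n_a^n_a · n_b^n_b` has at most 4096 points (i.e. up to 3 vs 3), the
  percentile interval is computed from the exhaustive enumeration of all
  equally likely resample pairs — exact endpoints, no Monte Carlo noise.
  This exhaustive path doubles as an oracle for the Monte Carlo path in
  the test suite, alongside an independent cross-check against
  `scipy.stats.bootstrap`.
* Two contrast schemes: `vs_baseline` (each of fed and starved against the
  pooled day-0 baseline, per day) and `fed_vs_starved` (per day).
  Replicates are pooled within day × treatment by default; stratified
  within-replicate resampling is available behind a flag. Days missing a
  group (e.g. after a terminated replicate when no other replicate covers
  the day) are skipped with a logged notice. No multiple-testing
  adjustment is applied across days: the output is per-day estimation CIs,
  not a family of hypothesis tests.
* Per-contrast seeds are spawned deterministically from one top-level seed
  (`numpy` SeedSequence, truncated to 31 bits), so a rerun reproduces every
  interval bit for bit.

## Size regressions

Ordinary least squares of CTmax on body size within each day × treatment
cell (scipy's `linregress`), with the usual homoskedastic two-sided t-test
on the slope. Cells with fewer than 3 usable records are flagged unfit and
report no p-value. Body-size units are carried opaquely ("size units");
individuals without a size (an unphotographed replicate) are dropped from
regression with a logged count but retained for effect sizes. The unbiased
sample variance of CTmax per cell is reported alongside (undefined for
n < 2).

## The synthetic-trial generator

The generator is the package's stand-in for a real data deposit and defines
the study conditions the tests probe.

* **Ramp physics.** The noiseless bath path solves
  `dT/dt = r − k (T − T0)` with `T0 = 18 °C`, `r = 0.3 °C/min`,
  `k = 0.008 /min` — the simplest model of a fixed-output heater with
  Newtonian losses, giving the observed deceleration. Over the working
  range (up to ≈38 °C) every per-minute average rate stays inside the
  0.1–0.3 °C/min target envelope: the first minute averages ≈0.299 and the
  rate at a 19.5 °C rise is ≈0.14 °C/min. Three sensors log every 5 s with
  fixed offsets (−0.1, 0, +0.1 °C) and Gaussian read noise (SD 0.05 °C).
* **Deaths and detection.** An individual dies when the *noiseless* mean
  path reaches its latent true CTmax (vials are assumed equilibrated with
  the bath). The observer is a fixed round-robin: `check_seconds` per vial
  over the vials still in the bath; an individual is scored at the first
  check ending strictly after its death time, and the recorded
  `vials_remaining` is the vial count at its previous check (itself
  included). That bookkeeping makes the `m·c` window rule exact by
  construction — the window always contains the true death time, with the
  detection lag equal to the full window achievable in the limit of a death
  just after a check.
* **Design.** Five replicates; per replicate a 10-vial fed baseline assay
  (day 0), then one 10-vial assay per day for 5 days drawing 5 fed and 5
  starved individuals without replacement from six holding groups (3 fed,
  3 starved, 15 each), vial order randomised, both treatments sharing one
  bath. True CTmax: fed and baseline `N(35.0, 0.7²) °C` (a documented
  placeholder level); starved on day d shifted by {0, 0, −1, −3, −5} °C
  with SD multiplied by {1, 1, 1.5, 2, 3} — the phenomenological effect
  trajectory and variance inflation the analysis is meant to recover, with
  no energetic mechanism modelled. Exclusion for abnormal pre-ramp
  behaviour with probability 0.06 per individual (matching a raw excluded
  fraction of ≈16/270). Optional per-replicate early termination (total
  starved mortality) and an unphotographed replicate whose body sizes are
  withheld from the trial sheet. An optional per-day size–CTmax slope can
  be injected into the starved group (default 0) for calibration studies.
* **Determinism.** The experiment is a pure function of the config,
  including its seed; identical configs produce byte-identical CSV file
  sets.

What the generator does **not** emulate: thermal lag between reservoir and
vials, sensor drift or dropout, observer misses or mis-scoring,
behaviour-based death criteria, within-group correlation beyond the
replicate structure, and any physiological model of starvation. Passing
tests therefore validate the estimation and statistical machinery under an
idealised but observation-limited data-generating process, not the field
validity of the assay itself.

## Problem sizes and numerical choices

* Parameter-recovery and trajectory checks run the full pipeline at 40
  replicates when 200 individuals per group per day are wanted (each daily
  assay keeps the realistic 10-vial geometry; a single 400-vial bath would
  outrun the observer and is not a meaningful condition). At that size the
  day-5 contrast still carries a sampling SE of ≈0.16 °C from the 3×
  starved SD inflation.
* Coverage calibration draws group samples directly from the generator's
  normal truth (500 experiments, n = 24 per group, percentile CIs at 1000
  resamples); null-scenario fidelity runs 200 complete
  simulate→estimate→contrast pipelines at 4 replicates × 1 day.
* Quantiles: linear interpolation (`numpy.quantile` default) everywhere,
  including the exhaustive path, so the two bootstrap modes agree in the
  limit.
* Windows clamped at ramp start keep their nominal duration (`m·c`) for
  audit but integrate only over the realised `[0, t_stop]` span.
* Ties in resampling need no special handling; duplicate values are
  resampled like any other.

## Known limitations

* BCa intervals are undefined for zero-variance groups; the fallback is
  percentile, which collapses to a point interval there.
* The exhaustive bootstrap mode is only engaged up to 3-vs-3 groups; above
  that the percentile endpoints carry Monte Carlo noise of order
  `1/sqrt(n_boot)`.
* The uncertainty-window rule assumes the observer's check cost is
  constant; variable check times would widen true windows unpredictably.
* CTmax levels, SDs and the effect trajectory are scenario parameters, not
  estimates from any real dataset; conclusions about real copepods require
  real files in the same CSV dialects.
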