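# Methods and design notes

This note documents the models implemented in `sertflow`, the defaults and
why they were chosen, the numerical decisions, what the synthetic generator
does and does not emulate, and the package's known limitations. It makes no
empirical claims beyond what the test suite and `scripts/acceptance.py`
compute.

## 1. Signal model

A photometry session is modeled as

```
F(t) = B(t) · (1 + s(t)) + ε(t)
```

- `B(t) = b0 · (a1·e^(−t/τ1) + a2·e^(−t/τ2))` — double-exponential
  photobleaching. Defaults `b0 = 200` (arbitrary fluorescence units),
  `a1 = 0.6, τ1 = 600 s, a2 = 0.4, τ2 = 3000 s`, so the baseline starts at
  `b0` and decays on a fast and a slow time scale, both long relative to a
  transient (≥ 10× the kernel width) so the baseline is locally flat across a
  peri-event window.
- `s(t)` — fractional ΔF/F signal: a sum of event transients plus optional
  zone-dependent tonic offsets. Each transient is an alpha kernel
  `k(τ) = (τ/τ_r)·e^(1−τ/τ_r)` (τ ≥ 0), peak exactly 1 at `τ = τ_r`, rise
  time `τ_r = 1 s` by default — a smooth, causal, single-parameter stand-in
  for a sensor transient. An event of amplitude `A` therefore peaks at
  exactly `A` in fractional units.
- `ε(t)` — i.i.d. Gaussian measurement noise, default SD 2.0 (1% of `b0`).

## 2. Detrending and z-scoring

`detrend_array` fits `c + a1·e^(−t/τ1) + a2·e^(−t/τ2)` by **variable
projection**: only `(log τ1, log τ2)` are optimized (`scipy.optimize.
least_squares`, trf, bounds `[1e−2 s, 1e4·span]`, start `(span/5, span)`,
≤ 200 function evaluations); the linear coefficients are solved by
`numpy.linalg.lstsq` at every step. Log-parameterization enforces positivity;
eliminating the linear parameters makes the 2-D problem fast (milliseconds)
and exact on pure double-exponentials. On failure or non-finite output the
function falls back to a linear detrend and sets `fallback=True`. A fit is
refused below 60 s of data (`MIN_DETREND_SPAN`): two exponentials are not
identifiable on a shorter record.

Z-scoring uses the population (n-denominator) SD, so `mean(z) = 0` and
`SD(z) = 1` exactly; a zero-variance trace raises rather than dividing by
zero. An optional static control channel can be regressed out first
(ordinary least squares) for rigs that co-record a serotonin-insensitive
fluorophore.

**Identifiability.** Z-scoring divides by the session SD, so the recovered
bout score is the true amplitude *rescaled by the session's own
variability*: absolute fractional amplitudes are not identifiable from a
z-scored trace. The generator therefore ships `expected_bout_scores`, which
z-scores the noiseless residual `B(t)·s(t)` and applies the identical
peri-event normalization — an exact oracle for recovery tests. In the
deterministic limit (flat baseline, no detrend) recovery is exact to machine
precision; through the detrend path it agrees within ~0.5% (tested at 2%).

## 3. Events and peri-event quantification

Bout hygiene is merge-then-filter: annotations whose gap is strictly less
than `merge_gap` are merged, then bouts shorter than `min_duration` are
dropped. The study convention is `min_duration = 1 s`. Event clocks can be
aligned to the photometry clock with an offset and linear drift; events that
fall entirely outside the record are dropped and counted.

`extract_peri_event` locks each window to the nearest sample of the event
anchor, takes `[−pre, +post)` (defaults 5 s / 10 s), and subtracts the mean
over the baseline window (default (−5, 0) s). The **bout score** is the mean
over the response window (default (0, 5) s) — a mean rather than a peak
because it is unbiased under symmetric noise, whereas a max is inflated by
noise. Aversive stimuli are anchored at stimulus end (scruff) or onset
(splash) with a (0, 60) s response and (−60, 0) s baseline, matching
minute-scale responses.

## 4. Arena geometry and spatial analysis

Arenas are exact `shapely` partitions, checked to 1e−6 cm²:

- **OFT** 50 × 50 cm: four 12.5 cm corner squares, a 25 cm center square,
  and the remaining edge band.
- **EPM** 76 × 76 cm, arm width 7 cm: open arms along x, closed along y, a
  7 × 7 center square.
- **Two-chamber place preference** 52 × 26 cm: two halves.

Zone assignment resolves boundary ties by anxiogenic priority (OFT:
center > edge > corner; EPM: open > center > closed) so a boundary sample is
never assigned to the safer zone. Samples up to 0.5 cm outside the floor
(tracking jitter) snap to the nearest zone; farther is an error. Occupancy
and signal maps are 2-D histograms; empty bins are NaN, and total occupancy
is conserved across every spatial output.

**Track simulator.** A Gaussian random-walk proposal (step SD 8 cm/√s,
optional mean reversion, default 0) with rejection of proposals outside the
floor and Metropolis acceptance `min(1, w'/w)` on zone-weight changes. This
is a deliberate design choice over a literal reflected Ornstein–Uhlenbeck
process: the Metropolis construction makes the stationary occupancy exactly
proportional to `weight × area`, which gives a closed-form oracle for
occupancy tests. Zone lookup during simulation uses a 0.25 cm rasterized
grid for speed.

## 5. Action selection

Explore (center→open) and retreat (open→center) transitions are detected by
run-length encoding of the zone series with a minimum commitment of 1 s on
both sides; an open run at session start may end in a retreat without a
preceding explore. The generator draws actions from a per-sample hazard
`P = logistic(β0 + β1·z)` evaluated only in the eligible zone (center for
explore, open for retreat).

`conditional_event_probability` estimates `P(≥ 1 event in (t, t + horizon])`
as a function of the serotonin level `z(t)`: eligible samples are subsampled
to 1 Hz, binned into quantile bins of `z` (default quintiles), and the
fraction of bin members followed by an event within the horizon (default
10 s) is reported. Because consecutive 10 s horizons at 1 Hz overlap, the
effective sample size is reduced; validation compares against the exact
discrete survival probability `1 − exp(Σ log(1 − p))` with a binomial CI
widened by the design effect `horizon × subsample rate = 10`.

## 6. Statistics

- **Welch t** with the Welch–Satterthwaite df, computed in closed form
  (identical inputs give t = 0, p = 1 rather than NaN).
- **Pearson correlation** via `scipy.stats`.
- **Šidák correction**: `α′ = 1 − (1 − α)^(1/m)`; adjusted p-values
  `1 − (1 − p)^m`, capped at 1. Šidák is the package default for post-hoc
  families (slightly more powerful than Bonferroni, exact under
  independence).
- **Mixed (split-plot) ANOVA** for designs with between-subject factors
  (group, sex) and one repeated within-subject factor (week). The
  between stratum is a factorial ANOVA on per-subject means (statsmodels
  OLS, type-2 sums of squares; subjects-within-groups error). The within
  stratum is computed by explicit sequential residual-sum-of-squares drops
  over dummy design blocks `[subject] → [+week] → [+week×group cells]` via
  `numpy.linalg.lstsq`, with analytic numerator df `Π(levels − 1)` and the
  subject × within interaction as the error term. This in-house stratum
  exists because generic OLS ANOVA tables mis-assign df for interaction
  columns collinear with the subject dummies; the implementation is
  validated exactly against `pingouin.mixed_anova` and a brute-force
  sum-of-squares oracle, and is null-calibrated (rejection rate 0.05 ± 0.02
  at α = 0.05 in simulation). Subjects with incomplete week coverage are
  excluded and reported; sphericity is assumed (no correction), which the
  result metadata states explicitly.

## 7. Intake and schedule

`consumed_ml = max(pre − post − drip, 0)` (bottle weights in ml of fluid);
dose in g/kg is `consumed_ml × 0.20 × 0.789 / (mass_g / 1000)` — 20% (v/v)
ethanol at 0.789 g/ml. Negative consumption (bottle refilled or mis-logged)
and drip overshoot are clipped to zero and flagged (`refill`,
`drip_clipped`). The weekly schedule audit expects 2, 2, 2, 4 h sessions
with alternating bottle sides. Worked example: pre 10.0, post 8.7, drip 0.2,
25 g body mass → 1.1 ml → 6.9432 g/kg.

## 8. Tracing quantification

Images are background-subtracted with a global low-percentile constant
(default 10th percentile; deterministic) or an optional rolling-ball
estimate. ROI intensity is the mean over a polygon mask
(`skimage.draw.polygon2mask`). Replicate images are averaged within subject
before any normalization; values are expressed as percent of the
within-region maximum (the maximum is forced to exactly 100.0 to guard
against float-division residue). Dominance per region (MRN vs DRN input) is
a Welch test with a Šidák family correction over the number of regions; a
non-significant region is "Mixed", and fewer than 2 subjects per source
yields "Mixed" with a `low_n` flag. With the typical n = 3 per source, power
is very low and the null call rate is far below the corrected α — the
classifier is conservative by construction.

## 9. Synthetic cohort defaults

The default `CohortDesign` mirrors a realistic binge-drinking photometry
study: cells `male:water = 10, male:DID = 10, female:water = 9,
female:DID = 10`; weeks 0, 1, 4; 30 Hz; 600 s sessions; per-subject gain SD
0.15. Default transient amplitudes (fractional): ACC — alcohol −0.8,
sucrose −0.8, high-fat −0.6, splash +1.0, scruff +1.0; CeA — +0.8, +0.8,
+0.6, +0.2, +1.0. EPM tonic offsets open/center/closed = 0.8/0.4/0;
OFT center/edge/corner = 0.5/0.2/0. Injected effects: a +0.5 shift of the
ACC alcohol amplitude at week 1 in the DID group (both sexes) and a +0.4
CeA shift in DID males — i.e. drinking history blunts the responses.
Per-subject, per-session seeds derive from the master seed via CRC32 of the
session key, so cohorts are reproducible across processes.

**What the generator does not emulate:** motion artifacts, hemodynamic
contamination, an isosbestic channel (only an optional static control),
sensor kinetics beyond the alpha kernel, inter-trial amplitude variability
within a session, circadian structure, or missing-data patterns other than
whole-session absence.

## 10. Numerical and reproducibility choices

- All randomness flows through `numpy.random.default_rng` with explicit
  (list-)seeds; derived seeds stay below 2³¹.
- CSV round trips use pandas `float_precision="round_trip"` so written and
  re-read tables are bit-identical.
- Event intervals are half-open `[start, stop)`; window extraction is
  `[−pre, +post)` at the nearest sample.
- Pipeline outputs include a manifest with the seed, package version, the
  echoed design, stage list, and a SHA-256 of the configuration; reruns with
  the same seed are byte-identical.
- Problem sizes in the test suite and acceptance script (e.g. a 5/5/5/5,
  two-week, consummatory-only cohort for the power check; 30–100 seeds for
  direction checks; 400–2000 replicates for null calibrations) are the
  package's own validation choices, sized to finish in minutes on one CPU.

## 11. Open design decisions and limitations

- The analysis API is a set of plain functions over typed containers, not
  fit/predict estimators: every stage is a deterministic transformation with
  no learned state, so an estimator interface would add ceremony without
  reuse.
- Bout scores are window means; peak-based scores are not offered.
- The mixed ANOVA supports exactly one within-subject factor (week), which
  covers the intended designs; multiple within factors raise.
- Sphericity is assumed (no Greenhouse–Geisser correction); with three
  within levels and null-calibrated simulations this was judged acceptable,
  but it is a limitation for strongly autocorrelated repeated measures.
- The conditional action-probability estimator uses fixed 1 Hz subsampling
  and quantile bins; it is an estimator of a marginal conditional
  probability, not a hazard-model fit.
- Dominance classification with n = 3 per source is intentionally
  conservative; it will rarely call dominance even for real differences.
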