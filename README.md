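# sertflow

Analysis toolkit for fiber-photometry studies of serotonin dynamics during
motivated behavior, with a matched synthetic-data generator for validation.

## Scientific problem

Genetically encoded serotonin sensors (e.g. GRAB-5HT) report extracellular
serotonin as a fluorescence time series recorded through an optic fiber in a
target region such as the anterior cingulate cortex (ACC) or the central
amygdala (CeA). A typical study asks whether serotonin transients locked to
behavioral events — drinking bouts of alcohol or sucrose, entries into the
anxiogenic compartments of an elevated plus maze (EPM) or open field (OFT),
aversive stimuli — change after a history of binge-like alcohol drinking
(drinking-in-the-dark, DID), and whether the change differs by sex, region,
and time point (baseline, one week, four weeks of drinking).

Answering that requires a chain of steps, each with sharp edge cases:

1. **Signal processing** — remove the double-exponential photobleaching trend
   and z-score each session within itself (`sertflow.signal`).
2. **Event handling** — merge drinking-bout annotations separated by short
   gaps, discard bouts shorter than 1 s, align event clocks to the photometry
   clock (`sertflow.perievent`, `sertflow.io`).
3. **Peri-event quantification** — baseline-subtracted event-locked traces and
   a per-bout response score (`sertflow.perievent`).
4. **Spatial analysis** — exact arena geometries (OFT corner/edge/center, EPM
   open/closed/center, two-chamber place preference), zone assignment, zone-
   conditioned signal averages, occupancy maps (`sertflow.arenas`,
   `sertflow.spatial`).
5. **Action selection** — detect explore (center→open) and retreat
   (open→center) transitions on the EPM and estimate the probability of an
   imminent transition conditioned on the current serotonin level
   (`sertflow.actions`).
6. **Intake and histology** — bottle-weight drinking arithmetic in g/kg and
   anterograde-tracing quantification with dominance classification
   (`sertflow.intake`, `sertflow.tracing`).
7. **Statistics** — Welch tests, mixed (split-plot) ANOVA with
   between-subject factors (group, sex) and a repeated within-subject factor
   (week), and Šidák multiple-comparison correction (`sertflow.stats`).
8. **Pipeline** — a deterministic end-to-end run over a whole simulated
   cohort, writing tidy CSV tables and a manifest (`sertflow.pipeline`,
   `sertflow` CLI).

## Core model

The generator and the analysis share one signal model:

```
F(t) = B(t) · (1 + s(t)) + ε(t)
B(t) = b0 · (a1 · exp(−t/τ1) + a2 · exp(−t/τ2))        (photobleaching)
s(t) = Σ_events  A_label · k(t − t_start)               (fractional ΔF/F)
k(τ)  = (τ/τ_r) · exp(1 − τ/τ_r),  τ ≥ 0               (alpha kernel, peak 1)
```

`A_label` is the true fractional transient amplitude of an event type; `ε` is
white measurement noise. Analysis recovers a z-scored trace (detrend, then
z-score with the population SD), extracts windows around each event, subtracts
the pre-event baseline mean, and scores each bout as the mean over a response
window. Because z-scoring divides by the session SD, recovered scores live on
the session z-scale, not the fractional scale; the generator exposes
`expected_bout_scores` which applies the identical normalization to the
noiseless signal, giving an exact oracle for recovery tests.

The synthetic cohort defaults mirror a realistic study design: four
sex × group cells (10/10/10/9 subjects), weeks 0/1/4, 30 Hz photometry,
a 2-2-2-4 h weekly DID schedule with 20% (v/v) ethanol, and injected week-1
group effects.

## Worked example

```python
import numpy as np
from sertflow.synth import GroundTruth, Bleach, simulate_photometry
from sertflow.signal import zscore_session
from sertflow.perievent import extract_peri_event, filter_bouts, session_mean_bout_score
from sertflow.types import EventLog

# ground truth: an aversive tastant suppresses ACC serotonin by 0.8 (fractional)
truth = GroundTruth(amplitudes={"alcohol": -0.8}, noise_sd=2.0,
                    bleach=Bleach(), seed=42)
raw_bouts = EventLog([("alcohol", 60.0, 63.5), ("alcohol", 63.8, 66.0),
                      ("alcohol", 150.0, 150.4), ("alcohol", 240.0, 246.0)])
session = simulate_photometry(truth, raw_bouts, duration=300.0, fs=30.0)

# bout hygiene: merge gaps < 0.5 s, keep bouts >= 1 s
bouts = filter_bouts(raw_bouts, min_duration=1.0, merge_gap=0.5)
print("bouts kept:", bouts.events)

z = zscore_session(session, detrend_first=True)
m = extract_peri_event(z, bouts, "alcohol")
print("per-bout scores:", np.round(m.bout_scores, 3))
print("session mean bout score: %.3f" % session_mean_bout_score(m))
```

prints

```
bouts kept: [('alcohol', 60.0, 66.0), ('alcohol', 240.0, 246.0)]
per-bout scores: [-4.786 -2.952]
session mean bout score: -3.869
```

The two sub-1 s/merged annotations collapse to two valid bouts, and both carry
the injected suppression. The scores are on the session z-scale (their
magnitude depends on within-session variability), which is why cross-session
comparisons always use within-session z-scores — see `docs/methods.md`.

Drinking arithmetic:

```python
from sertflow.intake import DrinkingRecord, session_intake
res = session_intake(DrinkingRecord(subject_id="m01", pre=10.0, post=8.7,
                                    drip=0.2, body_mass=25.0))
print("intake: %.2f ml -> %.4f g/kg" % (res.consumed_ml, res.g_per_kg))
# intake: 1.10 ml -> 6.9432 g/kg
```

A whole-cohort run, from the command line:

```bash
sertflow run --seed 7 --out results/study   # or: python -m sertflow.cli ...
```

writes `bout_scores.csv`, `bout_score_stats.csv`, `epm_zone_signal.csv`,
`epm_initiation.csv`, `epm_conditional.csv`, `aversive_responses.csv`,
`intake.csv`, `intake_weekly.csv`, `tracing_normalized.csv`,
`tracing_dominance.csv`, `recovery_report.csv` and `manifest.yaml`. Reruns
with the same seed are byte-identical.

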