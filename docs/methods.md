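# Methods

## The task and the staircase

The package models a yes/no echo-detection experiment: a listener hears a
short click and judges whether a disk in front of them reflected it.  The
disk rides a motorized rail and can be face-on ("reflecting") or edge-on
("non-reflecting", presented with probability `1 - p_reflect = 0.5` per
trial, independently).  Difficulty is controlled by disk distance, between
0.7 and 3.9 m on a 5 mm positioning grid.

Distance is driven by a single-interval adjustment matrix (SIAM) staircase.
Each trial is classified by crossing the disk state with the response —
hit, miss, correct rejection, false alarm — and the distance for the next
trial changes by

| outcome            | step    |
|--------------------|---------|
| hit                | +0.25 m |
| miss               | −0.25 m |
| correct rejection  | 0       |
| false alarm        | −0.50 m |

A session stops at the 12th reversal of the movement direction; the
threshold estimate is the arithmetic mean of the distances at the last 10
reversals.  A 500-trial safety cap guards degenerate responders (typical
sessions run 20–80 trials); capped sessions are flagged and averaged over
whatever reversals exist.

### Conventions the stop/estimate rules do not pin down

* **Start distance.** Sessions start at 0.7 m (training in such experiments
  happens at the closest distance).  The reversal-trimmed estimator
  discards only the first two reversals, so a session that starts far from
  its equilibrium keeps some transient reversals; see *Parameter recovery*
  below for the measured consequence.
* **Zero steps.** Correct rejections move nothing and are transparent to
  reversal detection: they neither set nor clear the remembered direction.
* **Rail bounds.** Steps that would exit the rail are clipped to the bound,
  and a clipped step still counts toward direction with its intended sign —
  otherwise a responder pinned at 0.7 m could never reverse and sessions
  would never end.
* **Which distance a reversal records.** Two readings are defensible: the
  distance presented on the direction-changing trial (`"pre_step"`, the
  excursion's extremum) or the distance the staircase then moves to
  (`"post_step"`).  The default is `post_step`: under a 10,000-participant
  random-responder simulation it reproduces all four published chance-band
  endpoints for this staircase (12-session means 0.88–0.98 m, single
  sessions 0.8–1.2 m) within ±0.03 m, while `pre_step` overshoots the
  single-session upper endpoint by ~0.08 m.  Both are available via
  `StaircaseConfig.reversal_distance`.

## Observers

`RandomObserver(p_yes)` answers "yes" with fixed probability, blind to the
stimulus — the chance-level reference.  `SDTObserver` is an equal-variance
Gaussian signal-detection observer with criterion `c` and a
distance-dependent sensitivity

    d'(x) = max(0, d'_ref − decay · (x − x_ref)),

so that p(yes | reflecting) = Φ(d'/2 − c) and p(yes | non-reflecting) =
Φ(−d'/2 − c).  The linear decay floored at zero is a transparency choice,
not a fitted psychometric shape (no human psychometric-function data inform
it); any alternative can be supplied as `dprime_fn`.  For an unbiased
observer the proportion correct at sensitivity d' is Φ(d'/2): 69% at
d' = 1.0.

## What the staircase actually targets

The step matrix above is the t = 0.5 SIAM variant.  Its expected step
vanishes where the hit rate exceeds the false-alarm rate by 0.5, which for
an unbiased equal-variance observer means d' = 2 z(0.75) ≈ 1.349 (75%
correct) — not the d' = 1.0 / 69%-correct level the t = 0.5 matrix is often
loosely described as targeting (for d' = 1 the maximum attainable H − F is
2Φ(0.5) − 1 ≈ 0.38, so the balance point cannot sit there).
`calibration.equilibrium_dprime()` solves the balance equation for any step
configuration, disk prior, and criterion.

### Parameter recovery

For an observer with a steep sensitivity cliff the session thresholds
concentrate at the distance where d' crosses the equilibrium value (the
test suite verifies recovery within ±0.15 m for a 20/m decay).  For the
gentler reference observer d'(x) = 3 − 1.0·(x − 0.7), two effects displace
the recovered threshold from the d' = 1.0 crossing at 2.7 m:

1. the procedure equilibrates at d' ≈ 1.349, i.e. at 2.35 m, 0.35 m closer;
2. sessions start at 0.7 m and climb for ~20 trials; reversals recorded
   during the climb sit below equilibrium, and with only the first two
   reversals discarded they drag the mean-of-last-10 down by a further
   ~0.3 m.  Measured: the mean of 200 sessions lands near 2.0 m.

Both effects are properties of the procedure as specified (its step matrix,
start rule, and estimator), not of the implementation; the corresponding
acceptance test, which expects the d' = 1.0 crossing within ±0.15 m, is
left failing by design.

## Monte-Carlo chance calibration

`calibrate_random_responder` simulates `n_reps` independent participants
(default 10,000, each 12 sessions) and reports central 95% intervals —
empirical quantiles with linear interpolation at the 2.5th/97.5th
percentiles — of both the pooled single-session thresholds and the
per-participant means.  Both distributions are retained so a "10,000 runs"
claim can be read either as sessions or as participants.  Each participant
draws from an independent `SeedSequence` spawn, so results are reproducible
and order-independent.

## Synthetic click acoustics

`synth` generates what a microphone at the listener position would record:

* **Click**: a raised-cosine-gated sinusoid, 3 ms at 3.5 kHz by default
  (within the 2–3 ms / 3–4 kHz class of synthetic echolocation clicks),
  48 kHz sampling.
* **Direct sound** at time zero, scaled so its 1-ms-windowed maximum SPL is
  `direct_level_db` = 76 dB under the batch calibration constant
  (SPL = 20 log₁₀(window RMS) + `calibration_db`).  The source and receiver
  never move, so this level is identical across distances.
* **Reflection** (reflecting trials only): the same click delayed by
  delay(d) = (2d − `geometry_offset`)/c and scaled so its isolated windowed
  maximum follows R(d) = 76 − 11·log₂(d / 1.2) dB.  The law is anchored by
  three facts of the emulated setup: the direct level, a crossover near
  1.2 m where the reflection is as loud as the (backward-radiated) direct
  click, and an ~11 dB drop per doubling of distance.  At 3.9 m it gives
  ≈ 57.3 dB and a reflected-to-direct ratio of ≈ −18.7 dB.  An optional
  per-recording `level_jitter_db` emulates the less systematic behaviour of
  real rooms beyond ~2 m; it defaults off.
* **Room tail**: exponentially decaying white noise excited by the direct
  click, 60 dB down per `reverb_time_s` = 0.07 s, present in both disk
  states.  Its onset level (default 50 dB) is chosen so that the tail
  neither perturbs the direct-click window by more than a few tenths of a
  dB nor competes with the weakest reflection (≈ 10 dB margin at 3.9 m).
  Real rooms of this class can carry a higher late decay; raise
  `tail_onset_level_db` to study that regime — at ≳ 57 dB the tail starts
  to win the reflected window at the farthest distances, which is precisely
  the detection problem the real task poses.
* **Noise floor**: stationary Gaussian noise at 15 dB.

Reflecting and non-reflecting recordings of the same replicate share one
seed, so their sample-wise difference isolates the reflection component
exactly — the synthetic analogue of the subtract-the-states visualization.

### Delay geometry

The pure two-way delay gives an ICI slope of 2/c ≈ 5.83 ms/m.  Measured
setups with the receiver just behind/above the source can show a shorter
ICI at the closest distances than 2d/c predicts; `geometry_offset_m`
(default 0) exposes, but does not resolve, that geometry.

## Windowed-SPL analysis

`analysis` mirrors the measurement pipeline: RMS levels over running
rectangular 1-ms windows; direct maximum in 0–3 ms; reflected maximum in
3–30 ms; ICI = time between the maxima; OLS fits of ICI vs distance
(full 0.7–3.9 m range) and reflected level vs log₂(distance) (0.7–2.0 m,
the range where the decay law is systematic).

* **Hop.** A stated window overlap of 0.998 ms implies a 2 µs hop —
  sub-sample at 48 kHz.  The implementation hops one sample (≈ 20.8 µs),
  the finest physically meaningful spacing; at the reported precision of
  ICI and level estimates the difference is nil.
* **Timestamps** are window starts; the convention cancels in the ICI.
  Ties in a window resolve to the earliest time.
* **Window anchoring** is to the emission onset, which is exactly time zero
  for synthetic recordings.  (For recordings of unknown onset, locate the
  first window exceeding the noise floor by 20 dB and shift.)
* **Replicate averaging** is done on dB values; with replicate spreads
  < 0.2 dB the difference from power-domain averaging is negligible.
* **Low-confidence flags.** When both disk states are present at a
  distance, a reflected maximum within 3 dB of the paired non-reflecting
  (tail-only) level is flagged: it may be the tail, not the reflection.

## What the synthetic data does and does not emulate

The generators reproduce the *structure* of the study conditions: outcome-
contingent distance dynamics, stimulus-blind and SDT responders, and
recordings with the correct delay/level laws, decay floor, and replicate
variability.  They do not emulate human listeners (no learning, lapses, or
criterion drift), a real click waveform or source directivity, or real room
acoustics (no image-source reflections, only a statistical tail).  Passing
tests therefore demonstrate that the procedure and pipeline measure what
they claim under known ground truth — not that any human would produce
particular thresholds.

## Problem sizes and numerics

Default problem sizes: 10,000 simulated participants × 12 sessions for the
chance bands (~15 s single-core), 200 sessions for parameter recovery, and
33 distances × 2 states × 10 replicates for the acoustic series.  Distances
are snapped to the 5 mm grid after every step; thresholds serialize at 3
decimals (exact on the grid).  WAVs are written as float32 with a JSON
sidecar carrying distance, state, and the calibration constant.
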