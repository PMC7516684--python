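# Methods

This note documents the models, rules and numerical choices behind
`gaitsole`, and what the synthetic validation does and does not show.

## Phase segmentation from plantar pressure

Each of the 8 pressure channels per foot is cleaned with a running
median (width 5 samples = 50 ms at 100 Hz; edge windows shrink to the
available samples).  A median was chosen over a low-pass filter because
insole pressure is an on/off-like signal whose step edges a median
preserves while still suppressing impulsive sensor noise.  A channel is
*activated* when its filtered value is at or above the activation
threshold (default 4.3 N/cm², inclusive).  Per frame, the count of
activated channels drives the phase rule: count 0 → swing, count > 0 →
stance.

Raw runs are then debounced: any run shorter than
`min_phase_duration_s` (default 60 ms) is absorbed into its
neighbours, shortest run first (ties to the earlier run).  60 ms is
shorter than any physiological swing or stance at TUG speeds but longer
than isolated sensor chatter.  The result is an alternating tiling of
the whole recording.

Bilateral support classification is an event sweep over the union of
both feet's phase boundaries: both-stance → double support, one-stance
→ single support (left/right), both-swing → `none`.  `none` frames are
physiologically impossible during walking; they are retained, counted
in the QC report, and excluded from support statistics.

## TUG sub-phases

The protocol does not mark sub-phases, so they are derived from the
summed bilateral filtered pressure:

* seated baseline = median over the first 1 s;
* standing plateau = median over double-support frames between the
  first and last real swing;
* sit-to-stand start = first crossing of baseline + 25 % of
  (plateau − baseline), sustained 0.3 s; sit-to-stand end = first
  sustained crossing of 90 % of the plateau;
* walking = first swing onset after sit-to-stand end → last stance
  onset; total TUG ends at the first sustained fall below the 25 %
  level after walking.

These fractions are operational definitions validated exclusively
against simulator ground truth; nothing anchors them to a published
convention.  Step count is the number of stance onsets of either foot
inside the walking window; cadence divides it by the walking time.

## Gait cycle, parameters and asymmetry

A gait cycle is anchored at stance onset (initial contact), the
standard convention: stance onset → next stance onset of the same foot.
Percentage ("pct") parameters are fractions of the **mean cycle
duration pooled over both feet of the trial** — a single reproducible
choice of the "corresponding gait cycle duration"; they are reported as
fractions (0.15, not 15 %).  Asymmetry metrics use the absolute
difference of per-side means; for controls the hemiplegic/sound slots
are filled by the right/left foot by declared convention, so diff
metrics remain |left − right|-based and relabeling flips the slots
without changing the differences.  Within-trial SDs are population SDs
(divide by n), since they describe the trial's own step-to-step
variability; `ddof` is configurable.

Walking speed defaults to the stride/cycle identity
(mean stride length ÷ mean cycle duration), which is self-contained
from insole data; `speed_mode="track"` instead uses
2 × track length ÷ walking time.  Stride length defaults to
ZUPT-corrected double integration of the gravity-free forward
acceleration axis: trapezoidal integration to velocity, zero-velocity
anchors at stance midpoints (plus the final heel strike), linear
detrending between anchors, and a second integration over each cycle.
Negative raw values are clamped to zero and QC-flagged.
`stride_mode="track"` assigns 2 × track length ÷ strides-per-leg
instead.  Orientation estimation from the raw IMU is explicitly out of
scope: the recordings are defined in a gravity-compensated foot frame.

## The simulator

The generator emulates the *structure* the analysis assumes, not the
full richness of hemiplegic gait.

**Timing.**  Walking is an alternating step sequence with a fixed
double-support overlap `d`: a foot lands `d` seconds before the other
lifts.  In steady gait this forces the identity
`stance(side) = swing(contralateral) + 2d`, so per-side stance and
swing cannot be chosen independently; `GaitConfig` accepts either and
derives the other (inconsistent pairs are a config error).  Per-step
swing durations are truncated-normal draws (floor 0.1 s).  Hemiplegic
gait uses a longer hemiplegic swing, which by the identity yields the
longer *sound*-side stance characteristic of stroke gait.  One
consequence: the generated stance and swing differences are equal in a
given trial, which real cohorts only approximate.  The turn is extra
stepping time (`turn_s`), not a distinct kinematic model.

**Default conditions.**  Controls: swing 0.40 s (SD 0.015), overlap
0.12 s → cycle 1.04 s, stride 0.91 m, speed ≈ 0.88 m/s, sit-to-stand
2.9 s.  Patients: sound swing 0.335 s, hemiplegic swing 0.605 s
(within-trial SDs 0.03/0.05), overlap 0.19 s → cycle 1.32 s,
stance difference 0.27 s, stride 0.40 m, speed ≈ 0.30 m/s,
sit-to-stand 4.0 s.  These echo the published ranges for chronic
hemiplegic versus healthy TUG performance; stride counts are set by
2 × 3 m track ÷ stride length.  Cohorts draw per-subject means around
these with between-subject SDs (e.g. 0.09 s on the hemiplegic swing),
and clinical scores follow `score = a + b · diff_stance_pct + ε` with
defaults a = 26.39, b = −38.64 (worse asymmetry → lower FMA
lower-extremity score) and σ chosen for a generating R² ≈ 0.6; scales
without a model are independent clinical-range draws.

**Pressure.**  Walking stance rolls heel → toe across three channel
zones at `pressure_peak` (20 N/cm²).  Swing frames carry folded-normal
noise (SD 0.5) whose per-channel tail probability of crossing 4.3 is
< 10⁻¹⁶; the config rejects SDs where that tail would exceed ~10⁻⁶.
Standing load is a fixed per-channel pattern whose bilateral sum equals
the walking double-support sum, so the plateau estimate is consistent.
The sit-to-stand ramp jumps to ~60 % of standing load at rise onset,
grows linearly to 89 %, and steps to 100 % at the true end; sitting
down descends to 55 % and unloads abruptly at seat contact.  These
near-discontinuities are deliberate: they make the generator's true
window endpoints coincide with the detector's threshold landmarks (a
25 %-crossing detector would lag a smooth 3 s ramp by ~0.75 s, which no
window tolerance could absorb) and keep every loaded channel clearly
above the activation threshold until seat contact, so unloading cannot
chatter around the threshold.

**Acceleration.**  Each swing's forward velocity is a sin⁴ bell whose
closed-form integral is the cycle's true stride length.  Velocity,
acceleration and jerk all vanish at the swing boundaries, so discrete
trapezoidal re-integration at 100 Hz reproduces the stride to ~10⁻⁶ m;
a half-sine velocity pulse was rejected because its boundary
acceleration discontinuity alone costs several percent at this rate.

**What passing tests do not show.**  The simulator has no
center-of-pressure dynamics beyond the three-zone rollover, no turning
kinematics, no walking aids, no sensor drift or dropout, and scores are
generated from exactly the linear model the statistics assume.  Green
tests therefore certify the measurement chain and statistics, not
performance on real insole data.

## Statistics

The group comparison is Welch's t by default (the pooled-variance
variant is available), two-sided throughout.  Correlations are Pearson
r with R² = r², the least-squares line of scale on parameter, and p
from t = r·√((n−2)/(1−r²)) on n−2 df.  The headline significance flag
is unadjusted at α = 0.05 — matching the uncorrected multiple-testing
posture of small pilot analyses — with Benjamini–Hochberg adjusted
flags carried as an extra honest column.  The outlier refit
unconditionally removes the point with the largest absolute internally
studentized residual and reports both R² values plus the excluded
index; it is a reporting device, not an outlier test.  Degenerate
inputs are handled explicitly: identical zero-variance samples give
t = 0, p = 1; zero-variance correlation inputs give NaN markers.

## Problem sizes and determinism

Validation runs use the study-scale sizes throughout: 10 + 10 subject
cohorts, 100 replicate cohorts for group-separation power, 200
replicates for correlation recovery, 1000 replicates for t-test
calibration, 50 trials for transition-detection recovery.  A single
simulated trial is 1.5–3 k frames and takes ~15 ms to simulate and
segment, so the full suite completes in about a minute.  All
randomness flows from `numpy.random.SeedSequence` seeds; the
simulate → extract → analyze chain is byte-identical for a fixed
(config, seed), and output CSVs carry a provenance header (tool
version, config hash, seed).

## Known limitations

* The double-support overlap is constant within a trial; real gait
  varies it step to step.
* The timing identity ties stance and swing asymmetries together
  (diff_stance = diff_swing in truth).
* TUG sub-phase rules are this package's operational definitions;
  absolute sub-phase times from other systems will differ by the
  stand-to-sit handling.
* Clinical scores are modelled as continuous; real instruments are
  integer-scored.
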