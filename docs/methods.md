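# Methods

`gymlanding` analyses landings in artistic gymnastics from two synchronised
wearable streams: six surface-EMG channels on the dominant lower limb
(native rates 1926 or 1111 Hz) and one six-channel inertial sensor at the
lower back (370.4 Hz; specific force in g on the medial–lateral,
anterior–posterior and vertical axes; angular velocity in deg/s about the
sagittal, frontal and transverse planes).  Trials are crossed over four
motor tasks — drop landing (DL), tucked somersault backward (SB), tucked
somersault forward (SF) and a backward acrobatic series (AS) — and two gaze
instructions (down, ahead), fully within subject, with 2–3 repetitions per
cell.

## Contact detection

An accelerometer in free fall reads a specific-force magnitude near zero.
Flight phases are therefore maximal runs with
`sqrt(a_ml^2 + a_ap^2 + a_v^2) < 0.3 g` lasting at least 80 ms, and contact
is the first local maximum of vertical acceleration exceeding 2 g within
200 ms after the end of the *last* flight phase (AS trials contain two
flights; the handspring contact between them must not be mistaken for the
landing).  The 0.3 g / 80 ms / 2 g / 200 ms constants are free parameters
of the detector with these defaults; the detection rule itself is fixed.

## Stabilisation indices

All six IMU channels are low-pass filtered (4th-order Butterworth, 30 Hz,
applied forward and backward for zero phase), windowed over 3 s and 1 s
after contact, and zeroed by subtracting the mean of the terminal quiet
tail (0.5 s for the 3-s window, 0.25 s for the 1-s window), so both indices
measure deviation from terminal quiet stance:

* **Dynamic stability index (DSI)** — the RMS of the zeroed segment,
  `sqrt(sum(x_i^2) / N)`, in the channel's units; smaller = more stable.
* **Time to stabilisation (TTS)** — sequential-average method: with
  `seq(k) = mean(x_1..x_k)` and threshold `T = 0.25 x SD(tail)`, TTS is the
  earliest time after which `|seq(k)| <= T` holds for every later sample.
  If the condition is never met the window length is returned and the value
  is flagged censored.

The default TTS variant (zero reference, quiet-tail threshold) follows the
zeroing step literally.  Because the cumulative average converges to the
*window mean*, channels whose zeroed window retains net area — notably the
vertical axis, where the impact transient has strictly positive area — are
frequently censored under this variant.  That is a property of the
definition, not a failure; censoring is logged per trial.  The classic
ground-reaction-force formulation (reference = whole-series mean, threshold
= 0.25 x whole-series SD, which always stabilises on decaying signals) is
available as `variant="series_mean"`, and `variant="unstable_last"` reports
the instant after the last threshold violation.

## EMG patterns

Fixed processing order: resample to 1000 Hz (polyphase, Kaiser beta 12, so
constants and envelopes pass with ~1e-7 ripple; 1111 to 1000 Hz is a
non-integer ratio, so interpolation rather than decimation) → 30–350 Hz
4th-order zero-phase Butterworth band-pass → full-wave rectification.
Quality control runs on the *raw* trace, since 3 mV is an electrode-level
physical bound: traces peaking above 3 mV, saturating (>= 50 consecutive
samples within 0.1% of the global extremum) or flatlining (>= 200 identical
consecutive samples) are excluded.  Kept traces are divided by the
participant's maximum processed amplitude over their AS trials (pooling
gaze conditions) inside the −300…+300 ms analysis window; a switch selects
the whole-trial maximum instead, as the amplitude reference is ambiguous in
principle.  Finally the normalised trace is integrated in thirty 20-ms
windows spanning −300…+300 ms around contact (rectangular rule, sample sum
x 1 ms; node 16 starts exactly at contact).  Patterns are non-negative with
units normalised·s.

## Statistics

**Scalar layer.**  Repetitions are averaged per subject x task x gaze cell
(standard for repeated-measures designs with unequal repetition counts);
imbalance is an error, never imputed.  The two-way fully within-subject
ANOVA tests each effect against its own effect-by-subject interaction:
`F_task = MS_task / MS_task:subj` (df 3, 3(n−1)), `F_gaze = MS_gaze /
MS_gaze:subj` (df 1, n−1), and likewise for the interaction.  The
decomposition is implemented directly (vectorised over arbitrary trailing
axes so the waveform layer can reuse it node-wise and permutation-wise) and
is verified in the tests against statsmodels' AnovaRM to 1e-8.  No
sphericity correction is applied by default; Greenhouse–Geisser is behind a
flag.  Significant effects get Bonferroni-adjusted paired t post hocs on
subject-level marginal means (6 task pairs, 1 gaze pair, 28 cell pairs for
the interaction; a simple-effects layout — task pairs within each gaze plus
the gaze pair within each task — is available for descriptive figures).
Normality is screened with a one-sample Kolmogorov–Smirnov statistic
against a normal with estimated mean and SD; because the parameters are
estimated, the p-value comes from a seeded 10^4-draw Monte-Carlo null
(Lilliefors correction), cached per sample size.

**Waveform layer.**  The same decomposition is applied at each of the 30
pattern nodes, giving F-curves for task, gaze and interaction.  Family-wise
inference across nodes uses within-subject permutation with the
max-statistic rather than random-field theory: gaze labels are flipped
independently per (subject, task); task labels are permuted independently
per (subject, gaze); for the interaction, estimated main effects are
subtracted and whole cells are permuted within subject (a restricted,
approximate scheme).  The critical value F* is the (1−alpha) quantile
(conservative "higher" order statistic) of the null distribution of the
curve maximum over 1000 permutations by default; clusters are maximal runs
of F > F*, each with p = the fraction of null maxima at or above its peak.
Exact enumeration of all gaze flips is available up to 2^14 patterns; with
fewer distinct permutations than 1/alpha the routine refuses.  At alpha = 1
the critical value is −infinity (every node trivially significant), a
degenerate but well-defined limit.

## Synthetic cohort

The generator reproduces the study design (18 x 4 x 2 x 2–3 by default)
with known ground truth.  IMU records are piecewise: quiet stance (vertical
~ 1 g; run-up bumps for SF), for AS an optional first flight plus
intermediate contact, a final flight at ~0 g, a half-sine vertical impact
transient, and a per-channel damped oscillation
`A e^(−t/tau) sin(2 pi f t + phi)` decaying into stance noise.  Key
modelling choices:

* The contact instant is defined at the transient apex, snapped onto the
  IMU sample grid, and the stance-weight ramp (0 → 1 g) completes exactly
  at the apex so the recorded vertical maximum coincides with the defined
  contact.  The free-fall span therefore ends half a transient width before
  contact — the transient terminates the flight.
* Defaults: transient duration 100 ms with peaks 3–4.5 g across tasks
  (sprung-floor magnitudes), oscillation 4 Hz with tau = 0.5 s, amplitudes
  0.35/0.5/1.2 g and 30–60 deg/s, accelerometer noise 0.01 g, gyro noise
  1 deg/s.  All deterministic spectral content sits well below the 30-Hz
  analysis low-pass, and the transient is long relative to the 2.7-ms
  sample spacing, so closed-form window energies (damped-sine integral in
  closed form plus A^2 d/4 for the transient half) remain valid references
  for the discrete filtered pipeline to within ~2%.
* Task and gaze "effects" enter as additive shifts of the oscillation
  amplitude multiplier (DSI is linear in amplitude); `gaze_effect = 0`, the
  default, reproduces the null-gaze regime.  A per-subject lognormal-ish
  amplitude multiplier (SD 0.10) induces between-subject variance.
* EMG channels are Gaussian carriers band-limited to 30–350 Hz at the
  native rate (so the processing band-pass is approximately transparent and
  envelope-level tests are isolated from filter effects), multiplied by
  envelopes with a smoothstep rise starting a task-dependent preactivation
  time before contact (80–150 ms; SF longest), a peak at contact, and a
  150-ms exponential decay.  AS carries the largest amplitude scale so the
  AS-max normalisation bounds the other tasks near 1.
* Randomness is drawn per (trial, stream) from
  `SeedSequence([master, hash(subject), task, gaze, rep, stream])`, so
  adding trials never perturbs existing ones and identical configurations
  are bit-identical on disk.

What the generator does **not** emulate: no musculoskeletal dynamics or
kinematic chain, no motion-artifact or powerline contamination in EMG, no
sensor drift or orientation change, no gaze behaviour.  Passing tests
demonstrate that the pipeline recovers known structure of this signal
model; they do not certify performance on vendor data with artefacts the QC
screen has never seen.

## Numerical and degenerate-input conventions

Zero-variance effects report F = 0, p = 1; a zero permutation threshold on
a nonzero signal returns the censoring sentinel with a warning; identical
paired samples report difference 0, p = 1; a zero-variance sample fails the
normality screen with a degenerate-sample error (the pipeline records it
and moves on — fully censored TTS outcomes produce exactly this).  Filters
require minimum lengths (3 x padding) and raise otherwise.  Write-then-read
round-trips are exact to better than 1e-9 (12 significant digits on disk).

## Problem sizes in the tests

The validation suite uses a 3-subject x 2-repetition cohort for I/O and
pipeline bookkeeping, 8 subjects for permutation calibration (200 null
replicates x 500 permutations), 18 subjects (the cohort size) for scalar
type-I/power checks with 1000 vectorised replicates, and one full
18 x 4 x 2 x 3 study end to end.

## Known limitations

The interaction permutation scheme is approximate (residualised cells);
the per-channel DSI is reported without Wikstrom-style composite indices;
no mixed-effects modelling, missing-data imputation, or random-field-theory
thresholds; conversion from vendor binary exports is out of scope.
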