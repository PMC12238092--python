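# Methods

## The measurement model

`graspkin` analyses grasp-and-place trials recorded with optical motion
tracking at 250 Hz. Seven marker roles are required per trial: thumb and
index fingernails, the radial and ulnar wrist styloids, one object-mounted
marker, and two markers on manually operated occlusion glasses (frame and
movable lens cover). The lens-cover pair doubles as the trial clock: the
distance between the two markers is minimal while the glasses are closed
(D1) and maximal once they are opened (D2), so the attainment of D2
timestamps the participant's first visual access to the scene.

All positions are normalized to centimetres on ingest (C3D `POINT:UNITS`
honoured; a file without declared units is rejected). The vertical axis is
the third coordinate, z-up. Frames are 0-based and time of frame *i* is
*i/f_s* seconds. Occlusion is represented by NaN; detectors refuse to run
across unfilled NaN (they flag instead of silently interpolating), and
`fill_gaps` linearly interpolates only runs up to a caller-chosen length.

## Signal construction

Raw marker trajectories are smoothed with a Gaussian-weighted moving
average, window 30 samples (120 ms at 250 Hz). The kernel's standard
deviation is window/5 — the usual convention that lets the window span
±2.5 σ; at the signal edges the window shrinks and the remaining weights
renormalize, so constants are preserved exactly everywhere. Velocity is
obtained by central differences on the smoothed signal (one-sided at the
two ends). Virtual markers are arithmetic: the wrist point is the midpoint
of the two styloid markers, the grasp aperture is the 3D thumb-index
distance, and the glasses signal is the frame-lens distance.

## Event detection rules

| event | rule |
|---|---|
| T1, glasses opening | first frame at which the smoothed glasses distance attains ≥ 99 % of its trial maximum (the opened distance D2) |
| T2, wrist lift | first frame after T1 at which the wrist vertical velocity exceeds 0.05 cm/s and stays above it for 20 consecutive frames |
| T3, maximum grasp aperture | the **second** significant peak of the smoothed aperture after T1 (two aperture cycles occur: release of the start cylinder, then preshaping for the grasp); "significant" = topographic prominence ≥ 10 % of the post-T1 aperture range |
| T4, object lift | first frame after T3 at which the object vertical velocity exceeds 0.01 cm/s for 20 consecutive frames |
| T5, stable placement | first frame after T4 with \|v_z\| < 0.01 cm/s whose next 75 frames average \|v_z\| < 0.05 cm/s |

Design choices where the protocol is ambiguous, all configurable in
`DetectionConfig`:

* **T1.** The prose definition ("first point after the maximum distance,
  when relative velocity becomes positive") is not self-consistent with
  the figure-level definition (trial onset = attainment of D2). The
  default follows the attainment-of-maximum reading
  (`t1_plateau_frac = 0.99`); a velocity-based reading is available via
  `t1_mode="velocity"`.
* **Sustained-run events** return the *first* frame of the qualifying run,
  and threshold comparisons are strict (`>` / `<`).
* **Placement** uses \|v_z\|: stability should penalize residual motion in
  either vertical direction.
* **Wrist path marker.** The wrist is defined as the styloid midpoint for
  T2, but the path-length definition names the thumb-index midpoint. The
  default follows the explicit path-length wording (`thumb_index`);
  `wrist_path_markers="wrist"` selects the styloid midpoint. Both are kept
  because the source definitions genuinely disagree.
* A failed detection flags the event (`not-found`, `nan-window`,
  `degraded`, `order-violation`) and cascades: all downstream events are
  marked not-found. Segmentation never raises on detection failure.

## Movement parameters and conditions

Six parameters per trial: initiation time (T2−T1), time to maximum grasp
aperture (T3−T2), reaching time (T4−T2), placement time (T5−T4), total
time (T5−T1), and the wrist path length — the 3D arc length of the
smoothed virtual hand point over [T2, T4]. Durations are exact frame
differences divided by the sampling rate, so
(T2−T1) + (T4−T2) + (T5−T4) = (T5−T1) holds identically.

Conditions are the *relative* rotation between object and target plate:
(plate − object) mod 360 mapped to N1 = 0°, N2 = 90°, N3 = 180°,
N4 = 270°. The sign convention (plate minus object) is a documented
package choice; only the four labels, not a direction, are defined by the
protocol.

## Statistics

One-way repeated-measures ANOVA per parameter on participant × condition
cell means (valid trials only; participants with an empty cell are
excluded listwise). The classical decomposition removes between-subject
variance; sphericity is tested with Mauchly's W (plain chi-square
approximation) and, when violated at p < .05, the reported p-value uses
Greenhouse–Geisser-corrected degrees of freedom with ε clamped to
[1/(k−1), 1]. Effect size is partial η². Follow-ups are paired t-tests
with Bonferroni correction over the 6 condition pairs. Wrist path length
is related to the four temporal components by Spearman rank correlation on
pooled trial-level data (average ranks for ties, large-sample p).
Performance drift over the 64-trial session is summarized by quartile
(trials 1–16, 17–32, 33–48, 49–64) collapsed across conditions, with a
paired first-vs-last-quartile comparison.

Monte-Carlo checks built into the test suite: under the null
(21 subjects, 4 conditions, 2000 replicates) the rejection rate at
α = .05 is within [0.04, 0.06]; with a planted 1-within-SD condition
effect the rejection rate exceeds 0.9.

## The synthetic generator

`synthetic` reproduces the experiment's structure: the 4 × 4 × 4 factorial
design (64 trials, each condition 16×), shuffled by sorting on i.i.d.
uniform keys; four planar five-cube object geometries (pairwise
non-congruent under 90° rotations, tracker cube on top of the centroid
cube); and per-trial seven-marker recordings with planted event frames.

Channel morphology: the glasses distance rises from D1 = 2 cm to
D2 = 10 cm along a smooth 60-frame ramp; the hand performs a straight
minimum-jerk reach (default 28 cm with a 4 cm vertical rise) whose
vertical-velocity threshold crossing lands on the planted T2; the aperture
is a baseline plus two Gaussian bumps (release 6 cm, grasp 8 cm, the
second apex at T3); the object rests, then lifts with a brisk minimum-jerk
rise (≤ 0.6 s), translates to the plate while descending linearly, and
stops abruptly on contact at T5. The sharp velocity transitions at
lift-off and touchdown are deliberate: the 0.01 cm/s crossings must be
steep relative to the smoothed-velocity noise floor for the sustain rules
to localize them — which is also what physical lift-off and contact look
like. No stretch of the transport is stationary long enough to satisfy the
75-frame placement test early.

Planted frames are anchored by calibration: each noiseless channel is
time-shifted (two or three fixed-point iterations) until the corresponding
detector, run on the same smooth-then-detect pipeline the analysis uses,
fires exactly on the planted frame. At zero noise recovery is therefore
exact, and recovery error at nonzero noise measures noise robustness
alone.

### Sensor noise and the velocity thresholds

The generator adds isotropic white Gaussian noise per coordinate per
frame, default **σ = 0.001 cm (10 µm)**. This value is constrained by the
detection thresholds, not free: for white positional noise at 250 Hz
passed through the window-30 Gaussian smoother and central differences,
the velocity noise floor is measured at σ_v ≈ 6.2 σ_pos (in cm/s per cm of
positional noise). The object-channel rule — 0.01 cm/s sustained for 20
frames — is only meaningful while σ_v stays well below 0.01 cm/s, i.e.
σ_pos ≲ 10–15 µm. At a noise level of 0.05 cm (0.5 mm), σ_v ≈ 0.23 cm/s:
the placement test (mean \|v_z\| < 0.05 cm/s over 75 frames) then never
passes and the lift rules false-trigger in most rest windows, so the
published thresholds presuppose an effective high-frequency noise in the
tens of micrometres. The test suite demonstrates both regimes: ≥ 95 % of
planted events are recovered within ±5 frames at the default noise, and
the recovery collapse at 0.5 mm noise is kept as a characterization of
that failure mode.

What the generator does *not* emulate: biomechanically valid joint
kinematics, grip forces, marker-occlusion patterns of real rigs,
low-frequency drift or calibration error of camera systems, and
participant idiosyncrasies beyond per-subject normal offsets. Passing
tests therefore show that the detection rules and statistics behave
correctly on signals with the stated morphology and noise — not that the
rules are robust to every artefact of real recordings.

### Planted condition effects

`EffectSpec` plants per-condition shifts of the event gaps (defaults
mirror the qualitative finding: rotated conditions slower — e.g.
initiation +150 ms for N2–N4 — and wrist paths longer), with per-subject
normal offsets (between-SD) and per-trial normal noise (within-SD). Gaps
are clamped to physically sensible minima (e.g. reaching ≥ 1 s, the
aperture gap inside the reach), which slightly shrinks extreme draws.

## Problem sizes used by the default runs

The test suite and the acceptance script use 200-trial recovery batches,
2000-replicate null calibrations, and one full-size end-to-end experiment
(21 participants × 64 trials ≈ 1344 recordings, streamed one at a time —
a materialized session would be ≈ 0.7 GB). These sizes give Monte-Carlo
standard errors of ≤ 0.5 % on the recovery rate and ≈ 0.005 on the type-I
rate.

## Known limitations

* The C3D writer/reader covers floating-point and scaled-integer point
  data with Intel byte order only; analog channels are ignored.
* Mauchly's p uses the first-order chi-square approximation (statistic
  identical to, p within a few percent of, implementations that add Box's
  second-order term).
* Spearman p-values use the large-sample approximation, adequate for the
  pooled trial-level n (~10³) they are meant for.
* The second-aperture-peak rule is planted by construction in the
  simulator; synthetic data cannot adjudicate whether dual aperture cycles
  generalize to other rigs.
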