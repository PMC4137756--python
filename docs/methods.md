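# Methods

## The kinematic model

A trial is a set of 14 marker trajectories (mm, lab frame, +Z vertical):
trunk (sternum, C7), right arm (acromion, lateral elbow epicondyle, forearm
shaft, radial/ulnar wrist pair), hand (first MCP, first PIP), instrument
(scroll, tailpiece, body — scroll and tailpiece define the *string axis*)
and bow (tip plus a proximal marker about two-thirds of the way from tip to
frog).  Some marker sets of this kind list a single wrist marker, but the
forearm and hand frames need the *line between two wrist markers*; the
marker model therefore requires both, and a single-wrist capture cannot be
analysed without modification.

Anthropometric virtual joint centers are added before decomposition:

* shoulder — the acromion, optionally shifted down the lab vertical by a
  configurable constant (default 0 mm);
* elbow — lateral epicondyle shifted by half the elbow width along the
  medial direction (perpendicular to the shoulder→elbow axis, toward the
  sternum);
* wrist — wrist-marker midpoint shifted by half the wrist width along the
  palmar-normal estimate `cross(forearm axis, radial→ulnar line)`;
* a hand reference point (MCP shifted by half the hand thickness) kept for
  bookkeeping only.

These constructions are decisions: the anthropometric-offset geometry is
not uniquely determined by the marker set, so the exact formulas are
exposed in the API (`estimate_joint_centers` keyword overrides) and the
defaults (elbow 70 mm, wrist 55 mm, hand 25 mm) are adult-scale values
carried in trial metadata.

Five local coordinate systems are built per frame by Gram–Schmidt on two
vectors each: scapula (sternum→shoulder center; vertical × primary), upper
arm (shoulder→elbow centers; primary × lower-arm primary), lower arm
(elbow→wrist centers; primary × wrist line), hand (wrist center→MCP;
primary × wrist line) and bow (proximal→tip marker; proximal marker→distal
finger marker, taken to be the PIP as the most distal hand marker).  The
upper-arm recipe degenerates when the elbow fully extends; degenerate
frames (collinearity below 1e-6 relative) are flagged invalid and excluded
from stroke selection rather than patched.

The chain representation stores the scapula pose in the lab (root) and each
distal segment's pose in its proximal segment's frame (shoulder, elbow,
wrist, hand→bow), as rotation matrices plus translations.  Marker positions
are stored as *per-frame* offsets in their owning segment's frame, not as
constants: soft-tissue wobble therefore survives the round trip, and
`reconstruct(decompose(x)) == x` holds to numerical precision (< 1e-6 mm
over thousands of frames, verified in the suite).  This exactness is what
guarantees that a frozen-joint surrogate differs from the original data
*only* through the manipulated joint: segments proximal to the frozen joint
reconstruct bit-identically.

A note on frame conventions: the scapula frame uses the lab vertical as one
construction vector, so joint motions are invariant under lab-frame
rotations about the vertical (and all translations), but the shoulder
motion is not invariant under rotations that tilt the vertical.  The distal
joints (elbow, wrist, hand→bow) are invariant under arbitrary rigid
transforms.  The tests check exactly these two statements.

## Bow kinematics and measures

The scalar bowing coordinate is the arc-length position, along the bow's
long axis from the proximal bow marker, of the point on the bow axis
closest to the string axis (common-perpendicular foot).  This is the
physically bowed coordinate and is well defined from the recorded markers;
computing velocity from a single bow marker instead is available as a
configuration choice.  Velocity and acceleration are central differences
(`numpy.gradient`; one-sided only at the trial edges, which stroke
selection never reaches).  The bow–string angle is the full-range
arccosine of the axis dot product (so deviations to either side of 90° keep
their sign); an absolute-value (acute) convention is available.

Strokes are intervals between velocity reversals.  A reversal is a zero
crossing confirmed by hysteresis: the crossing counts only once |velocity|
exceeds 5 % of the trial's median absolute velocity on the far side, which
suppresses jitter reversals near zero (threshold configurable).  A trace
that begins at zero velocity contributes its initial crossing.  Only
strokes lasting 0.5–1 s (instructed pace 0.75 s) are scored; the first ten
clean up-bows and ten clean down-bows — no missing samples in the stroke or
in either bounding 45-sample (0.75 s) reversal window — are analysed.
Positive velocity is labelled "down-bow" by convention; all analyses are
direction-symmetric.

Measures per direction: amplitude = position range over the full stroke
including both bounding reversal samples; angle SD and velocity variance
over the central 80 % (trimming `floor(0.1·n)` frames per side, rounding
inward); between-bow variance after linear resampling of each stroke's
central 80 % to 100 normalised time points; acceleration amplitude =
max |a| in the reversal window (peak-to-peak available by flag — the
operationalisation is not uniquely fixed by the protocol, so both are
implemented).  Variances and SDs use the population convention (divide by
n); the choice cancels in surrogate/original ratios and is fixed for
reproducibility.

## Freezing

Freezing replaces a joint's full 6-DoF rigid motion — rotation *and*
translation — at every frame by its value at the reference frame: the
midpoint `floor((start+end)/2)` of the first analysed stroke for the
movement measures, the first analysed reversal for acceleration amplitude.
Stroke and window definitions are taken from the *original* segmentation
and re-applied verbatim to the surrogate: surrogate velocity need not cross
zero at all (a fully frozen arm is static), so re-segmenting would make the
comparison ill-defined.  This is the analysis' most consequential
convention and is logged prominently at run time.  Ratios with an original
measure below 1e-12 are recorded as undefined (never ±∞).

## Statistics

`one_sample_t` is the two-sided one-sample t (sample SD, df = n−1) with
explicit zero-variance handling; `adjust_p` defaults to Holm step-down with
Benjamini–Hochberg as the alternative; `anova_group_lab` fits
`value ~ Group * Lab` and reports Type-II sums of squares for the Group
main effect (statsmodels under the hood; the test suite cross-checks
against closed forms and brute-force projections).  Adjustment families
default to the 6 joint × direction cells within one group × measure for the
one-sample tests and within one measure for the group contrasts; both are
configurable because family boundaries are a genuine analysis choice.

Note: Holm adjustment is *not* idempotent in general (adjusting an
already-adjusted pair like {0.02, 0.04} changes it again), so the suite
asserts the true guarantees instead: adjusted ≥ raw, order preservation,
and the hand-computed step-down values.

## The synthetic generator

The generator works in joint space and synthesises markers through the same
forward model the analysis inverts, so decomposition and freezing have
exact ground truth.  The arm is a shoulder–elbow–wrist chain (300 / 280 /
80 mm segments, 650 mm bow rigid in the hand) bowing against a string axis
parallel to lab Y.  Each joint has two rotation channels:

* *elevation* (about lab Y): transports the bow along its own axis and, by
  construction, cannot change the bow–string angle;
* *yaw* (about lab Z): tilts the bow toward the string axis and perturbs
  the angle.

Transport follows a normalised waveform with reversals every 0.75 s: a
sinusoid (bell velocity) or a trapezoid whose plateau covers a configurable
fraction of the stroke, with peak reversal acceleration `V/ramp` — both
closed forms the measure tests check against.  Coordination enters through
two gains: `wrist_counter_gain` (wrist elevation counter-rotates against
the proximal transport; freezing the wrist then releases the hand lever and
*increases* amplitude) and `angle_compensation_gain` (wrist yaw cancels
proximal yaw noise; freezing the wrist then *increases* angle SD, the
conservative signature of coordination, whereas with independent noise the
frozen-wrist angle SD can only fall).

Presets: `expert_like` (shoulder 0.30 rad + elbow 0.35 rad in-phase
transport, plateau 0.8, counter 0.95, compensation 0.9, joint noise 0.010
rad), `novice_like` (shoulder-only 0.52 rad, sinusoidal, no gains, noise
0.015 rad), `independent_noise` and `compensatory` (shoulder 0.45 rad,
noise 0.020 rad, compensation 0 vs 0.9).  Task parameters are 20 cycles at
0.75 s per bow, 60 Hz, with 0.5 s of padding at each end so the first and
last reversal windows fit.  Marker noise is i.i.d. Gaussian, SD 0.5 mm
(typical optical-capture magnitude); joint noise is Gaussian low-passed at
3 Hz and rescaled to its target SD, mimicking slow physiological
fluctuation.  Transport amplitudes were chosen to give bow strokes of
roughly 300–450 mm on the ~580 mm-reach arm while keeping the elbow safely
away from full extension.

A second entry point, `simulate_tracking_trial`, *programs the bow contact
trajectory directly* and solves planar inverse kinematics for the joints;
it is the reference for validating the bowing-coordinate geometry (the
pipeline recovers the programmed trajectory to < 1e-6 mm) and the
acceleration closed form.

The elbow and wrist markers are placed by a fixed-point iteration such that
the pipeline's anthropometric joint-center constructions land exactly on
the generator's true joint centers; this is what upgrades the
joint-angle-recovery and freezing-null tests from approximate to exact.

What the generator does *not* emulate: soft-tissue artefact (marker noise
is white, not correlated with motion), out-of-plane shoulder girdle or
trunk motion (the root is static), muscle or torque dynamics, and any
acoustic consequence of bowing.  Passing tests on synthetic data therefore
certify the *analysis machinery* — decomposition, surrogate construction,
measures, statistics — and the internal consistency of the coordination
logic, not the physiological realism of any particular profile.

## Numerical choices and degenerate inputs

* Filtering: bidirectional 5th-order Butterworth, 20 Hz cut-off, applied
  per contiguous non-missing block; blocks shorter than the filtfilt
  warm-up are passed through and logged.  Filtering precedes decimation
  (120 → 60 Hz sample picking), so the 20 Hz cut-off already bounds content
  below the post-decimation Nyquist.  Missing samples are never
  interpolated.
* Gram–Schmidt degeneracy tolerance 1e-6 (relative), including a
  cross-product-magnitude guard for frames whose secondary axis is itself a
  cross product of nearly parallel vectors.
* Rotation matrices are composed in double precision; orthonormality drift
  over 100+ compositions stays below 1e-9 (asserted).
* Contact point undefined (bow parallel to string) → frame marked missing;
  zero-variance t-test sample with mean ≠ 0 → explicit error; ANOVA with a
  saturated design (one observation per cell) → explicit "not estimable"
  error, skipped with a warning at the report level.
* Problem sizes in the test and acceptance runs — 10 participants per
  cohort, 20 cycles per trial, 10 000 replicates for the type-I
  calibration, 400 for the ANOVA power check — were chosen as the smallest
  sizes at which the cohort-level sign patterns and calibration bands are
  stable across seeds.

## Known limitations

* The analysis is purely kinematic: joint torques, interaction torques and
  muscle-level constraints (e.g. biarticular coupling) are out of scope, so
  frozen surrogates can be physiologically unrealistic — most plausibly at
  reversals, where inter-segment dynamics are strongest.  Reversal-measure
  effects deserve the most caution.
* Freezing confounds *removing motion* with *removing coordination* for
  amplitude-type measures; only variability increases are unambiguous
  evidence of coordination (the property the compensatory/independent
  presets probe).
* The C3D reader requires the optional `ezc3d` package; the native exchange
  format is the vendor-neutral wide TSV + YAML sidecar.
* The planar two-channel joint model spans the coordination structure the
  analysis is sensitive to, but real bowing has richer DoF (e.g. forearm
  pronation) that the marker set only partially constrains.
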