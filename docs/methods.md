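# Methods

This note documents the models, parameter choices and known limitations
of the package: what each stage computes, why its defaults are what
they are, what the motion simulator does and does not emulate, and
which design questions were genuinely open.

## Scale model

The FMA-UE rates 33 items 0/1/2; the three reflex items need externally
applied forces and are out of scope, leaving 30 voluntary items with a
maximum total of 60.  The registry binds each item to one of 17 motion
tasks (several items are parsed from a single recording: the nine
within-synergy items from the composite motion I, shoulder flexion
0–90° and 90–180° from one 0–180° movement, the wrist stability and
repetition items from one recording each, mass flexion and extension
from one open–close cycle).  Items 14 and 17 are composites of a
positioning movement and a pronation/supination movement; items 14, 17
and 33 carry prerequisites.  Motions I, II, III and V are performed
twice per side; their feature vectors are averaged before
classification (the merge rule for repetitions was an open choice;
averaging is the least-variance option).

## Preprocessing

**SSA filter.**  Each scalar channel is embedded in an L×(N−L+1) Hankel
trajectory matrix, decomposed by SVD, truncated to the k singular
triplets with largest singular values (ties broken by index order) and
reconstructed by anti-diagonal averaging.  Defaults L=15 frames
(0.5 s at 30 fps) and k=2 keep trend plus the dominant oscillation of a
discrete reaching movement.  For the finger-to-nose motion the default
would erase the 4–6 Hz tremor band that one item must see, so the
pipeline keeps a per-motion override (k=6 for motion XV), exposed in
`PipelineConfig.ssa_overrides`.  The exact override strength is a
tunable: any k large enough to retain a 5 Hz component at 30 fps works.

**Which reconstruction feeds which feature.**  Segmentation, the
wrist–nose distance and movement time are computed from the default
(k=2) reconstruction — they want the movement trend, and the minimum of
a distance over frames is biased downward by any retained noise.  Only
the smoothness metric (SPARC) is computed from the k=6 reconstruction.

**Segmentation.**  The motion segment runs from the first to the last
frame whose endpoint (wrist) speed strictly exceeds the trial mean; a
series that never exceeds its mean yields the full range.  This rule
necessarily trims the slow tails of a bell-shaped speed profile — for a
minimum-jerk reach padded with rest it covers about two thirds of the
movement interval — which is fine for ratio-type features because both
sides are trimmed the same way.  Segmentation runs on filtered data
(denoising precedes segmentation in the pipeline).

**Low-pass comparison filter.**  A zero-phase 4th-order Butterworth
(default cutoff 5 Hz) is provided only to reproduce the filter
comparison; no pipeline stage uses it.

## Features

The Shoulder/Elbow vector has exactly 36 entries: 6 endpoint features
(path length; max/mean speed; speed variance; SPARC; dimensionless
jerk), 24 angular features (shoulder flexion, shoulder
adduction/abduction, shoulder rotation, elbow flexion × ROM, max, min,
max/mean angular velocity, angular-velocity variance) and 6 others
(inter-joint coordination index, movement time, max shoulder
displacement per axis, trunk compensation).

Numerical conventions, fixed once and used everywhere:

* derivatives by central finite differences (second-order edges);
  non-uniform timestamps are handled by `numpy.gradient` on the
  timestamp vector;
* "mean velocity" is the mean speed magnitude; mean angular velocity
  uses the absolute value, its variance the signed value;
* angles in degrees, positions in meters, speeds in m/s; offsets are
  reported in millimeters only at the reporting boundary;
* movement time is frame count × mean frame interval, so a 60-frame
  segment at 30 fps is exactly 2.0 s;
* SPARC uses the literature-standard parameterization: zero-padded FFT
  (≥4096 bins), amplitude-normalized magnitude spectrum, 10 Hz maximum
  cutoff, 0.05 adaptive amplitude threshold.  It is invariant to
  amplitude and duration scaling (bit-exact for power-of-two amplitude
  factors, to rounding otherwise);
* dimensionless jerk follows the speed-based convention
  DJ = −(T³/v_peak²)·∫(d²v/dt²)² dt.  The T³ exponent is what makes the
  quantity dimensionless and temporally scale-invariant for a speed
  profile (T⁵ is the exponent for the position-based variant);
* the inter-joint coordination index is the Pearson correlation between
  the shoulder-flexion and elbow-flexion angle trajectories over the
  segment — the simplest scalar coupling summary; alternatives
  (angle-angle plot area, CRP) would slot into the same interface;
* shoulder rotation from position-only skeletons is the angle of the
  forearm's component perpendicular to the upper arm, measured against
  the projected trunk-forward axis; when the elbow is numerically
  straight the angle is undefined and reported as 0;
* trunk compensation is the maximum excursion of the mid-shoulder point
  from its segment-start position; per-axis shoulder displacement is the
  maximum absolute per-axis deviation of the moving-side shoulder.

## Scoring

**Rule layer.**  Every Wrist/Hand, Grasp and Coordination/Speed item is
scored by one IF-ELSEIF-ELSE rule on a performance ratio r: for
higher-is-better features r = x_p/reference, for lower-is-better
features r = reference/x_p (x_p ≤ 0 counts as perfect).  Scores are 0
for r < 1/3, 1 for 1/3 ≤ r < 2/3, 2 for r ≥ 2/3; the half-open
bands make a ratio of exactly 1 unambiguously a 2.  References are the
same subject's less-affected side (h) or a cohort normal constant (N),
the mean of all subjects' less-affected values; under leave-one-out the
held-out subject is excluded from that mean (the conservative reading).

The per-item bindings (which feature, which reference mode, which
direction) ship as data in `src/fmascore/data/rules.json` so they can
be audited and adjusted without touching code.  Two bindings deserve
comment:

* item 31 (tremor) uses the magnitude |SPARC| with a lower-is-better
  rule.  A ratio of raw (negative) SPARC values would invert the
  ordering, so the magnitude form is the faithful realization of
  "smoother is better".  Note a structural property: because the
  normalized-spectrum arc length of any speed profile is bounded, the
  |SPARC| ratio of two profiles rarely drops below ~0.5, so the 1/3 cut
  essentially never fires and the item distinguishes scores 1 and 2
  only.  This is a property of the metric, not a defect of the rule
  engine, and it is visible in the simulation results;
* items 24/25 (mass flexion/extension) use a per-finger rule on the
  fingertip angle (flexion peak, or extension excursion = flexion peak
  minus post-peak minimum), then feed the 4-finger total (0–8) through
  the same three-way rule with reference 8.

**Prerequisites.**  Items 14/17: the positioning channel (elbow or
shoulder flexion) must reach at least λ₂ = 2/3 of its less-affected
reference.  Item 33: the paretic wrist must come within 0.25 m of the
nose — an accurate fingertip touch still leaves the wrist roughly a
hand-length (~0.08 m) away, so the cut sits well above that.  Unmet
prerequisites score 0.

**Random-forest layer.**  One classifier per Shoulder/Elbow item
(scikit-learn, 100 trees, 6 features considered per split, seeded per
item for reproducibility), trained on the 36-feature vectors of the
item's motion with reference scores as labels.  If a training fold
contains a single label class the fit degenerates to a constant
classifier with a warning — unavoidable for, e.g., an all-unimpaired
cohort.  Evaluation protocols: subject-wise leave-one-out, and a
simulated-online split that ranks subjects by reference total and
alternates them into train/test halves (ties broken by subject id;
odd-sized cohorts are rejected because the protocol is defined for an
even split).

## Sample-size utility

The two-stage approximation for a Pearson-correlation design: stage 1
sizes the study from the large-sample Fisher-z width formula,
n₀ = 4(1−r²)²(z₁₋α/₂/ω)² + 3, rounded up; stage 2 back-transforms the
Fisher-z interval achieved at n₀ to the correlation scale (width b₀)
and corrects n = (n₀−3)(b₀/ω)² + 3, rounded to the nearest integer.
The rounding pair (up, nearest) is the convention of the published
worked examples; it is isolated in one function.  At (r=0.9, ω=0.3,
α=0.01) the method returns 20.

## The simulator

The clinical recordings behind this kind of system are not publicly
available, so the package ships a generator whose outputs exercise the
identical pipeline surface (same file formats, same validation).  Per
subject it emits skeleton (30 fps), hand (100 fps) and grip (10 Hz)
recordings for all 17 motions on both sides.

Impairment enters through per-item ability levels a ∈ [0, 1], scattered
around a subject base ability (items sharing a recording channel share
a level).  The planted reference score is the third of the ability
level — deliberately the same three-way division as the rule engine, so
that rule-based recovery is exact in the noise-free limit.  That is the
intended oracle structure, not a hidden calibration: the simulator's
job is to let tests verify the pipeline, and the noise-free limit is
the identity check.

Paretic-side generation: ranges of motion and channel amplitudes scale
with a (so measured performance ratios equal a up to noise);
durations stretch by 1 + 1.2(1−a); movements fragment into 2–3
staggered minimum-jerk sub-movements below a = 0.7/0.4; a forward trunk
lean of 0.13(1−a)² m emulates compensation; the finger-to-nose movement
gains a movement-gated 5 Hz tremor (amplitude 0.05(1−a₃₁)^1.5 m — the
gating keeps the hold phase quiet so the time item is not corrupted), a
residual wrist–nose distance 0.08/a₃₂ m and a duration 1.5/a₃₃ s capped
at 8 s.  The positioning channels of items 14/17 degrade more slowly
(scale min(1, a + 1/3)) so the reach-the-start-position prerequisite
flips at a ≈ 1/3, consistent with the planted score.

Sensor noise: skeleton coordinates receive slowly drifting tracking
error (0.5 s correlation) plus white jitter, combined SD 15 mm, which
puts the raw-vs-truth mean wrist offset at the tens-of-millimeters
scale of depth-camera skeletons; hand angles receive 1.5° noise, grip
force 0.3 N.  Purely white position noise at that SD would make
finite-difference speeds noise-dominated, which no tracking sensor
exhibits; the drift/jitter split is the realistic middle ground and
keeps the SSA stage consequential.

What the simulator does **not** emulate: occlusion and tracking loss
(the known failure mode of the hand-behind-back item), soft-tissue and
marker-placement artifacts, synergy-specific coupling patterns between
joints, fatigue across repetitions, and any between-item correlation
structure beyond the shared subject base ability.  Passing tests
therefore certify the pipeline's numerics and logic on data with the
assumed statistical shape — they are not clinical validation.

## Problem sizes used in tests

The acceptance suite runs cohorts of 20 simulated subjects (the size
the sample-size computation itself prescribes): 50 seeded replicates
for rule-layer recovery (rule-relevant motions only), two full-pipeline
replicates for rank-order recovery, and a 60-sample 3-class Gaussian
problem for the random-forest sanity check.  These sizes give stable
statistics while keeping the default test run short.

## Known limitations

* Shoulder rotation from position-only skeletons is a projection-based
  surrogate; a sensor with orientation data would measure it directly.
* Item 31's score-0 band is unreachable through the |SPARC| ratio (see
  above); a cohort-calibrated absolute threshold would be needed to
  separate severe tremor from moderate.
* The normal constants (N references) are cohort means; with very small
  or skewed cohorts they drift, and the held-out-subject exclusion
  makes them fold-dependent under LOOCV.
* The rule bindings are reconstructions from the per-item feature
  lists; they are shipped as data precisely so domain experts can
  revise them.
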