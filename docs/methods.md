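# Methods

This note documents the scientific model behind `oculoscreen`: what the
synthetic cohorts emulate, how the oculomotor features are defined, how the
screening classifier is trained and evaluated without subject leakage, and
which choices were genuinely open and how they were resolved.

## The screening problem

Unilateral amblyopia alters oculomotor control in ways that persist under
binocular, best-corrected viewing: less efficient visual search (higher
scan-path entropy, more regressions, larger inter-fixation steps), delayed
and less stable fixation of a central pattern (longer fixation latency,
larger orientation-referenced drift and dispersion), and degraded smooth
pursuit (larger tracking error, lower velocity gain, more catch-up
saccades). The package turns 30 Hz binocular gaze recordings from a
three-task battery into trial-level feature vectors and trains a calibrated
random-forest classifier to separate children with unilateral amblyopia
from visually normal controls, with every learning step confined to
training subjects.

## Gaze preprocessing

Pixels are converted to degrees of visual angle with a per-axis arctangent
about the screen center (origin center, x rightward, y upward; the default
display is a 24-inch 1920x1080 panel at 60 cm). The primary analysis stream
is cyclopean gaze: the sample-wise mean of the two eyes where both are
valid, the single valid eye otherwise, missing where neither. Samples are
invalidated by device flags, positions off the display, raw inter-sample
speeds above 1000 deg/s, and a +/-1-frame margin around invalid runs.
Interior gaps of at most 200 ms (6 samples) are bridged linearly; trials
with more than 30% invalid/missing samples are excluded (30.0% exactly is
retained — the exclusion rule is read strictly). Positions are smoothed
with a Savitzky-Golay filter (window 5, order 2) applied independently per
contiguous valid run (shorter runs pass through unsmoothed), and velocity
is the central difference of the smoothed positions.

Two decisions here were genuinely open:

- The 1000 deg/s glitch screen runs on raw forward differences of the
  unsmoothed, uninterpolated stream. Its purpose is glitch rejection;
  smoothing first would smear glitches into neighbouring samples and
  interpolating first would let them contaminate bridged gaps. The
  smoothed-central alternative is config-selectable.
- Strict mask idempotence of flag -> interpolate cannot hold under the
  margin rule (a margin re-applied to its own output dilates by one more
  frame); the chain is treated as a single pass over raw input, and the
  margin-free chain is verified idempotent in tests.

## Event detection and features

Fixations come from a greedy dispersion-threshold (I-DT) scan on the
smoothed positions: windows grow while (x-range + y-range) stays at or
below 1.0 deg and become fixations at 100 ms or more. Saccade-like events
are maximal runs of gate-speed above 60 deg/s; by default the gate uses raw
forward-difference speed on the cleaned pre-smoothing positions, and event
amplitude is the position change between the flanking sub-threshold
samples. At 30 Hz a 0.3-1.0 deg single-interval step can never reach
60 deg/s under any velocity signal; the amplitude band is therefore
populated by overshoot-return events (two fast legs with a small net
displacement), which is also how the simulator realizes small corrective
behaviour. Catch-up saccades are events with amplitude above 1.5 deg whose
gaze-target position error strictly decreases from the last valid
pre-event sample to the first valid post-event sample; they are counted for
the pursuit task only. Pursuit onset latency is the first post-onset time
at which gaze speed exceeds 5 deg/s with a positive gaze-target velocity
dot product for at least three consecutive samples.

Task-level features (p = 15, fixed across trials):

- Search (Task 1): fixation-duration mean/SD, within-fixation RMS
  dispersion, refixation count (centroid within 1.0 deg of a non-adjacent
  earlier centroid), mean inter-centroid saccade amplitude, regressions
  (steps whose horizontal component opposes the sign of the summed
  horizontal displacement; no magnitude gate), and scan-path entropy: the
  plug-in Shannon entropy (bits) of the empirical distribution of
  (from-cell, to-cell) transition pairs on a uniform 8x6 display grid.
  Entropy of transition *pairs* was chosen over state entropy or
  conditional entropy; the published group means are attainable under all
  three readings, so the definition is a documented choice.
- Grating viewing (Task 2): latency from stimulus onset to the first
  fixation whose centroid lies in the 2.0 deg ROI; directional drift, the
  absolute projection of the net first-to-last-sample displacement onto
  the grating orientation axis; convex-hull area of in-ROI samples; and
  the small-corrective-event rate per minute. Trial features are
  median-summarized within orientation, then averaged across the 12
  orientations.
- Pursuit (Task 3): mean Euclidean gaze-target distance; pursuit gain, the
  median gaze-speed/target-speed ratio over samples with target speed
  above 2 deg/s (target velocity is analytic); catch-up count; onset
  latency.

Missing features (excluded trials, undefined quantities) propagate as NaN
and are median-imputed inside model training folds, never at extraction.

## Synthetic cohorts

No public recordings exist for this setting, so the generator is a
first-class, tested component. Its guiding principle is target-first
construction: each subject's latent parameter *is* the intended extracted
feature value, drawn from group distributions whose defaults equal the
published subject-level summaries (e.g. pursuit gain 0.946 +/- 0.046
vs. 0.799 +/- 0.074; scan-path entropy 2.126 +/- 0.282 vs. 2.824 +/-
0.354), and the trial kinematics are built so that the full extraction
chain recovers that value. Residual deterministic biases of the chain
(Savitzky-Golay shrinkage, frame quantization, folded-normal inflation of
absolute projections, hull geometry of a correlated cloud) are absorbed by
a small set of calibration constants fitted once on noise-controlled
simulations and frozen in `Calibration`.

Key constructions:

- **Scan paths with exact entropy.** For a trial with T inter-fixation
  transitions the planner enumerates transition-count partitions of the
  form {c_1..c_k, 1^(k-1)} — k dwell blocks of self-transitions joined by
  k-1 distinct between-cell moves — and picks the partition whose plug-in
  entropy is closest to the subject's target. Blocks are realized as >1 deg
  hops inside one grid cell (so I-DT separates the fixations but the cell
  sequence repeats), moves as large jumps to unused cells whose length
  solves the mean-saccade-amplitude target. Every hop carries a deliberate
  horizontal sign so measurement noise cannot flip the regression reading;
  the planned number of leftward steps realizes the regression target
  exactly.
- **Grating fixation.** After a latency-delayed entry from a parking
  position just outside the ROI (placed perpendicular to the stimulus
  orientation so the entry step projects to ~0 on the drift axis), gaze
  follows a two-timescale Ornstein-Uhlenbeck process: fast jitter (SD 0.30
  deg, tau ~0.3 s) plus a slow meander whose variance is solved from the
  subject's hull-area target through a calibrated power law. The slow
  meander collapses in the last samples (a re-foveating settle), so the
  net trial displacement reflects the injected oriented drift, which is
  solved by inverting a folded-normal mean. Oblique orientations receive a
  1.4x drift multiplier (normalized to unit mean across orientations).
- **Pursuit.** Between corrective movements, gaze displacement is the
  target displacement scaled by the velocity gain. Steady-state error is
  absorbed by sub-detection corrective hops (single-frame, < 60 deg/s, so
  the event detector cannot see them) triggered at a threshold solved from
  the tracking-error target; counted catch-up saccades come from scripted
  lapse episodes (pursuit pauses, error grows to ~2.6 deg, a one-frame
  ~2.2 deg jump recovers it), whose number per trial is the subject's
  catch-up target. The gain correction applied during injection scales
  with the square of the configured eye noise, so noise-free simulations
  inject the target gain unchanged and recover it within 0.02.
- **Binocular emission.** Left/right streams are the latent trace plus
  independent per-eye noise (0.10 deg SD) and a slow disconjugate wander.
  In amblyopia the designated amblyopic eye carries 1.5x noise and a much
  larger wander (0.35 vs 0.07 deg SD). This is the mechanism behind the
  gaze-stream sensitivity analysis: the amblyopic-eye stream carries the
  group signal of the shared trace *plus* an eye-specific instability
  signal, so it is at least as informative as the fellow-eye stream.
- **Artifacts.** Blinks (0.22/s, log-normal durations around 140 ms, so
  both bridgeable and non-bridgeable gaps occur), per-eye tracking loss,
  binocular one-sample teleports (> 1000 deg/s) and short off-display
  excursions. The generator reports, per trial, the injected-invalid
  fraction and its +/-1-frame dilation; the latter equals the fraction
  preprocessing flags.

What the generator does **not** emulate: real pupil-detection physics, head
motion and calibration drift, saccadic main-sequence kinematics at high
temporal resolution, orientation-report behaviour, or any correlation
structure between clinical covariates and oculomotor latents beyond group
membership. Passing tests therefore demonstrate the correctness and
leakage-freeness of the pipeline and the self-consistency of the
generator, not clinical performance on real recordings.

## Classifier and evaluation protocol

Trial rows from all tasks share one 15-dimensional schema (features of the
other tasks are NaN and fold-imputed). Within each training set:
standardization and median imputation are learned from training rows only;
a 300-tree Gini random forest (per-node sqrt(p) feature subsampling,
inverse-class-frequency weights, bootstrap resampling of trials) produces
trial posteriors by averaging tree posteriors; an isotonic
(pool-adjacent-violators) map fitted on inner out-of-fold trial
predictions calibrates them; subject evidence is the median of calibrated
trial probabilities; and the decision threshold maximizes Youden's J on
the inner out-of-fold subject probabilities (ties to the smallest
threshold; the decision rule is boundary-inclusive). The outer loop is
leave-one-subject-out; per-fold seeds derive only from the master seed and
the held-out subject's id.

Open choices, resolved as the package's own defaults:

- Per-node feature subsampling is sqrt(p). Subsampling at p features would
  be a no-op and defeat its stated purpose of decorrelating trees.
- Inner CV is subject-wise, label-stratified, 5-fold.
- Tree shape defaults to depth 8 with min leaf 3. Trial-level labels are
  inherently overlapping (a single 2-s grating trial rarely identifies the
  subject's group), so unbounded trees grow to depth ~40 chasing noise at
  10x the fitting cost with no gain in subject-level discrimination;
  compact trees are the tuned configuration. A hyperparameter grid over
  depth and leaf size is supported (`param_grid`) but the default fits the
  configured setting directly.
- Isotonic calibration uses inner out-of-fold predictions, not
  resubstitution, to avoid optimistic calibration; the threshold is
  selected on subject-level aggregates because the decision rule is
  subject-level.

Baselines (L2 logistic regression, linear SVM via its decision function,
gradient-boosted trees), task ablations (all seven task subsets),
gaze-stream substitutions (cyclopean / amblyopic-eye / fellow-eye /
both-valid-only), learning curves over nested subject subsets, clinical
covariates (BCVA per eye, interocular difference, log stereoacuity,
spherical equivalents and their absolute difference) alone and combined
with gaze features, and a preprocessing robustness grid all rerun the
identical nested protocol with one substitution each.

## Statistical layer

Group comparisons aggregate trial features to subject level (median;
orientation-then-average for the grating task), choose a two-sided t-test
(Cohen's d) or Mann-Whitney U (rank-biserial r) by a Shapiro-Wilk
normality gate at alpha = 0.05 in both groups, and control FDR with
Benjamini-Hochberg at q = 0.05 within each task's feature family.
Operating-point metrics carry Wilson score intervals; AUC/AP use
subject-level bootstrap percentile intervals (subjects are the exchangeable
unit, never trials). Calibration is summarized by the Brier score and ECE
with 10 equal-width bins. Order effects compare early versus late halves
of retained trials per subject (odd counts give the early half the extra
trial) with paired two-sided Wilcoxon signed-rank tests (Pratt zero
handling). Prevalence-adjusted PPV/NPV follow Bayes' rule.

## Problem sizes used in the checked runs

The default synthetic cohort is 35 subjects per group with the full trial
plan (8 search trials, 72 grating trials, 6 pursuit trials), matching the
study design; the nested-LOSO evaluation on it uses the default forest.
Auxiliary property checks choose sizes appropriate to the property: the
leakage audit runs all 70 outer folds with a 40-tree forest and 3 inner
folds (the property is structural, not statistical); the gaze-stream
ordering uses 18 subjects per group with 150 trees; generator target
recovery uses 200 subjects per group simulated in per-subject chunks; and
noise-free gain recovery uses a small cohort with artifacts and
measurement noise disabled.

## Known limitations

- The generator's calibration constants are tied to the default extraction
  parameters (30 Hz, SG(5,2), I-DT 1.0 deg / 100 ms, ROI 2.0 deg);
  re-calibration is needed if those defaults change.
- Small-corrective-event rates on 2-s trials are coarse (one event changes
  the rate by 30 per minute), so that feature is weakly informative by
  construction.
- Subject-level probabilities concentrate near 0 and 1 on synthetic
  cohorts whose group effects match the published summaries; ECE on 70
  subjects is accordingly noisy.
- Pursuit onset latency inherits the variability of the random target
  phase at motion onset; its extracted values are noisier than the other
  pursuit features.
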