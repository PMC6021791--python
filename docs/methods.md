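# Methods

`shankgait` implements a complete shank-gyroscope gait-analysis
pipeline for frailty assessment: synthetic signal generation,
gait-cycle and propulsion-phase segmentation, six sensor-derived gait
parameters, Fried phenotype staging, cohort effect-size statistics, a
small neural-network stage classifier, and a walking-bout monitor for
unsupervised deployment. This note records the models, the parameters
that matter, the numerical choices, and what the synthetic data can
and cannot show.

## Signal model and the six gait parameters

The pipeline works from the three-axis angular velocity of the shank
sampled at 100 Hz, in deg/s. The x-axis lies along the tibia
(transverse-plane rotation), the y-axis is anterior–posterior
(frontal plane) and the z-axis mediolateral — the sagittal-plane
rotation that dominates walking. One gait cycle runs heel-strike →
heel-off → toe-off → mid-swing → next heel-strike; the propulsion
phase is the heel-off-to-toe-off interval in which the body is pushed
forward.

Per accepted cycle the six parameters are:

| parameter | definition | unit |
|---|---|---|
| toe-off speed | magnitude of ω_z at toe-off | deg/s |
| mid-swing speed | magnitude of ω_z at the mid-swing peak | deg/s |
| mid-stance speed | max − min of ω_z over the stance window | deg/s |
| propulsion duration | toe-off − heel-off | s |
| propulsion acceleration | average slope of ω_z over the propulsion ramp | deg/s² |
| speed norm | per-cycle max of √(ω_x² + ω_y²) | deg/s |

Per subject-leg, each parameter is summarised by its mean, sample SD
and coefficient of variation over accepted cycles; a leg with fewer
than two accepted cycles is excluded from analysis.

Two definitions were genuinely open and are resolved as follows, each
behind a config switch:

* **Mid-stance window.** A literal stance window running all the way
  to toe-off makes the range reach down into the toe-off trough, so
  the "mid-stance" value would nearly duplicate
  acceleration × duration and carry no independent information (the
  test suite demonstrates this identity on synthetic signals). The
  default window therefore ends at heel-off;
  `midstance_window="toe_off"` restores the literal reading.
* **Propulsion acceleration.** Default is the endpoint slope
  |ω_z(toe-off) − ω_z(heel-off)| / duration — the average slope of
  the ramp; `acceleration_method="least_squares"` fits a line to the
  ramp samples instead (identical on a clean linear ramp).

A "heel-off speed" is sometimes listed alongside these parameters in
the frailty literature but has no agreed operational definition; it
is deliberately not computed.

## Segmentation

Detection runs on the sagittal channel after a 4th-order zero-phase
Butterworth low-pass (default cutoff 10 Hz — gait energy in shank
angular velocity sits below that; `cutoff=None` skips filtering for
clean signals):

1. **Mid-swing** peaks: local maxima above 60 deg/s with ≥ 0.6 s
   separation. The threshold sits a factor ~4 under the frail-group
   mean mid-swing speed (230 deg/s), the separation well under any
   plausible stride time; both are configurable.
2. **Toe-off**: the most negative local minimum in a window covering
   45% of the local stride estimate before each mid-swing peak;
   **heel-strike**: likewise after the peak. Ties break toward the
   sample nearest the peak. Because zero-phase filtering rounds these
   asymmetric troughs and shifts their minima by a few samples, each
   trough is re-located on the unfiltered channel within ±30 ms of
   the filtered detection.
3. **Heel-off**: within each stance, the local slope is estimated by
   a Savitzky–Golay derivative (150 ms window); the steepest descent
   marks the interior of the propulsion ramp, and the ramp is
   extended backwards on the raw first difference while the slope
   stays below 10% of that steepest descent, tolerating
   interruptions up to 50 ms. Heel-off is the first sample of the
   descending run. The 10% onset fraction is configurable because
   published heel-off operationalisations differ. A stance that is
   one pure ramp puts heel-off at the stance start; stances under
   three samples are flagged `rejected`.

Cycles are delimited heel-strike to heel-strike; partial cycles at
recording boundaries are discarded, so an n-cycle walk yields n−1
complete cycles.

## Synthetic gait generator

The generator is a test fixture, not a biomechanical simulation: it
reproduces the morphology of the sagittal shank-gyro waveform and the
per-stage parameter distributions, not gait dynamics, turning, or
sensor artefacts beyond band-limited noise. Passing round-trip tests
on it shows the segmentation and extraction are mutually consistent
and exact on clean morphology — not that they are robust to every
real-world artefact.

One cycle is a piecewise curve through exact anchors (mid-swing peak
positive, toe-off trough negative — the common shank-gyro convention;
all extracted parameters are magnitudes, so results do not depend on
it):

* heel-strike trough at ω_HO − R_MS, monotone shape-preserving-cubic
  (PCHIP) rise to the heel-off value ω_HO over the early stance —
  monotonicity makes the realised mid-stance range exactly R_MS;
* a linear propulsion ramp of duration d_P and slope −a_P ending at
  the toe-off trough −v_TO (hence ω_HO = a_P·d_P − v_TO);
* a PCHIP swing rising to the mid-swing peak +v_MSw and returning to
  the next cycle's heel-strike value.

Frontal/transverse channels are two seeded sinusoids at stride and
double-stride frequency, rescaled so the per-cycle maximum Euclidean
norm equals the requested speed norm exactly. Anchor times snap to
the sample grid and the sidecar ground truth stores the *realised*
values, which is what makes 1-sample/1% round-trip assertions
meaningful. Specs whose ramp cannot fit inside the stride (or whose
ramp start would exceed the mid-swing peak) are rejected as
infeasible rather than silently distorted. Walk noise is Gaussian,
low-passed at 15 Hz and scaled to the requested SD.

Stride duration is a generator-only control (it is not one of the six
parameters): defaults are 1.20 / 1.30 / 1.45 s for non-frail /
pre-frail / frail, stretching per subject when a drawn propulsion
duration needs more room.

**Cohorts.** Default group sizes are 49 / 92 / 20 (non-frail /
pre-frail / frail — the composition of the 161-subject reference
cohort) with per-stage parameter means and SDs from the reference
right-shin table. The six parameters share a single-factor
correlation (loading 0.7): one latent "slowness" on which propulsion
duration loads positively and the five speed/acceleration parameters
negatively. Draws are clipped to the feasible region (positivity,
toe-off below mid-swing); clipping moves group means by far less than
the 2-SE convergence band checked in tests. Demographics (age,
height, BMI, sex ratio) come from the per-stage reference
distributions. Fried phenotype measures are generated from the same
gait latent with decreasing loadings — slowness strongest, then
weakness, exhaustion, low activity, shrinking near zero — so the
sign structure between gait parameters and phenotypes matches the
reference cohort. The stage label attached to each subject is the
generating group's; re-deriving stages from the generated measures
via the Fried rules approximates but does not exactly reproduce these
labels, because quintile cut-offs are cohort-relative.

## Fried phenotyping

Shrinking is an absolute rule (≥ 4.54 kg unintentional loss in a
year); the other four are cohort-relative worst-quintile (20%) rules:
grip strength stratified by sex × BMI, walking time over 4.57 m
stratified by sex × height (slowest quintile), exhaustion and
activity scores unstratified. Cut-offs use inclusive linear
interpolation and ties at the cut-off are all flagged — the
conservative convention; published operationalisations vary, so the
quantile and convention are exposed. Continuous strata use within-sex
quartile bins, since no standard bin edges exist. A missing measure
yields an explicitly undetermined flag (NA), which counts as absent
for staging. Staging: 0 flags non-frail, 1–2 pre-frail, ≥3 frail.

## Cohort statistics

All tests that can run from group summary statistics do — mean, SD
and n are sufficient for one-way ANOVA, η², Cohen's d and
Games–Howell — so published group tables can be re-analysed without
raw data. η² = SS_between/SS_total; Cohen's d uses the pooled SD.
Games–Howell uses the Welch–Satterthwaite df and the
studentized-range distribution (SciPy's quadrature implementation;
the suite cross-checks it against an independent double quadrature to
1e-6 and against a raw-data reference implementation). χ² tests on
2×2 tables are Pearson without continuity correction. Spearman uses
tie-averaged ranks. ANCOVA fits outcome ~ group + age + sex + BMI by
least squares and tests the group factor with a partial (Type III)
F; its type-I error is calibrated by simulation in the suite.
Interpretation bands follow convention (η²: 0.01/0.06/0.14; d:
0.2/0.5/0.8) and α = 0.05 throughout, with no multiple-testing
correction beyond the Games–Howell family.

## Stage classifier

One hidden layer of five TanH units with a softmax read-out, L2
penalty 1e-3, trained by full-batch L-BFGS on cross-entropy with
features z-scored on each training fold (the optimiser, penalty and
iteration cap are reproducibility choices, not scientific claims —
all seeded and configurable, including multi-layer variants).
Evaluation: 8-fold cross-validation pooling out-of-fold
probabilities, one-vs-rest ROC/AUC per stage, and a percentile
bootstrap (default 500 unstratified subject resamples, redrawn if a
class disappears) for the AUC confidence intervals.

The cross-validation partition is **stratified by class** by default.
With a rare class (20 frail of 161), an unstratified split makes
training and test class proportions anti-correlate, which biases the
label-permutation null AUC to ~0.43 instead of 0.5; stratified folds
keep the same fold sizes (20–21 subjects) while restoring an unbiased
chance level (measured 0.497–0.499). `stratified=False` gives the
plain random split, with automatic redraw when a training fold loses
a class.

Absolute AUC values reported for real cohorts depend on the raw
recordings and are not reproducible from synthetic data; what is
checked instead is structure: chance level under label permutation, and the ordering
that the pre-frail stage is the hardest to separate (frail-vs-rest
AUC exceeds pre-frail-vs-rest AUC in ≥ 90% of seeded cohort
replicates).

## Bout monitor

A pure finite-state machine over time-stamped step events: sleep →
armed after 3 consecutive steps within the inter-step gap limit
(default 2.5 s — the same limit defines both arming and bout
continuation, since no separate value is established); recording
accumulates steps; a gap before step 20 discards the bout; reaching
step 31 closes the bout at 30 steps. Accepted bouts (20–30 steps)
report cadence 60·(n−1)/(t_last − t_first) steps/min. With a single
shank sensor, one detected cycle is one stride; per-leg step counts
double the stride count. The 20-step floor reflects that longer
bouts approach habitual cadence (~110 steps/min in non-frail
walkers); the 30-step cap avoids fatigue confounds without changing
the parameter averages.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed; one global seed fans
out through a spawning `numpy` seed sequence, so stages are
independently reproducible and pipeline reports are byte-identical
across reruns. The test suite and the acceptance script size their
simulations for desk-scale runs: 5-cycle walks for round-trip checks,
161-subject cohorts, 30 permutation replicates for the null-AUC check
(per-replicate SD ~0.06, so the mean carries ~0.012 Monte-Carlo
error), 1000–2000 null simulations for ANCOVA calibration, and 50
cohort replicates for the AUC-ordering check.

## Known limitations

* The generator's waveform family is one plausible morphology; real
  shank-gyro signals vary with footwear, pathology and turning, none
  of which are modelled.
* Spatial gait parameters (stride length, speed in m/s) are not
  computable from a single gyroscope without a biomechanical model
  and are out of scope.
* Printed propulsion durations in reference cohorts (0.7–1.1 s) are
  long relative to typical stance times; the heel-off onset fraction
  is configurable for that reason, and synthetic strides allot a
  correspondingly large share of the stride to the ramp.
* Fried flag generation in cohorts reproduces sign structure, not
  calibrated prevalences; recomputed stages need not match the
  generating labels subject by subject.
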