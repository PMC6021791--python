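# shankgait

Gait analysis from a single shank-worn gyroscope, aimed at frailty
assessment in older adults.

Frailty staging by the Fried phenotype (non-frail / pre-frail /
frail, from five markers: shrinking, weakness, slowness, exhaustion,
low activity) normally needs trained staff and a supervised setting.
The angular velocity of the shank during ordinary walking carries
much of the same information — particularly during the **propulsion
phase**, the heel-off-to-toe-off interval in which the body is pushed
forward. `shankgait` implements the full pipeline that turns a
three-axis shank angular-velocity recording (deg/s, 100 Hz) into a
frailty assessment, for researchers in wearable gait analysis and
digital biomarkers:

* **synthetic data** — seeded gait-cycle and cohort generators with
  exact ground truth, so every downstream stage is testable without
  any recorded data;
* **segmentation** — heel-strike, toe-off and mid-swing by sagittal
  peak detection; heel-off by locating the steepest descending slope
  of the propulsion ramp and walking back to its onset;
* **gait parameters** — per cycle: toe-off speed |ω_z(TO)|, mid-swing
  speed |ω_z(MSw)|, mid-stance speed (range of ω_z over stance),
  propulsion duration t_TO − t_HO, propulsion acceleration
  |Δω_z|/Δt over the ramp, and the speed norm max √(ω_x²+ω_y²);
  aggregated per subject-leg as mean ± SD with CV, requiring at
  least two accepted cycles;
* **Fried phenotyping** — the 4.54 kg shrinking rule plus stratified
  worst-quintile rules for weakness, slowness, exhaustion and low
  activity; staging by flag count (0 / 1–2 / ≥3);
* **cohort statistics** — one-way ANOVA with η², Games–Howell
  post-hoc tests with Cohen's d and mean-difference CIs (all
  computable directly from published group summaries), percent
  differences, ANCOVA adjusting for age/sex/BMI, Spearman
  correlations, pairwise χ²;
* **classifier** — a five-node TanH network over the six parameters
  with 8-fold cross-validation, one-vs-rest ROC/AUC per stage and
  percentile bootstrap AUC intervals;
* **bout monitor** — a wearable-deployment state machine that wakes
  on 3 consecutive steps and analyses unbroken walking bouts of
  20–30 steps.

## Worked example

Simulate a short non-frail walk, segment it, extract the six
parameters, and re-analyse a published-style group-summary table:

```python
from shankgait import synthetic as syn, segmentation as seg, parameters as par
from shankgait.stats import GroupSummary, anova_eta2, games_howell

spec = syn.cycle_spec_for_stage("non-frail")
rec, truth = syn.make_walk_recording([spec] * 5, noise_sd=3.0, seed=1)
events = seg.segment_recording(rec)          # 10 Hz low-pass + peak detection
cycles = par.cycle_parameters(rec, events)
leg = par.aggregate_leg(cycles)
```

which prints (via the obvious loop over `leg.mean/sd/cv`):

```
cycles detected: 4, accepted: 4
              toeoff_speed:   151.47 +/- 4.50  (CV 0.030)
            midswing_speed:   335.61 +/- 2.63  (CV 0.008)
           midstance_speed:   138.43 +/- 4.34  (CV 0.031)
       propulsion_duration:     0.69 +/- 0.01  (CV 0.007)
   propulsion_acceleration:   371.71 +/- 7.26  (CV 0.020)
                speed_norm:   196.91 +/- 2.79  (CV 0.014)
```

Five rendered cycles give four complete heel-strike-delimited cycles
(boundary partials are discarded), and the recovered values sit
within a few percent of the generating targets (149.4, 336.9, 137.6,
0.70, 366.6, 196.4) despite 3 deg/s of sensor noise.

Group statistics run straight from summary statistics — here the
propulsion-duration summaries of a 161-subject cohort staged
49/92/20:

```python
groups = [GroupSummary("non-frail", 49, 0.70, 0.11),
          GroupSummary("pre-frail", 92, 0.83, 0.23),
          GroupSummary("frail",     20, 1.11, 0.46)]
anova_eta2(groups)       # F=20.1, p=1.7e-08, eta^2=0.203
games_howell(groups)
```

```
ANOVA F=20.1, p=1.70e-08, eta^2=0.203
  non-frail vs pre-frail p=0.000  d=0.66  CI [-0.20, -0.06]
  non-frail vs frail     p=0.002  d=1.56  CI [-0.67, -0.15]
  pre-frail vs frail     p=0.038  d=0.99  CI [-0.55, -0.01]
```

η² = 0.20 means stage membership explains 20% of the variance in
propulsion duration — a large effect; frail subjects push off for
0.41 s longer than non-frail on average (d = 1.56).

The same stages are scriptable from the shell:

```sh
shankgait simulate --group frail --n 20 --seed 7 --out recs/
shankgait extract recs/*.csv --out params.csv
shankgait cohort-stats --from-summaries table_right.csv --out report.json
shankgait pipeline --seed 7 --out report.json   # full synthetic cohort run
```

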