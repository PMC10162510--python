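# wantpred

Predicting Wingate anaerobic power outputs from a standard graded exercise
stress test.

## The problem

The Wingate anaerobic test (WAnT) — a 30-second all-out cycle sprint against
a resistance of 0.075 × body mass — is the standard measure of anaerobic
capacity: peak power (PP, the maximal mechanical power in the first seconds)
and mean power (MP, the 30-s average), both in watts. It is exhausting and
rarely performed in clinical settings. A graded exercise test (GXT) on a
treadmill — incremental speed/slope with ECG and heart-rate monitoring but
no gas-exchange measurement — is routine. `wantpred` implements a
computational pipeline that predicts PP and MP from the variables a GXT
actually records: exercise time, treadmill speed and slope, and heart rate,
for tests terminated at 85%, 90% or 100% of age-predicted maximal heart
rate.

It is aimed at exercise physiologists, sports scientists and methodologists
who want either (a) to apply the published prediction equations to their own
GXT data, or (b) to retrain the underlying feature-selection algorithm on a
cohort with measured Wingate outcomes.

## The method

**Features.** For each subject, age-predicted maximal heart rate is
HRmax = 208 − 0.7·age (Tanaka formula). The treadmill state (time, speed,
slope) at the first upward crossing of 85%, 90% and 100% of HRmax is located
by linear interpolation of the heart-rate trace, and predicted oxygen uptake
at that state follows the ACSM running equation

    VO2 [mL/kg/min] = 0.2·speed + 0.9·speed·grade + 3.5

with speed in m/min and grade as a fraction; multiplying by body mass gives
absolute VO2 in mL/min. Together with intensity composites (slope×speed,
slope×speed×time), exercise time, and predicted VO2 at the
anaerobic-threshold surrogate (the minute the protocol first raises the
slope, i.e. the RQ = 1 event), this yields 8 feature families × 3 levels +
age = 25 candidate predictors.

**Training.** Subjects are split 40/30/30 into calibration, test and
validation subsets, stratified on predicted VO2max. On the calibration set a
greedy forward selector builds a multiple linear regression: at each
iteration every remaining candidate is tried and the one minimizing the
residual sum of squares is kept; selection stops before adding a feature
whose relative adjusted-R² improvement is below 0.5% (or negative). The
fitted equation is scored by Spearman rank correlation on the held-out
subsets, and the percent error |y − ŷ|/y × 100 is summarized as mean ± SD
over 100 resampled validation subsets with the model held fixed.

**Published equations.** The six published PP/MP equations at 85/90/100%
HRmax ship as a structured JSON resource (intercepts in watts, coefficients
on z-scored predictors) and can be applied to new cohorts given reference
standardization statistics.

**Synthetic cohorts.** Because the original 93-subject cohort is not
deposited, a generator simulates demographically matched cohorts (40 women,
53 men), protocol-faithful treadmill trajectories, and Wingate outcomes from
a planted linear model plus Gaussian noise — so the whole pipeline is
testable end to end, including exact parameter recovery at zero noise.

## Worked example

Simulate a 93-subject cohort and run the full pipeline:

```python
import wantpred as w
from wantpred.pipeline import format_report

subjects = w.simulate_cohort(w.CohortConfig(seed=1))
report = w.run_pipeline(subjects, w.RunConfig(seed=1))
print(format_report(report))
```

```
wantpred run  seed=1  config=3145c1c136263d5f  n=93

cell        k  rho(val)      p(val)  RMSE[W]        %err
MP@100      2     0.544    2.76e-03    108.9   15.2 ± 6.2
MP@85       3     0.906    3.39e-11     60.9   10.3 ± 2.3
MP@90       3     0.880    7.13e-10     54.1   10.0 ± 2.7
PP@100      2     0.900    7.33e-11     79.9   10.9 ± 2.2
PP@85       3     0.972    8.71e-18     37.8    5.1 ± 1.3
PP@90       2     0.912    1.49e-11     65.3    7.3 ± 1.6
```

Each row is one (outcome, level) cell: `k` selected features, the validation
Spearman rho and p-value, validation RMSE in watts, and the resampled
percent error (mean ± SD over 100 validation subsets). In this synthetic
cohort the planted model lives at the 85% level, so the 85% cells fit best;
cells at other levels recover what transfers through the correlated
features.

The same workflow is available from the shell:

```bash
wantpred simulate --seed 1 --out-prefix data/cohort
wantpred derive   --subjects data/cohort_subjects.csv \
                  --trajectories data/cohort_trajectory.csv --out data/features.csv
wantpred fit      --features data/features.csv --subjects data/cohort_subjects.csv \
                  --outcome pp --level 85 --seed 1 --out data/model.json
wantpred run      --seed 1 --out-dir data/run        # full pipeline
```

Applying a published equation to one subject:

```python
eq = w.load_published_equation("PP", 0.85)       # 644 + 225·z(VO2 abs) − 87·z(VO2 rel) − 26·z(slope·speed·time)
fv = w.derive_feature_vector(subjects[0], 0.85)  # raw feature vector
watts = w.predict_power(eq, fv, stats)           # stats: reference means/SDs
```

Note that the published coefficients apply to z-scored predictors; the
original calibration means/SDs were not published, so absolute predictions
depend on the reference frame you supply (see `docs/methods.md`).

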