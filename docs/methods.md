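# Methods

This note documents the models, conventions and design choices behind
`wantpred`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic validation does and does not
show.

## Feature derivation

**Age-predicted maximal heart rate.** HRmax = 208 − 0.7·age (Tanaka), in
beats/min, never rounded. Submaximal levels are plain fractions:
HR(level) = level × HRmax for level ∈ {0.85, 0.90, 1.00}.

**Level localization.** The trajectory is an ordered sequence of
(time, speed, slope, heart rate) samples with strictly increasing times.
The state at a level is taken at the *first upward crossing* of the target
heart rate, linearly interpolated between the bracketing samples. If the
target is at or below the first sample the first sample is used; if the
trajectory never reaches the target a "level not reached" error names the
level. First-crossing with interpolation is deterministic and well defined
for any nondecreasing heart-rate trace; protocol heart rate is monotone in
expectation, and the synthetic generator enforces monotonicity.

**ACSM running equation and units.** Predicted oxygen uptake is
VO2 = 0.2·speed + 0.9·speed·grade + 3.5 in mL/kg/min, with speed in m/min
and grade a dimensionless fraction (the ACSM handbook convention).
Trajectories store treadmill units — km/h and percent grade — and the
conversion (×1000/60, ÷100) happens inside feature derivation, never at
I/O. Absolute VO2 (mL/min) is relative VO2 × body mass (kg). The intensity
composites keep raw trajectory units: slope×speed is percent·km/h and
slope×speed×time is percent·km/h·min.

**Anaerobic-threshold surrogate.** A plain GXT has no gas exchange, so the
ventilatory threshold cannot be measured. The incremental protocol,
however, raises the treadmill slope when RQ reaches 1, so the first slope
increase is the one AT-aligned event visible in speed/slope data. The
surrogate AT time is therefore the time of the first sample whose slope
exceeds its predecessor's, overridable by an explicit `at_time` input.
VO2-at-AT is recomputed from the interpolated treadmill state at that time
via the ACSM equation. Subjects with neither an explicit `at_time` nor any
slope change get missing AT features; the pipeline drops candidate columns
that are incomplete for part of the cohort.

**Registry.** Eight families per level — HR at level, exercise time,
predicted VO2 (absolute, relative), slope×speed, slope×speed×time,
VO2-at-AT (absolute, relative) — times three levels, plus age: 25
candidates. A fit at one level uses that level's eight families plus age
(9 candidates), reflecting that a test terminated at 85% HRmax only yields
85%-level features. "Maximal intensity" composites are represented by
slope×speed×time, the only additional intensity product appearing in the
published equations. Registry order is fixed and doubles as the
deterministic tie-break order during selection.

## Standardization

All predictors are z-scored with calibration-set statistics using the
sample (n−1) SD; the same statistics are reused unchanged on test and
validation data, so every prediction lives in the calibration frame.
Zero-variance columns raise an error naming the column. Round-tripping
(standardize, then invert with the returned statistics) reproduces inputs
to floating-point precision.

The published equations' coefficient magnitudes (hundreds of watts per
unit of a predictor whose raw scale is thousands of mL/min) are only
dimensionally coherent for z-scored predictors, so applying them requires
reference statistics. The original calibration means/SDs were not
published; absolute predictions from the shipped equations are therefore
reference-frame dependent, and the package requires the caller to supply
the frame explicitly rather than silently assuming one. Intercepts are
read as watts at the standardized origin. In the printed equations,
dash-separated terms are parsed as subtractions, and the two untagged
"Predicted VO2" terms are mapped to the absolute (mL/min) feature by
parallelism with the tagged columns. The units of "time" in the composites
are taken as minutes.

## The greedy selector

Training splits the cohort 40% calibration / 30% test / 30% validation
("train" and "calibration" denote the same subset). The split is
stratified on ACSM-predicted relative VO2max at the fit level: subjects
are ranked, cut into 4 equal-rank bins (the count is a package default;
any ≥1 works), and within each bin membership is drawn at the target
fractions, with per-bin quotas reconciled against global largest-remainder
targets so the three subsets are always disjoint, exhaustive, and
size-correct to within ±1.

Selection is forward-stepwise least squares. At each iteration every
remaining candidate is added in turn to the current model, the ordinary
least-squares fit (intercept always included) is computed, and the
candidate with the smallest residual sum of squares wins; ties break to
the lowest registry index. The calibration adjusted R²,
1 − (1 − R²)(n − 1)/(n − p − 1), is recorded after each addition. The
stopping rule: a candidate is only accepted while its relative adjusted-R²
improvement is positive and at least `min_pct_improvement` (default 0.5%);
when the previous adjusted R² is ≤ 0 any positive gain is accepted. The
first feature is always accepted (with a warning if it explains nothing),
and a safety cap (`max_features`, default 10; also bounded by n − 2)
guarantees termination. The test-set Spearman correlation is recorded as a
diagnostic but never drives selection — no decision rule on it is defined,
and features are never removed once added.

Model quality is reported on the validation subset: Spearman rho with
two-sided p (average ranks for ties), RMSE in watts, and the percent error
|y − ŷ|/y·100. The percent-error distribution holds the fitted model fixed
and draws 100 validation subsets of 30% of the held-out validation pool
without replacement, reporting the mean and sample SD of the per-subset
mean errors. Re-drawing subsets of a fixed held-out pool (rather than
refitting or re-splitting) matches the description of applying the trained
model to repeatedly sampled validation sets, and keeps the quantity a pure
measure of the fixed equation.

All randomness descends from a single root seed through named substreams
(cohort, split, error-reps, one per pipeline cell), so identical seeds and
inputs give bit-identical results and each stage is independently
reproducible.

## Synthetic cohort generator

The generator's purpose is statistical, not physiological: it produces
cohorts whose demographics match the study population, whose trajectories
follow the incremental protocol, and whose Wingate outcomes follow a
*known* linear model so the selector can be checked against ground truth.

* **Demographics** — truncated normals at the published cohort moments: 40
  women (age 26 ± 4 y, mass 60.9 ± 9.8 kg, height 163.8 ± 6.4 cm) and 53
  men (age 29 ± 6 y, mass 75.7 ± 10 kg, height 176.6 ± 6.8 cm), truncated
  at generator policy bounds (age 18–50 y, mass 40–120 kg, height 140–210
  cm). Truncation shifts means slightly (≈ +0.2 y for female age); tests
  compare against the analytic truncated-normal moments.
* **Protocol** — minute-resolution staircase: speed starts at a
  per-subject warm-up end speed (8 ± 1.5 km/h, truncated 5–12) and rises
  1 km/h per minute until the drawn RQ = 1 time (8 ± 2 min, truncated
  3–15), after which speed holds and slope rises 2% per stage for 4 ± 1
  stages (truncated 2–8).
* **Heart rate** — rises from a starting HR (100 ± 8 bpm) to exactly the
  subject's Tanaka HRmax at termination, following a power-law ramp
  (t/T)^γ with a per-subject lognormal exponent (median 0.70, log-SD
  0.25, clipped to [0.4, 1.5]), plus 2 bpm Gaussian jitter, isotonically
  corrected so every level is crossed exactly once. The concave median
  ramp reflects the clinically typical fast early HR rise with a plateau
  near maximum; the per-subject exponent makes the submaximal crossing
  time vary between subjects rather than being a fixed fraction of test
  duration, which matters for the identifiability analysis below.
* **Outcomes** — PP = 644 + 170·z(VO2 abs) − 80·z(VO2-at-AT rel) +
  30·z(time) + N(0, σ) and MP = 478 + 140·z(VO2 abs) − 60·z(VO2-at-AT
  rel) + 25·z(time) + N(0, σ), with independent noise draws and σ = 40 W
  by default; features are taken at the 85% level and z-scored across the
  cohort. The planted families and signs mirror the published equations
  (positive absolute VO2, negative relative VO2-at-AT, positive exercise
  time, intercepts at the printed values), with magnitudes of the printed
  order and PP spread larger than MP.

**Planted-model identifiability.** The candidate registry contains
structurally collinear pairs: absolute and relative VO2 share the crossing
state, the two absolute features share the body-mass factor exactly, HR at
level is an exact affine function of age, and the composites share
slope×speed. A planted combination aligned with the body-mass direction
alone (e.g. a pure absolute-vs-relative VO2 contrast) is mimicked almost
perfectly by the VO2-at-AT absolute feature and cannot be recovered
reliably by any subset selector at n ≈ 100 — the relevant correlation
margins are smaller than their sampling noise. The default planted trio
(+VO2 abs, −VO2-at-AT rel, +time) loads on three distinguishable latent
directions (mass×fitness, AT timing, HR dynamics) and is recovered exactly,
with calibration R² = 1, in every tested noiseless replicate. This is a
property of planted-truth *recovery*, not of fitting: with noise present
the selector is free to choose whichever correlated proxy predicts best,
exactly as stepwise regression behaves on real data.

**What passing tests show, and what they do not.** The synthetic cohorts
validate the machinery — feature derivation, splitting, selection,
termination, evaluation, determinism — under a linear ground truth with
Gaussian noise and protocol-exact trajectories. Real GXT data have
measurement error in heart rate and belt state, non-linear
power–physiology relationships, population structure beyond sex, and an
anaerobic threshold only loosely tied to the slope-increase event. Passing
recovery tests therefore says nothing about the predictive accuracy of the
published equations on new human cohorts, which additionally depends on
the unavailable original standardization frame.

## Numerical choices and degenerate inputs

* OLS via `numpy.linalg.lstsq`; the public `fit_ols` raises on rank
  deficiency, while the greedy inner loop tolerates it (minimum-norm
  solution) so that an exactly collinear candidate is simply never the
  strict SSE argmin.
* An SSE improvement smaller than 1e−12 × SST is treated as a tie (the
  incumbent, lower-index candidate wins).
* Spearman correlation and its two-sided p come from
  `scipy.stats.spearmanr`; constant vectors raise rather than returning
  NaN.
* Percent error is undefined at y = 0 and raises; Wingate power is
  strictly positive so this only guards corrupted input.
* Degenerate configurations (empty cohort, zero-variance target, subsets
  too small to populate, fewer than 2 resampling reps) raise typed errors
  rather than producing silent NaNs; CLI exit codes are 2 for schema
  errors and 3 for numeric/degeneracy errors.

## Problem sizes used in the validation suite

The test suite exercises: exact worked examples (instant); greedy-vs-
exhaustive oracle equivalence on 200 random instances with n ≤ 60 and ≤ 12
candidates; noiseless recovery on 20 cohorts of n = 100; the stochastic
pipeline contract on 100 cohorts of n = 200 at 40 W noise (validation
Spearman > 0.85 in ≥ 90 runs); 10,000 split-contract replicates at n = 93;
and demographic-moment convergence at n = 5,000. These sizes give stable
pass/fail behavior for the statistical contracts while keeping the full
suite fast on a single CPU.

## Known limitations

* The 25-feature registry is reconstructed from the feature families that
  accompany the published equations; the original complete feature
  enumeration was not available, so the registry is configurable.
* The published equations cannot be re-derived (the original cohort is not
  deposited) and their absolute predictions are reference-frame dependent.
* The AT surrogate conflates the RQ = 1 protocol event with the
  ventilatory threshold; on real data with a measured threshold, pass
  `at_time` explicitly.
* Treadmill running only; no cycle-ergometer metabolic equations, no
  breath-by-breath processing, no fatigue-index prediction.
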