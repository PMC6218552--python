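# Methods

## The estimation problem

For each analyzed limb of an ambulatory child with cerebral palsy, two
potential follow-up outcomes exist: the Gait Deviation Index (GDI) the limb
would reach 9–36 months later with a single-event multilevel surgery
(SEMLS), and the GDI it would reach under conservative care only.  The
surgery effect for the limb is the difference of these two quantities; only
one is ever observed.  In retrospective gait-lab cohorts the observed arm is
strongly informative about severity — more affected limbs are likelier to be
operated — so the two arms are not exchangeable and naive between-arm
contrasts are biased.

The package estimates the effect with two arm-specific outcome regressions
fitted on propensity-reweighted data:

* a propensity model `e(x) = P(surgery | x)` (random forest, 100 trees,
  class priors rebalanced to 50/50 so the roughly 61/39 arm imbalance does
  not dominate);
* inverse-propensity weights `w = 1/e(x)` (surgery) or `1/(1 − e(x))`
  (control), with `e(x)` clipped to [0.05, 0.95];
* per arm, on the limbs with follow-up only: l1 feature selection with
  weighted 10-fold cross-validation, then a weighted least-squares refit of
  the selected features in natural units;
* per limb, the estimated effect `Δ̂(x) = ŷ_s(x) − ŷ_c(x)` with separate
  95% prediction intervals for each arm.

Identification rests on the usual observational assumptions: no unmeasured
confounding given the pre-treatment feature set, overlap (enforced
numerically by clipping), and correctly specified linear outcome models
within each arm.  None of these is testable on real data; all of them hold
by construction in the synthetic cohorts used for validation.

## Synthetic cohort generator

The generator produces per-limb tables with the statistical structure the
analysis assumes, plus the hidden truth (both counterfactual outcomes and
the true assignment probability).  Its default parameterization is the
package's reference study condition:

* **Outcome models.** Follow-up GDI in each arm is linear in the
  pre-treatment features with independent Gaussian noise.  The coefficient
  maps are published fitted values for this population — surgery: first-visit
  GDI 0.27, non-dimensional speed 11.50, selective-motor-control score 4.21,
  strength score 5.51, peak ankle plantarflexion moment 1.58, contralateral
  GDI 0.050, knee flexion at initial contact −0.059 °⁻¹-scaled,
  quadriplegia −2.01, intercept 48.03; control: GDI 0.57, SMC 3.71, step
  length 5.67, contralateral GDI 0.096, speed 4.17, intercept 19.99 (GDI
  units per feature unit).
* **Feature spreads.** Each feature's SD is identified from the ratio of the
  published standardized effect to the natural-unit coefficient (averaged
  when both arms constrain the same feature, e.g. GDI: 2.58/0.27 ≈ 9.56 and
  5.40/0.57 ≈ 9.47 → 9.51).  For the binary quadriplegia flag the same ratio
  equals √(p(1−p)), giving prevalence p ≈ 0.226 (lower root).
* **Feature centers** are not identifiable from effect sizes; defaults are
  clinically plausible (GDI 70, contralateral GDI 72, non-dimensional speed
  0.35, non-dimensional step length 0.65, knee flexion at initial contact
  20°, peak plantarflexion moment 0.8 N·m/kg, exam summary scores centered
  at 0) and freely overridable.
* **Correlations.** A deliberately minimal structure: ipsilateral/
  contralateral GDI 0.6 and speed/step-length 0.7, all else 0.  This is
  enough to exercise collinearity in selection without claiming fidelity.
* **Confounded assignment.** Surgery propensity is logistic in the features
  with a negative loading on first-visit GDI (−0.48 per SD) and smaller
  loadings on the other severity markers.  The loadings and the logit
  center (0.55 at the feature means) were calibrated once, by simulation,
  so that (i) control limbs average ≈ 4.4 GDI points above surgery limbs and
  (ii) a held-out random forest classifies assignment with ≈ 67% accuracy —
  the two confounding summaries reported for the real cohort.  Arms are
  assigned by exact-count sampling (rank by propensity minus an independent
  uniform draw), so a 2,333-limb cohort contains exactly 1,424 surgery and
  909 control limbs while each limb's inclusion chance still tracks its
  propensity.
* **Noise.** Residual SDs (4.27 GDI surgery, 7.27 GDI control) were
  calibrated once so each arm's true model explains ≈ 0.41 / 0.40 of outcome
  variance within its own arm under the confounded assignment.
* **Attrition.** Follow-up availability uses per-arm exact-count sampling at
  rates 1,133/1,424 (surgery) and 582/909 (control), so the canonical cohort
  reproduces those retained counts deterministically.  Limbs without
  follow-up still enter the propensity model, never the outcome models.
* **Nuisance features.** Ten independent standard-normal columns
  (`nuisance_01`…`nuisance_10`) with true coefficient exactly zero in both
  arms, to exercise the sparsity machinery.
* A fraction of limbs (75%) share a patient id in bilateral pairs; this is
  bookkeeping realism only — features and noise are drawn independently per
  limb.

What the generator does *not* emulate: raw kinematic or kinetic time
series, item-level physical-exam data, longitudinal multi-visit
trajectories, within-patient correlation between limbs, non-Gaussian feature
distributions, heteroscedastic noise, and any model misspecification.
Passing validation on these cohorts therefore shows the estimation chain is
correct *under its own assumptions*; it cannot show robustness to the many
ways real clinical data violate them.

## Preprocessing operators

* **Non-dimensionalization.** Walking speed is divided by √(g·L) and step
  length by L (leg length, m; g = 9.81 m/s²), removing body-size effects.
* **Mean imputation** fills sporadic missing values with column means of the
  observed entries (observed entries never change).
* **Exam summary scores.** Joint-level strength, selective-motor-control and
  spasticity measurements are noisy but correlated; each modality is
  condensed to the first principal component of the standardized items,
  with missing cells re-imputed each iteration from the rank-1
  reconstruction until scores move less than a tolerance (default 1e-8,
  100 iterations max; non-convergence returns the last iterate with a
  warning).  With complete data this is exactly plain first-PC scoring.
  The exact robust-PCA algorithm used on the original exam data is not
  reproducible from public descriptions; this EM-style rank-1 iteration is
  a declared simplification.  Loadings are flipped so their sum is positive
  ("higher score = more function"); spasticity items are negated before
  scoring so the same convention holds.  Scores are standardized to mean 0,
  SD 1 on the fitting set.

## Numerical choices

* **Selection.** Features are standardized with weighted moments inside the
  lasso only; reported coefficients are natural-unit from the refit.  The
  penalty grid has 100 log-spaced values spanning 4 decades down from the
  smallest penalty that zeroes every coefficient.  The cross-validation is
  weight-aware on both sides (weighted fits, weighted validation MSE).  The
  "sparsest adequate" model is operationalized by the one-standard-error
  rule: the largest penalty whose mean CV error is within one SE of the
  minimum.  All-constant columns are excluded with a warning; fewer rows
  than folds is an error.
* **Refit.** Weighted least squares via sqrt-weight row scaling and a
  least-squares solve; residual variance is weighted RSS over n − p − 1 with
  weights normalized to mean 1 per arm (normalization affects only the RSS
  scale, never coefficients); coefficient covariance is the classical
  σ̂²(XᵀWX)⁻¹, with an HC1-type sandwich available behind a flag since the
  weighted residuals are not exactly homoscedastic.  Rank-deficient designs
  are rejected with the redundant columns named (pivoted QR).
* **Intervals** use the normal quantile (not t; the working sample sizes
  make the difference negligible) and cover an individual limb's outcome:
  half-width z·√(xᵀΣx + σ̂²).
* **Evaluation** is unweighted.  Ties at the GDI-80 threshold count as
  positive (≥, "at least 80").  The ROC sweeps all distinct predicted-GDI
  thresholds; AUC is trapezoidal and equals pairwise concordance with ties
  counted half.
* **Effect flags.** Control limbs with estimated effect ≥ 5 GDI are
  under-treated, otherwise conservatively treated; surgery limbs with effect
  ≤ 0 are over-treated, ≥ 5 appropriately treated, and strictly between 0
  and 5 *indeterminate* — an explicit extra category for the case the
  four-way illustration leaves unlabelled.  No interval is reported for the
  effect difference itself: the two arms' coefficient covariances are
  estimated separately, so a difference interval would require a joint
  covariance the two-regression design does not provide.
* **Determinism.** Every stochastic step takes a seed: cohort generation is
  bit-reproducible (same config + seed ⇒ identical CSV bytes); the 70/30
  split is arm-stratified and fixed; repetition i of the harness uses
  base_seed + i for the forest and the fold shuffle.  Repetition failures
  are logged and skipped; more than 10% of failures aborts.

## Reference experiments and problem sizes

The package validates itself with three simulation studies
(`semlseffect.experiments`), sized so each check has comfortable statistical
power:

* **Coefficient recovery** (also run by `scripts/acceptance.py`): a cohort
  of ≈ 82,600 limbs (so both arms retain at least 20,000 follow-up limbs),
  propensity forest on all limbs, IPW-weighted OLS per arm on the true
  feature set with exactly 20,000 limbs.  Recovered coefficients match the
  encoded ones to Monte-Carlo error (2–3 SE; e.g. SE ≈ 0.004 for the surgery
  GDI coefficient, ≈ 0.46 for the control step-length coefficient, whose
  0.7 correlation with speed inflates its variance).  Standardized effects
  (coefficient × training SD) land a few percent below the encoded
  standardized column because conditioning on the confounded assignment
  shrinks within-arm feature SDs ~2–4% relative to the population values
  the encoding implies.
* **Noise calibration**: a full pipeline pass on a 20,000-limb cohort;
  held-out R² per arm lands within ±0.05 of the configured 0.41 / 0.40.
* **Selection consistency**: 200 repetitions, each a fresh 40,000-limb
  cohort weighted by the generator's own propensities (isolating selection
  behaviour from classifier fitting, and keeping the study cheap); every
  true-model feature with |standardized effect| ≥ 0.5 is kept in > 80% of
  repetitions and every nuisance feature in < 50%.  The 40,000-limb size was
  chosen by a power analysis: the binding feature is the control arm's
  non-dimensional speed (standardized effect 0.50, correlated 0.7 with step
  length), which needs ≈ 6,000 control follow-up limbs for the
  one-standard-error rule to keep it reliably.

## Known limitations

* In-sample random-forest propensities are overconfident (fully grown trees
  partially memorize their own labels), which pushes weights toward
  uniformity within each arm and attenuates the covariate balancing that
  inverse weighting would achieve with the true propensities.  The balance
  diagnostics show this directly: weighting with the generator's true
  propensities removes ≈ 98% of the between-arm GDI gap, while in-sample
  forest weights remove only a modest share.  Coefficient recovery is
  unaffected because the outcome models are correctly specified on
  synthetic data, but on real data (where they are not) the residual
  imbalance matters; stratified balance tables on held-out limbs are the
  honest diagnostic.
* Limbs are modelled as independent units; bilateral patients contribute
  two correlated limbs in reality, and the same patient's limbs may land in
  different split halves.
* The generator's feature centers, correlation block and bilateral fraction
  are plausibility choices, not estimates; quantities that depend on the
  full feature distribution (e.g. the share of limbs with a clinically
  meaningful expected effect) are therefore generator-specific and should
  not be read as clinical estimates.
* The candidate feature list is the generator's own (true features plus
  nuisance columns); the much wider candidate sets of real gait datasets
  make selection harder than these studies exhibit.
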