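# Methods

## Index scoring model

Each HBI component is scored by a piecewise-linear proportional rule on
its own basis: beverage categories as a share of total reported fluid,
total beverage energy as a share of total energy intake, and the fluid
requirement as absolute mL/day.

* adequacy: `points = max_points · min(observed/standard, 1)` — credit
  grows linearly with intake and saturates at the standard;
* moderation: `points = max_points · clip(1 − (observed − standard)⁺ / standard, 0, 1)`
  — full credit at or below the standard, linear decline, zero at twice
  the standard.

The rule is monotone in the healthy direction of every component, which
is the property the index's interpretation rests on ("better compliance
scores higher"); the bounds and monotonicity are enforced by property
tests. The exact per-component standards of the index's source
publication are not reproduced here; the shipped standards are package
defaults chosen under the calibration constraint below, and every
standard, direction and point weight is overridable from YAML with the
variant-level invariants (component points summing to 100 for the
original index and 90 for the adapted one, 5 points each for diet
drinks and alcohol) re-validated on load.

Default allocation (adapted variant, 90 points): water 25 (adequacy,
standard 100% of fluid — i.e. proportional credit for the water share),
SSB 25 (moderation, 15% of fluid), unsweetened coffee/tea 10 (adequacy,
35%), low-fat milk 10 (adequacy, 35%), full-fat milk 5 (moderation,
10%), 100% juice 5 (moderation, 6%), total beverage energy 5
(moderation, 12% of energy), fluid requirement 5 (adequacy,
2000 mL/day). The original variant adds diet drinks and alcohol
(moderation, 5% of fluid, 5 points each). Both excluded components are
treated as moderation: they are capped at 5 points and lower intake
scores higher, which matches their role in a beverage-quality index and
is configurable.

## Sarcopenic-obesity classifier

Within-sample quintile rule: SO requires SMM ≤ P40, FM ≥ P60 and
BMI ≥ 30 kg/m², with P40/P60 the linear-interpolation sample quantiles
of the analysed (post energy-filter) sample. Both comparisons are
inclusive so tied or degenerate data classify rather than drop; on
continuous data the inclusive convention changes nothing (the P40
cutpoint is almost surely not an observed value). BMI ≥ 30 is retained
as an SO criterion even though cohort inclusion starts at BMI ≥ 25 —
the phenotype requires obesity, the cohort merely overweight. A hook
accepts external reference cutpoints for populations where
within-sample quintiles are not appropriate.

## Association models

Exposure quartiles default to the fixed score cutpoints 63/65/68 with
half-open intervals right-inclusive at the top (63 → Q2, 65 → Q3,
68 → Q4); data-driven sample quartiles are available. Logistic models
are fitted by Newton MLE (|Δ loglik| < 1e-8, ≤ 100 iterations), with a
BFGS fallback when the Hessian goes singular under separation.
Separation is flagged when any coefficient exceeds 15 in absolute
value; separated or non-converged models are reported with NaN odds
ratios and `reportable = False` instead of meaningless Wald bounds.
Odds ratios use Wald intervals `exp(β ± z·SE)`, z = 1.959964 at 95%,
matching the conventions of mainstream epidemiology software. The
trend test replaces the quartile factor with each participant's
within-quartile median score and reports the Wald p of that single
regressor — one of several common conventions; quartile-rank scoring
would be an alternative. ANCOVA adjusted means are model predictions at
the grand covariate means with a partial-F test of the quartile
dummies; with no covariates this reduces exactly to one-way ANOVA.
Education (4 levels, reference illiterate) and economic class
(3 levels, reference poor) are dummy-coded with first-level reference;
economic class is derived from the 0–9 score as poor 0–3, moderate
4–6, good 7–9. Missing data are handled complete-case per model with
the per-model n logged.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not any real participant:

* marginals matched to the study population — age 36.18 ± 8.44 y
  (truncated 18–56), BMI 30.79 ± 4.17 kg/m² (truncated at the ≥ 25
  inclusion bound, with the underlying location/scale solved so the
  *truncated* moments match), FM 33.42 ± 8.11 kg, SMM 25.7 ± 3.4 kg,
  energy 2600 ± 760 kcal/day, activity gamma with mean
  1050 MET-min/week;
* body composition regresses positively on BMI (FM slope 1.6, SMM
  slope 0.55 kg per kg/m²), with residual variances shrunk so the
  marginal SDs stay on target whatever effect is injected;
* beverage intakes are gamma distributed (non-negative, right-skewed,
  the standard shape for consumption data) with per-category means and
  shape parameters; a single latent standard-normal factor H shifts
  each category's log-mean by its loading (positive for water,
  coffee/tea, low-fat milk; negative for SSB) and shifts SMM by
  +`delta_smm`·H and FM by −`delta_fm`·H. Defaults
  `delta_smm` = 1.0 kg, `delta_fm` = 1.5 kg per unit H — a moderate
  protective effect; `set_effect(params, 0, 0)` gives the exact null;
* alcohol intake is identically zero by default (the target population
  reports none), diet drinks are near-zero — which is precisely why the
  adapted 0–90 variant exists;
* total beverage energy derives from fixed energy densities
  (SSB 0.40, 100% juice 0.46, full-fat milk 0.61, low-fat milk
  0.42 kcal/mL); total fluid is the sum of category intakes.

Beverage means, shapes and the component standards were calibrated
jointly, once, so the scored adapted HBI lands near 65 ± 4.4 with all
four fixed quartiles populated, and the emergent SO prevalence sits
near 7% (the quintile rule makes prevalence emergent, bounded above by
the 40% low-SMM share intersected with the BMI ≥ 30 share).

What the generator does **not** emulate: FFQ measurement error and
item-level structure, seasonal intake variation, the joint household
structure of socio-demographics, and any nutrient co-consumption
beyond beverage energy. Passing tests therefore demonstrate that the
pipeline recovers the structure it assumes — they do not validate the
index against real dietary behaviour.

## Numerical choices

* Quantiles: linear interpolation of order statistics (the common
  statistical-software default); convention isolated in one function.
* Energy filter bounds inclusive (exclusion is strictly outside
  500–3500 kcal/day).
* Wald (not profile-likelihood) intervals.
* Degenerate inputs: n < 5 refuses quintile classification; a single
  outcome class refuses logistic fitting; empty contingency tables and
  empty quantile inputs raise; groups of < 2 observations are excluded
  from ANOVA with a warning; rank-deficient designs raise naming the
  collinear columns.
* Determinism: one `numpy` Generator seeded from the params; a fixed
  generation order; identical run-configs give byte-identical CSVs.

## Problem sizes

The replicate suites run at n = 2000 × 100 seeds (null calibration:
CI coverage of 1.0 and the size of the trend test) and
n = 5000 × 50 seeds (effect recovery: monotone declining median ORs) —
sizes at which the crude model is comfortably estimable while the full
suite completes in well under a minute of fitting time. The worked
example runs at the study scale (n = 210), where the fully adjusted
model genuinely separates; this is reported, flagged, and is itself an
accurate reproduction of how such models behave at ~11 events.

## Known limitations

* The per-component standards are calibration defaults, not the source
  index's published standards; analyses of real cohorts should override
  them from the source publication via the YAML config.
* The latent single-factor mechanism is the minimal structure that
  produces a beverage-pattern/body-composition association; real
  confounding is richer (diet, activity and SES correlations are only
  partially represented).
* Quintile cutpoints from the analysed sample make SO prevalence
  sample-relative; external-cutpoint mode exists but no reference
  tables ship with the package.
* The adapted 0–90 score is not rescaled to 0–100; the fixed quartile
  cutpoints 63/65/68 presuppose the 0–90 scale.
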