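# hbiso

Beverage-quality scoring and sarcopenic-obesity association analysis for
cross-sectional cohorts of overweight and obese women — with a calibrated
synthetic cohort generator so the whole pipeline can be exercised and
validated end to end without access to participant-level data.

## The problem

Sarcopenic obesity (SO) is the joint presentation of low skeletal muscle
mass (SMM) and high fat mass (FM) in people with obesity. In cohorts
without external reference cutoffs it is commonly phenotyped
within-sample:

```
SO  =  (SMM in the two lowest cohort quintiles)
     ∧ (FM  in the two highest cohort quintiles)
     ∧ (BMI ≥ 30 kg/m²)
```

The **Healthy Beverage Index (HBI)** summarises how closely a person's
beverage consumption matches healthy-beverage standards across eight
beverage categories (water, unsweetened coffee/tea, low-fat milk,
full-fat milk, 100% fruit juice, sugar-sweetened beverages, diet drinks,
alcohol) plus total beverage energy and fluid adequacy. The original
index ranges 0–100; the **adapted variant** used in populations where
diet drinks and alcohol are essentially absent removes those two
components (5 points each), giving a 0–90 range.

`hbiso` implements the full analysis chain:

1. **simulate** — synthetic cohort with the study's marginal
   distributions (age 36.18 ± 8.44 y, BMI 30.79 ± 4.17 kg/m² truncated
   at the BMI ≥ 25 inclusion bound, FM 33.42 ± 8.11 kg, …), gamma
   beverage intakes, and a latent "healthy beverage pattern" factor H
   that shifts beverage intakes and body composition simultaneously
   (+`delta_smm`·H kg muscle, −`delta_fm`·H kg fat; both zero = null).
2. **filter** — exclude implausible energy reporters (< 500 or
   > 3500 kcal/day, bounds kept inclusive).
3. **score** — component-wise piecewise-linear HBI: adequacy components
   earn `max_points · min(observed/standard, 1)`; moderation components
   earn full points at or below the standard, declining linearly to
   zero at twice the standard.
4. **classify** — SO from within-sample SMM/FM quintile cutpoints
   (inclusive at P40/P60) plus BMI ≥ 30.
5. **associate** — HBI quartiles at the fixed cutpoints 63/65/68
   (data-driven quartiles optional); crude and adjusted binary logistic
   regression (model 1: age, energy, physical activity; model 2:
   + education, economic status), Wald odds ratios
   `exp(β ± 1.96·SE)`, and a median-score trend test.

## Worked example

The numbered scripts under `analysis/` run the study-scale analysis
(n = 210, seed 1) and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_score_beverages.py
python analysis/03_classify_sarcopenic_obesity.py
python analysis/04_association_models.py
python analysis/05_calibration_replicates.py
```

Output of steps 2–4:

```
energy filter: kept 195, excluded 15
HBI (adapted, max 90): 65.20 +/- 4.95
quartile occupancy (cutpoints 63/65/68): {'Q1': 28, 'Q2': 29, 'Q3': 104, 'Q4': 34}
cutpoints: SMM P40 = 25.02 kg, FM P60 = 35.90 kg
SO cases: 11  prevalence: 5.6%
odds of sarcopenic obesity by HBI quartile (Q1 reference):
   crude Q2: OR 0.44 (95% CI 0.07-2.65), p=0.37, p-trend=0.03
   crude Q3: OR 0.24 (95% CI 0.06-1.03), p=0.05, p-trend=0.03
   crude Q4: OR 0.18 (95% CI 0.02-1.73), p=0.14, p-trend=0.03
  model1 Q2: OR 0.62 (95% CI 0.10-4.03), p=0.62, p-trend=0.09
  ...
  model2 Q3: OR nan ...  [non-reportable: separation/non-convergence]
largest protective contrast: crude Q4, odds reduced by 82% vs Q1
```

Reading this: the scored index lands near its calibration target
(65 ± 4.4); about 6% of the women are sarcopenic-obese; women in the
top beverage-quality quartile have 0.18 times the odds of SO of the
bottom quartile in the crude model (a wide CI — only 11 cases). The
fully adjusted model *separates* at this sample size (education strata
with zero cases) and is flagged non-reportable rather than printed with
meaningless confidence bounds — the expected behaviour of a
10-parameter logistic model fitted to 11 events.

Step 5 checks calibration across replicates: under the null generator
the crude Q4-vs-Q1 confidence interval covers 1.0 in 19/20 replicates,
and with the default protective effect the median crude OR declines
monotonically across quartiles (Q2 0.64, Q3 0.36, Q4 0.15 at n = 5000).

The same pipeline runs as a CLI (`hbiso simulate|score|classify|
associate|run`) driven by a YAML run-config, writing a manifest with
config hash, per-stage row counts and cutpoints; identical configs give
byte-identical outputs.

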