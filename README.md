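# cdvar

**Within-person variability, determinants, and measurement-error
attenuation of urinary cadmium biomarkers.**

Urinary cadmium (U-Cd) is widely used as a biomarker of long-term
cadmium body burden in environmental epidemiology. But a biomarker is
only as good as its repeatability: if a large share of its variance is
within-person noise, a single measurement misclassifies exposure and
biases health-effect estimates toward the null. `cdvar` packages the
full analysis chain for this problem — aimed at exposure scientists and
epidemiologists planning or interpreting biomarker-based studies:

- a **seeded synthetic-cohort generator** (women with repeat 24-hr urine
  collections, questionnaire covariates, FFQ responses, and planar GIS
  layers) so the entire pipeline runs and is testable without any real
  data;
- **biomarker preprocessing**: substitution of non-detects by
  LOD/√2, creatinine adjustment (µg/g), 24-hr output (µg/day),
  natural-log transform, GM/GSD summaries;
- **exposure metrics**: FFQ × contaminant-table dietary Cd with caloric
  plausibility exclusions, traffic density (VKT/km² in a 300-m buffer
  with exact line–circle clipping), industrial emissions within 5 km,
  census-tract air linkage, Du Bois body surface area, pack-years and
  passive intensity-years;
- **reliability analysis**: REML variance components of the one-way
  random-intercept model on ln U-Cd, the intraclass correlation
  ICC = σ²_b/(σ²_b+σ²_w), the variance ratio λ = σ²_w/σ²_b, and the
  attenuation of a logistic slope estimated from *n* replicate
  measurements,

  β_E = β_T / (1 + λ/n),  % bias = −100·λ/(n+λ),

  verified by a logistic case–control Monte-Carlo simulation;
- **determinants models**: Kruskal–Wallis screening, age-adjusted trend
  tests, random-intercept mixed models with backward elimination
  (p < 0.1, environmental/dietary terms forced), percent-change
  reporting ([exp(β)−1]×100), cumulative R², participant-level 10-fold
  cross-validation, and the post-cessation decay of U-Cd among former
  smokers.

## Worked example

```bash
python examples/reliability_attenuation.py
```

prints, for the default 296-woman cohort at seed 1:

```
between-person variance: 0.410
within-person variance:  0.359
ICC = 0.53   variance ratio lambda = 0.88

closed form, lambda = 1.0, true OR 2.0:
  n=1: observed OR 1.41  (50% attenuation of the log-OR)
  n=2: observed OR 1.59  (33% attenuation of the log-OR)
  n=4: observed OR 1.74  (20% attenuation of the log-OR)

simulated case-control, single measurement: mean observed OR 1.39 (95% MC CI 1.38-1.40)
```

Reading: about half the log-scale variance of U-Cd in this synthetic
cohort is within-person noise (ICC ≈ 0.5, λ ≈ 1). At that reliability, a
case–control study that characterises exposure with one 24-hr sample
would see a true odds ratio of 2.0 as roughly 1.4 — the Monte-Carlo
simulation reproduces the closed-form prediction. Averaging two or four
collections per subject cuts the bias to 33% and 20%.

Other entry points: `examples/simulate_cohort.py` (cohort and biomarker
summaries), `examples/exposure_metrics.py` (GIS/dietary metrics on a
hand-built scene), `examples/determinants_model.py` (mixed model with
elimination and CV), `examples/full_pipeline.py` or the `cdvar run`
command (everything, writing plain-text artifacts to a run directory).

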