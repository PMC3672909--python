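# Methods

## The biomarker model

Urinary cadmium concentrations are treated as log-normal. For
participant *i* at collection occasion *s* the generator draws

    ln Cd_is = mu + sum_k beta_k (x_ik − x̄_k) + b_i + e_is,

with person intercept `b_i ~ N(0, sigma2_between)` and occasion noise
`e_is ~ N(0, sigma2_within)`. Covariates are centred, so the geometric
mean of generated concentrations is `exp(mu)` whatever effects are
configured. The same two-component structure is what the reliability
module estimates: the intraclass correlation
`ICC = sigma2_b / (sigma2_b + sigma2_w)` is the share of biomarker
variance that is stable within a person, and the variance ratio
`lambda = sigma2_w / sigma2_b` drives measurement-error attenuation.

With exposure measured as the mean of *n* replicates, the expected
logistic slope in a case–control study shrinks by the classical factor

    beta_E = beta_T / (1 + lambda / n),
    % attenuation bias = (beta_E − beta_T)/beta_T × 100 = −100 lambda/(n + lambda).

For reporting, the variance ratio is rounded to one decimal before the
multi-sample computations: with components 0.221/0.216 the unrounded
ratio 1.023 would print a 34% two-sample bias where the conventional
presentation (ratio "1.0") prints 33%.

## Generator defaults and what they emulate

The defaults describe a low-exposure cohort of middle-aged women:

| parameter | default | meaning |
|---|---|---|
| n_participants | 296 | cohort size |
| repeat_fraction | 141/296 | share with a second 24-hr collection, 3/6/9 months later |
| sigma2_between / sigma2_within | 0.216 / 0.221 | residual log-scale variance components |
| mu_log_cd | ln 0.27 | geometric-mean U-Cd, µg/L |
| lod | 0.1 µg/L | assay detection limit; non-detects substituted by LOD/√2 |
| creatinine | GM 0.71 g/L, GSD 1.6 | 60/40 person/occasion split of log variance |
| volume | GM 1.7 L/day, GSD 1.35 | 50/50 split |
| dietary intake | GM √(7.9·14) µg/day, log-sd ln(14/7.9)/1.349 | quartiles sit at ≈7.9 and 14 µg/day |

Default covariate effects (log-scale, centred) correspond to +15% U-Cd
per 0.1 g/L creatinine, +1.4%/year of age, +1.1% per pack-year, −4.6%
per pregnancy, −16% per alcohol category, +0.2% per passive
intensity-year among never-smokers, and −1.5% per year since quitting
among former smokers. Environmental and dietary metrics carry no effect
by default, mirroring a population in which tobacco smoke is the only
detectable non-dietary source; they are forced into final models anyway
(see below). Under these defaults the fixed effects explain roughly 40%
of ln U-Cd variance, dominated by creatinine (dilution) and age.

The repeat subset has a deterministic size, `round(repeat_fraction·n)`,
drawn by a seeded permutation: at the defaults exactly 141 of 296.
Repeat intervals are uniform over {3, 6, 9} months with no drift by
default (a per-month log drift is configurable); reliability is assumed
exchangeable across intervals.

Geography is a 60×60 km planar region in km coordinates — at buffer
radii of 0.3–5 km the planar approximation is innocuous and avoids any
geodesy dependency. Road segments are placed within 250 m of a seeded
~66% of residences (so ~a third of participants have zero traffic
density), with AADT capped so that no 300-m-buffer density exceeds
427,000 VKT/km²; facilities are sparse point sources with heavy-tailed
annual emissions capped at 1,760 kg, leaving most residences with none
within 5 km; each 5-km census tract gets an air concentration in
0.05–0.65 ng/m³. FFQ responses are constructed top-down: a log-normal
per-participant intake target is split across items by a Dirichlet draw
and converted to servings/day given portion categories, so the intake
distribution is controlled exactly while item-level structure remains
realistic enough to exercise the scoring code, including caloric
plausibility exclusions (<600 or >5,000 kcal/day) and a small fraction
of missing questionnaires.

What the generator does **not** emulate: assay batch effects and drift,
real street-network topology, spatial correlation between emissions and
traffic, seasonality of diet, iron status, and any non-log-normal shape
of the true U-Cd distribution (the real lower tail appears thinner than
log-normal; see "Numerical behaviour"). Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
fidelity of any particular real cohort.

## Estimation choices

**Variance components.** REML via a one-way random-intercept mixed
model (statsmodels `MixedLM`). REML rather than ML because component
estimates are unbiased at small n and, on balanced data with interior
estimates, coincide with the one-way ANOVA method-of-moments estimator —
which the test suite uses as an independent oracle (A:{1,3}, B:{5,7}
gives σ²_w = 2, σ²_b = 7, ICC = 7/9). Participants with a single sample
are retained; they inform the total variance. Boundary estimates are
truncated at zero; λ is undefined (NaN) when σ²_b = 0.

**Case–control simulation.** True exposure is standardized
(X ~ N(0,1)) and the true log-OR is per SD of X, so the simulation is
scale-free. Case status comes from a logistic model with intercept 0
(marginal prevalence ≈ ½); arms are filled by rejection-free batch
sampling; the observed exposure adds N(0, λ/n) noise; the slope is
refit by ordinary logistic regression and summarised as the
exponentiated mean over replicates. At large effect sizes the
simulation sits very slightly below β_T/(1+λ/n) because the residual
exposure distribution given the noisy measurement makes the true
conditional model mildly non-logistic; at the scales used here the
difference is within a percent of the odds ratio and both round to the
same printed value.

**Mixed determinants models.** Outcome is ln U-Cd with creatinine as a
covariate (not as a divisor of the outcome), REML estimation, Wald
tests. Backward elimination removes one non-forced term per iteration —
the largest p, ties broken toward the later position in the declared
order — until all non-forced p < 0.1; the dietary and environmental
metrics are always retained. Scales follow the reporting conventions:
creatinine per 0.1 g/L, air per 0.1 ng/m³, traffic and emissions per
10-fold change (log₁₀, zeros mapped to half the smallest positive
value — a configurable convention, since a log scale is otherwise
undefined at zero), alcohol as one ordinal slope over {0, 1, 2}. Age is
rescaled so the youngest participant is zero; this moves only the
intercept, which the suite verifies by refitting under both codings.

**R² for a mixed model** has no single definition. Here it is the
proportional reduction in total residual variance (σ²_b + σ²_w) against
the intercept-only model, accumulated term by term in the declared
order. The nested sequence is fit by ML rather than REML: the ML
profile likelihood can only improve as terms are added, which keeps the
cumulative sequence monotone, whereas REML's degrees-of-freedom
correction can dip by a few thousandths when a null term enters. The
squared observed–fitted correlation is reported alongside for
transparency. Final-model coefficients and components are still REML.

**Cross-validation** partitions participants, never samples, so repeat
collections stay together; each fold refits the final model on the
remaining ~90% and reports coefficients and R².

**Years since quitting** are recorded as of a questionnaire predating
collection and brought forward by +3 years; the offset shifts only the
intercept of the decay model, which is tested explicitly.

## Numerical behaviour and edge cases

- LOD substitution applies strictly below the limit; at-LOD values are
  detects. The substitution compresses the lower tail: in the
  equal-components recovery experiment (141 pairs, σ² = 0.22 each,
  GM 0.27 µg/L) ≈6% of draws fall below 0.1 µg/L and the mean recovered
  ICC is ≈0.494 versus 0.499 when the GM is set far above the LOD — an
  artifact of the substitution step itself, not of the estimator.
- Traffic clipping is exact line–circle intersection (quadratic roots
  per segment), not polygon-buffer approximation, and the density
  divides by the exact πr² (0.2827… km² at 300 m, printed 0.28).
- Rank-deficient model designs are rejected with the offending term
  named; a constant or age-collinear screening predictor is likewise
  rejected rather than silently fit.
- The Du Bois BSA height exponent is configurable (default 0.725, the
  canonical value, reproducing ≈1.7–1.8 m² for this population); the
  variant 0.275 seen in parts of the exposure literature is a
  transcription error and is supported only as an explicit option.
- All randomness flows from a single root seed through named
  substreams (cohort / samples / geography / ffq / contaminants), so
  identical configurations are byte-identical and each stage is
  independently reproducible.

## Problem sizes

The test suite and the acceptance script run everything at the sizes
the analyses describe: 296 participants (141 with repeats) for
pipeline-level checks, 141 pairs × 200 replicates for ICC recovery,
5,000+5,000 subjects × 200 replicates for the case–control simulation,
5,000 participants for generator moment-recovery, and 900–1,500
participants where a test needs comfortable power for parameter
recovery. Multi-facility emission totals are summed over all in-radius
facilities (not nearest-only) — the alternative convention would only
lower the categorised exposure of multiply-exposed residences.

## Known limitations

- The bivariate screen (p < 0.2) that historically precedes stepwise
  selection is available (`screen_variable`) but the default elimination
  starts from the full declared term list; the candidate list is
  configurable.
- Interval-stratified reliability is estimable with the provided
  tools, but no interval effect is generated by default, so those
  stratified ICCs are exercised only structurally.
- Measurement-error *correction* (regression calibration, SIMEX) is out
  of scope; the package quantifies bias, it does not undo it.
- The synthetic cohort matches marginal distributions, not the joint
  correlation structure of a real population (e.g. smoking and alcohol
  are drawn independently).
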