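# Methods

## Estimand and case definitions

For each condition the estimand is the share of people *with disease* who
are undiagnosed, where "disease" is operationally defined by the survey
instruments: a person has disease when they show clinical signs (a
measurement crossing the screening threshold) **or** self-report a
diagnosis, and is undiagnosed when they show signs without a self-report.
The thresholds and their strictness are part of the definition:

| condition    | signs variable          | rule            | diagnosed rule |
|--------------|-------------------------|-----------------|----------------|
| hypertension | systolic BP (mm Hg)     | strictly > 140  | point-in-time self-report |
| diabetes     | HbA1c (mmol/mol)        | ≥ 48            | point-in-time self-report |
| depression   | SF-12 MCS (score)       | ≤ 42            | ever-reported across waves |

A diagnosed person currently below the signs threshold still counts as a
disease case (outcome 0); remission is not modelled. Rows with a missing
measurement and no diagnosis are dropped with a logged count — their disease
status is unknowable — rather than treated as signs-absent. For depression
the diagnosed flag is carried forward across a person's panel waves: once
reported, reported thereafter.

Six age bands are used (18–29, 30–49, 50–59, 60–69, 70–79, 80+); together
with 2 sexes, 5 IMD quintiles and 9 regions they define the 540 population
segments all predictions are made for.

## The undiagnosed-fraction model

Among disease rows, the indicator of being undiagnosed follows a logistic
model with fixed main effects for age group, sex, IMD quintile and region, a
linear year trend centred at 2011, and a subset of the ten two-way
interactions among those five variables. Fitting maximises the weighted
log-pseudo-likelihood Σᵢ wᵢ[yᵢ log pᵢ + (1−yᵢ) log(1−pᵢ)] by Newton
iteration with step-halving; survey weights are normalised to mean one
before fitting so the AIC behaves like an n-sized quantity (the AIC under
survey weights is otherwise scale-dependent; this is a documented
convention, not survey-design-based inference). The coefficient covariance
is the inverse of the weighted information matrix at the optimum —
model-based, not Taylor-linearised design-based, which is a stated
non-goal.

Interaction selection is bidirectional stepwise by AIC: starting from the
full two-way model, every single-term drop and add is evaluated each step,
the best accepted while it lowers AIC, ties broken toward the smaller model.
Main effects are never dropped. The year trend can join the droppable set
(used for hypertension, whose truth carries no time trend); it may only be
dropped while no selected interaction involves year. If the full starting
model fails (quasi-separation in sparse cells at small n), selection
restarts from the main-effects model with a logged warning and proceeds by
adds. Each accepted step strictly lowers AIC, so the selection path is
monotone. Complete separation and non-convergence raise explicit errors.

The fitter is a hand-written IRLS rather than a GLM-library call because the
stepwise loop needs on the order of a hundred warm-started refits per model;
warm starts from the incumbent coefficients cut each refit to 2–4 Newton
iterations. The test suite cross-checks coefficients, covariance and
log-likelihood against statsmodels GLM (equal and frequency weights) to
1e-8.

Goodness of fit uses the Hosmer-Lemeshow statistic on weighted deciles of
predicted risk, Σ (O−E)²/(E(1−E/n)) against chi-square with g−2 df; when
there are fewer distinct predictions than groups the group count is reduced
with a warning. Its null rejection rate is verified by simulation in the
tests. (The depression fit on panel data can fail this test: person-waves
are correlated and the pseudo-likelihood treats them as independent, so both
the HL test and the AIC are liberal there — consistent with the depression
model retaining most interactions. The confidence intervals for depression
are accordingly somewhat narrow; the recovery tests bound the practical
consequence.)

## Predictions and national summaries

Segment predictions evaluate both models on all 540 segments per year.
Uncertainty comes from parametric simulation: n_sim (default 10 000)
coefficient vectors drawn from N(β̂, Σ̂), pushed through the inverse logit,
percentile intervals taken — the method is a documented substitute for
whatever interval method produced the published figures, which is not
stated. Mean adjusted predictions fix a focal variable at a level for every
observed row, predict, and take the survey-weighted mean (the
"marginaleffects"-style summary), with intervals from the same draws; a test
pins this to the explicit row-by-row counterfactual average at 1e-10.

The national estimate weights each segment's P(undiagnosed | disease) by
population count × P(disease), the latter from a companion prevalence model
(outcome: signs or diagnosis, full survey). By default the prevalence model
uses main effects + year only: it only supplies weights, and its interaction
structure moves the national estimate by far less than sampling noise at
these sample sizes; full stepwise selection for it is available via
`PipelineOptions.prevalence_stepwise`. Intervals propagate paired draws from
both models through the same weighting. With a time-constant model
(hypertension) the summary pools numerator and denominator over 2011–2019.

## Synthetic-data generator

The generator emulates the structure the analysis assumes, with ground truth
recorded for recovery testing. A person in segment s and year t has disease
with probability expit(η_dis(s,t)) and, given disease, is undiagnosed with
probability expit(η_und(s,t)); both linear predictors are named coefficient
maps using the same column vocabulary as the fitted models, so truth and
estimate are directly comparable.

* **Cross-sections (diabetes, hypertension):** 35 000 respondents per run,
  segment drawn from a default mix (uniform over sex, IMD and region; adult
  age shares 0.20/0.33/0.16/0.14/0.11/0.06), year uniform over 2011–2019,
  log-normal survey weights (σ = 0.3) normalised to mean one.
* **Panel (depression):** 50 000 persons entering at a uniform year with
  per-wave retention 0.78 (mean observed waves ≈ 3, matching the emulated
  panel's person-year/person ratio). Latent disease is persistent within a
  person, drawn at entry; the per-person diagnosis time comes from a single
  uniform draw u: the person is undiagnosed at year t iff
  u < P(undiagnosed | s, t). When that probability is non-increasing in t
  (true of all shipped truths) this reproduces the per-year marginal exactly
  while making the self-report flag monotone — the ever-diagnosed
  carry-forward. This is why the depression disease model carries no year
  term: wave-level prevalence then matches the entry-year draw for every
  calendar year.
* **Measurements:** a case's measurement lands on the signs side of the
  threshold with probability `screening_sensitivity` (non-cases with
  1 − `screening_specificity`), uniform within the implied side. Both
  default to 1.0: the estimand is defined *by* the screening rule, so the
  generator's latent status is "would screen positive or be diagnosed";
  the knobs exist to exercise imperfect-instrument sensitivity analyses
  (e.g. the MCS threshold and PPV layers), not as base conditions.
* **Population:** 191 CCGs in contiguous region blocks, 8 LSOAs per CCG
  cycling through the five IMD quintiles (so every region × IMD cell is
  populated), national total 191·8·12·2000 ≈ 36.7 million allocated to
  segments multinomially by the segment mix and spread across eligible
  LSOAs. QOF-like tables add truncated Gaussian noise to each area's true
  diagnosed prevalence. Adjacency is a ring plus half-way chords: symmetric,
  connected, degree ≥ 2.
* **Reproducibility:** one root seed; every generator and pipeline stage
  derives a named 31-bit substream from it (SHA-256 of "seed:stage"), so a
  whole run is reproducible from a single integer and regeneration is
  byte-identical.

What the generator does **not** emulate: household clustering, informative
nonresponse/attrition, realistic weight construction, comorbidity
correlation between conditions, measurement error beyond the threshold
mechanism, or real LSOA geography. Passing recovery tests therefore shows
the pipeline's arithmetic and selection machinery are sound under the
assumed data-generating process, not that the published figures are correct
for England.

## Calibration

For recovery runs the undiagnosed model's intercept and year slope are
solved (Newton/`fsolve`, residuals < 1e-9) so that the population-weighted
truth Σ P_s p_dis p_und / Σ P_s p_dis equals the anchored national figures:
diabetes 26% (2011) → 22% (2019), hypertension 23% pooled with no time
trend, depression 68% (2011) → 64% (2019). Segment-level effects are fixed,
field-realistic choices (hypertension underdiagnosis higher for men and
lower in deprived areas; depression the reverse with a U-shaped age
pattern; diabetes nearly flat) — the calibration adjusts only the two
solved parameters, so the target is an exact property of the truth, not of
any fitted model. Disease prevalence structures use strong age gradients
for the cardiometabolic conditions and a mild deprivation gradient
throughout, giving roughly 4 500 (diabetes), 12 000 (hypertension) and
31 000 (depression) disease rows per run.

## Microsimulation

Person-level Bernoulli flags are replaced by distributionally identical
cell-level draws: per LSOA × age × sex cell, n_dis ~ Binomial(count, p_dis)
then n_und ~ Binomial(n_dis, p_und), independent across conditions. Cells
aggregate to CCGs; 200 replicate draws give a Monte-Carlo percentile
interval per area. Counts are conserved exactly from cells to areas to the
national total within every replicate. An area with zero drawn disease count
reports a missing proportion and a flag, never 0/0.

## Spatial test

Global Moran's I, I = (n/S₀)·(Σᵢⱼ wᵢⱼ zᵢ zⱼ)/(Σᵢ zᵢ²), on the per-area
2011→2019 change in proportion undiagnosed, with row-standardised binary
adjacency weights by default (adjacency is supplied as a file so real
geographies can be swapped in). Significance is by random relabelling with
the plus-one estimator, two-sided on |I| by default; constant inputs raise a
zero-variance error rather than returning NaN. Two or more areas are
accepted (the two-area antithetic case gives I = −1 exactly). Note that on
the synthetic geography the change maps are strongly clustered by
construction — model-driven change varies by region and IMD, and the ring
adjacency follows the region blocks — so small p-values there characterise
the fixture, not the method's null behaviour, which is verified separately
on iid values.

## Sensitivity layers

* `undiagnosed_from_prevalence`: (total − diagnosed)/total per area, with
  diagnosed > total clamped to 0 under a warning (how such areas were
  handled originally is not stated) and total = 0 flagged as undefined.
* `ppv_adjusted_fraction`: with U the apparent undiagnosed share and PPV the
  screen-positive predictive value, adjusted = PPV·U/(PPV·U + (1−U)).
  Misclassification is applied only to the screen-positive-without-report
  group; self-reports are taken at face value. At U = 0.64–0.66 and
  PPV = 0.48 this gives ≈ 0.46–0.48.
* Alternative MCS threshold: the depression pipeline re-runs end to end with
  a stricter (lower) cut; the shipped analysis uses 38, a config choice
  (no canonical alternative value is asserted). Lowering the cut can only
  shrink the signs set (subset property, tested).

## Numerical choices and limitations

* IRLS: tolerance 1e-10 on the max coefficient step, 100 iterations,
  step-halving; |β| > 30 is reported as separation. Aliased columns fall
  back to minimum-norm steps and pseudo-inverse covariance, with AIC's k
  taken as the information-matrix rank.
* Stepwise ties break toward the smaller model; an accepted move must lower
  AIC by more than 1e-9.
* Percentile CIs use draws from the fitted covariance (eigenvalue-clipped to
  PSD); degenerate covariance yields near-zero-width intervals rather than
  errors.
* Problem sizes in tests and the acceptance run — 35 000/50 000 survey
  units, 200 microsim replicates, 500-replicate null calibrations,
  199–9 999 permutations — were chosen as the smallest sizes at which the
  binomial/Monte-Carlo tolerances in the checks are meaningful.
* The pipeline's inference is model-based throughout; design-based survey
  variance, multilevel structure for the panel, and regularised fits are out
  of scope.
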