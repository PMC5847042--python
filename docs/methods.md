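# Methods

## The scores

`ihc4c` implements four related prognostic scores for ER-positive breast
cancer, all expressed on a log-hazard scale multiplied by 100 (a 100-point
difference corresponds to a hazard ratio of *e*):

**IHC4** combines the four immunohistochemical markers:

```
IHC4 = 94.7 × [ −0.100·(ER H-score/30) − 0.079·(PgR%/10)
                + 0.586·1[HER2 = 3+] + 0.240·ln(1 + 4·Ki67) ]
```

**Clinical score** combines nodal status, tumour size category, grade and
dichotomised age:

```
C = 100 × [ 0.417·N1–3 + 1.566·N>3
            + 0.93 × (0.497·T1–2 + 0.882·T2–3 + 1.838·T>3
                      + 0.559·Gr2 + 0.970·Gr3 + 0.130·1[age ≥ 65]) ]
```

**IHC4+C** is their sum. The **refitted combined (PathIES) score** was
re-estimated on an endocrine-switch population (patients disease-free after
2–3 years of tamoxifen, randomised to continue or switch to exemestane);
grade and age drop out, the treatment arm enters, and IHC4 enters
continuously:

```
PathIES = 100 × ( −0.13·exe + 0.46·N1–3 + 1.45·N>3
                  + 1.37·T1–2 + 1.65·T2–3 + 2.21·T>3 + 0.0048·IHC4 )
```

Conventions that the published equations leave open, and how this package
resolves them:

* **Ki67 scale.** Ki67 enters as a percentage (0–100), not a fraction. With
  typical ER+/PgR+ marker values only the percent scale yields a cohort
  median IHC4 near −19; the fraction scale would push medians below −100.
  A `ki67_as_fraction` override exists for sensitivity analyses.
* **HER2 2+** counts as negative, with no ISH reflex.
* **Duplicated size term.** The printed refitted equation lists the T1–2
  coefficient twice (1.37 and 1.65). The second occurrence is read as T2–3:
  the categories otherwise duplicate and the coefficients would not be
  monotone in size.
* **Age boundary.** Age exactly 65 scores the ≥65 indicator as 1.
* **Quartile groups.** Cutpoints are type-7 (linear-interpolation) empirical
  quantiles; a score exactly at a cutpoint goes to the upper group (Q1 <25th,
  Q2–Q3 25th–75th, Q4 ≥75th). Grouping refuses degenerate inputs (identical
  cutpoints, or an empty lower quartile).
* **Missing clinical data.** Records missing grade, nodes or size are never
  silently scored: they stay in IHC4-only analyses and are flagged
  incomplete for the clinical/combined scores, reproducing the two nested
  analysis sets (all-marker vs complete-case).

## Endpoint and survival analyses

The endpoint is time to distant recurrence (TTDR): time from randomisation
to distant recurrence or death from breast cancer or unknown cause; all
other terminal events (local/regional recurrence, contralateral disease,
other-cause death, administrative end of follow-up) censor at their time.
Since a follow-up record carries a single terminal event, a record whose
terminal event is a local recurrence censors at that time; whether the real
study instead kept such patients under observation is not documented, so
this convention is explicit here rather than configurable at the record
level.

Kaplan–Meier estimation (Greenwood intervals with log(−log) transform),
log-rank tests and Cox proportional-hazards models (Efron tie handling) are
delegated to `lifelines`; confidence intervals are Wald, exp(β ± 1.96·SE),
at a fixed 95% level, and no multiplicity adjustment is applied anywhere.
Model selection is backward stepwise with the treatment term forced: at each
iteration the non-forced term with the largest p-value above α (default
0.10) is removed, single-column terms judged by Wald p, multi-column blocks
(the two nodal indicators, the three size indicators, the two grade
indicators) entering and leaving as a block judged by a likelihood-ratio
test. The treatment-by-risk-group interaction is a likelihood-ratio
comparison of the main-effects Cox model against the model with interaction
products (Wald variant available); it refuses designs with an empty
group×arm cell. Fits are rejected with a diagnostic error on constant
covariates, fewer events than terms, or suspected monotone likelihood
(|β̂| > 10 or SE > 50).

## Predicted probabilities and calibration

The combined score divided by 100 is treated as a Cox linear predictor, so

```
P(DR by t | score) = 1 − S0(t) ^ exp(score/100)
```

The baseline S0 is either supplied as an external (time, S0) table — the
mode for applying externally derived weights — or estimated internally by
the Breslow estimator with score/100 as a fixed offset (no coefficient
refit), which asks only whether the score's *spread* is calibrated, not its
level. The default horizon is 120 months, truncated to the baseline's
support. Calibration splits the cohort at the empirical 10th percentiles of
the score and compares, per decile, the mean predicted probability against
the observed Kaplan–Meier event probability with its Greenwood interval; a
decile with no events and nobody under observation at the horizon reports a
missing observed value. Reported predicted-risk quantiles use the empirical
(inverted-CDF) convention, matching statements of the form "half the
patients had predicted risk ≤ x".

## The synthetic cohort generator

No patient-level data from the emulated study are deposited, so a generator
reproduces its structure; its defaults are the study conditions and are not
tuned per experiment.

* **Markers.** ER H-score ~ 300·Beta(2.06, 0.78) (an ER-positive trial
  population, median ≈ 234); PgR is zero-inflated (91.4% positive,
  positives ~ 100·Beta(0.91, 0.71)); HER2 categories (0, 1+, 2+, 3+) with
  probabilities (0.45, 0.30, 0.203, 0.047); Ki67 ~ lognormal with σ = 1.34
  and location pinned so P(Ki67 ≥ 13%) = 0.43, truncated at 100. The beta
  and σ parameters were calibrated once (scripts/calibrate_generator.py) so
  the induced IHC4 distribution has median ≈ −20 and IQR ≈ (−51, 11).
  Markers are drawn independently; marker–marker correlation is not claimed.
  Staining intensity, percent-positive and Allred companions are derived
  from the H-score for the eligibility rules.
* **Clinical factors.** Nodal status (48.9/36.2/14.9% for N0/N1–3/N>3 among
  non-missing), grade (25.3/54.4/20.3%), tumour size ~ lognormal(0.589,
  0.5425) cm (median 1.8 cm), age ~ N(63.7, 8.4²) truncated to [35, 95],
  treatment 50/50. Per-field missingness (nodes 35/430, grade 46/430, size
  3/430, independent) gives an expected 350.3 complete cases per 430 — the
  two analysis sets arise from the masking, not from a tuned knob.
* **Follow-up.** Distant-recurrence-type events from an exponential hazard
  h0·exp(lp); independent exponential competing processes for other-cause
  death (0.001/month) and local/contralateral recurrence (0.00153/month,
  tuned to the ~38 non-distant per ~67 distant recurrence split);
  administrative censoring uniform on 61–121 months (median follow-up 91).
  Event types within the TTDR family are 90/7/3% distant recurrence /
  breast-cancer death / unknown-cause death.
* **Hazard modes.** In *continuous* mode (the default, study-emulating
  mode) lp = combined score/100, so the cohort is exactly proportional
  hazards in the score; h0 = 4.82×10⁻⁴/month, calibrated so a default
  430-patient cohort yields ≈ 67 TTDR events among its complete cases. In
  *quartile-contrast* mode lp is a planted log-hazard per true score
  quartile, with defaults anchored to the published quartile hazard ratios
  (1.45/2.32 for IHC4, 3.80/8.96 for IHC4+C, 5.54/15.54 for the refitted
  score). Here the baseline (≈ 2.7×10⁻³/month for all three drivers) is
  instead calibrated so the *reference* group carries the study's
  cohort-average event fraction (~0.19): this mode is a recovery harness,
  and an event-starved reference quartile would bias the partial-likelihood
  estimator and make the harness test estimator small-sample bias rather
  than pipeline correctness.
* **Determinism.** All draws flow from one `numpy` Generator seeded by the
  config; identical (config, seed) gives byte-identical CSVs. Truth columns
  (linear predictor, latent event/censor times, planted group) are written
  to a separate table and never consumed by the analysis pipeline.

### What passing tests do and do not show

The generator reproduces the published *marginal* cohort descriptors and a
proportional-hazards event process. It does not reproduce marker–marker or
marker–clinical dependence, non-proportional or time-varying hazards,
informative censoring, or inter-laboratory measurement error — so passing
recovery and calibration tests demonstrate correctness of the pipeline's
computations under the stated model, not robustness of the scores on real
data. One visible consequence: holding the study's event yield fixed under
an exponential hazard places the median predicted 10-year risk near 0.18,
higher than the ≤ 0.10 reported for the real cohort; the predicted-risk
profile test freezes the generator's own values rather than the study's.

## Problem sizes

Simulation-based tests use the smallest sizes at which the checks are
statistically meaningful: hazard-ratio recovery averages 60 (tests) or 100
(acceptance script) replicate cohorts of n = 2000; marginal calibration uses
one n = 50,000 draw; complete-case and event-count calibration average 100
or 200 cohorts of n = 430; the interaction-test size check uses 500 null
replicates of n = 1000; calibration self-consistency uses one n = 5000
cohort (mean |predicted − observed| < 0.03 across deciles).

## Known limitations

* The external baseline survival used by the original combined-score
  derivation is not published; external mode accepts a user table but ships
  no claimed "true" values.
* The eligibility filter applies the ER-positivity rules to whatever ER
  measures are present; it cannot adjudicate conflicting measures.
* The stepwise procedure inherits the usual caveats of backward selection
  (unstable near-threshold terms, optimistic p-values in the final model).
* Exponential baselines mean the generator cannot exhibit the late-failure
  plateaus typical of ER-positive disease.
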