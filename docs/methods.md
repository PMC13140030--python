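# Methods

This note documents the models, conventions and design choices behind
`hivprognosis`, in the spirit of a statistical-software methods appendix.

## Study design being emulated

The pipeline targets the external-validation setting for a points-based
prognostic score in a prospective HIV cohort: subjects enter at their first
visit aged ≥70 within a recruitment window (default 2014-06-01 to
2017-12-31), are followed to the earliest of death, five years, or the
administrative study end (default 2019-12-31), and are otherwise censored at
their last known-alive date. Eligibility requires HIV-1 infection and at
least one CD4 count within ±12 months of entry; subjects lost to follow-up
are censored (no registry linkage is implemented).

### Calendar conventions

A month is 30.4375 days and a year 365.25 days everywhere (window rules,
ages, follow-up durations). Age is exact fractional years at entry.

### Baseline-value resolution

Among in-window measurements of an analyte, the value closest to the entry
date wins; on an exact distance tie the after-entry value is taken (values
after entry tend to be drawn closer to the first visit). Two same-day
measurements keep the last listed, with a warning. BMI has two modes:
`windowed` applies the ±12-month rule to weight, `unrestricted` takes the
globally closest dated weight so rarely-weighed stable patients are not
excluded; height is treated as static and resolved without a window. The
unrestricted mode deliberately allows weights recorded after study exit.
When the "closest" rule and the after-entry preference could conflict beyond
exact ties, nearest-wins takes precedence.

## Score engines

Score definitions are versioned YAML assets, schema-validated at load time
(intervals must tile the covariate's domain half-open on the right;
risk-group cut-points must increase; group survival must be non-increasing).
Components are category intervals, boolean indicators, or piecewise-linear
functions of a continuous input clamped to the knot range (the clamping is
the input-domain restriction for continuous scores).

Provenance of the packaged assets:

* `dataids_score_synthetic.yaml` — the component list, the age points
  (1 for 65–74, 8 for ≥75), the 0–73 theoretical range, the cut-points
  0–3/4–13/14–19/≥20 and the group 5-year predictions 0.95/0.90/0.80/0.53
  follow the published description of the Dat'AIDS score; the remaining
  per-category points are synthetic values consistent with those
  constraints (per-component maxima sum to 73). Integrity is asserted by
  tests (max total, age points, cut-point boundaries).
* `vacs1_index.yaml` — transcription of the published VACS 1.0 categorical
  table (Justice et al. 2013).
* `vacs2_index_synthetic.yaml` — the published VACS 2.0 spline coefficients
  are not reproduced; this stand-in keeps the correct variable list
  (adds BMI, albumin, WBC, platelets) and monotone risk directions with
  piecewise-linear components. It supports computability accounting and
  rank-based comparisons only.

Neither reconstruction is suitable for clinical scoring.

Missing components render a score non-computable (listed in the result);
the normal-value imputation policy fills exactly albumin (4 g/dL ≡ 40 g/L —
cohort albumin is stored in g/L and converted before scoring), ALT
(25 IU/L) and AST (20 IU/L), is idempotent, and flags imputed provenance.

### Predicted survival

The derivation study's baseline survival function is not available, so the
default prediction mode is the group-level 5-year mapping, bridged to
intermediate horizons at constant hazard: S_g(t) = S_g(5)^(t/5). When a
continuous-prediction asset (S₀ at 5 years plus log-hazard per point λ) is
supplied, S(t) = S₀(t)^exp(λ·total) with the same constant-hazard bridge
for S₀. The asset slot ships empty.

## Validation statistics

* **Kaplan–Meier** — product-limit estimate via lifelines, with Greenwood
  variance accumulated from the event table and log(−log) 95% CIs.
* **Harrell's C** — own implementation, mortality-oriented: a pair is
  comparable when the follow-up times differ and the shorter ends in death;
  concordant when the shorter-lived subject has the higher score; marker
  ties count ½. Time-tied pairs are not comparable (immaterial on
  continuous times; on heavily tied data conventions differ across
  packages). The CI is a leave-one-subject-out jackknife with a normal
  interval clipped to [0, 1] — the method is unspecified in the validation
  literature this mirrors, and is isolated so it can be swapped. An O(n²)
  brute-force enumeration and lifelines' concordance serve as independent
  oracles in tests, never as the implementation.
* **Cox PH across risk groups** — indicator covariates with the lowest
  group as reference, fitted by lifelines (partial likelihood, Efron tie
  correction, Newton updates), Wald CIs. A Breslow option is not provided
  (lifelines implements Efron only). Groups with no events produce a
  monotone likelihood; their coefficients are flagged `unstable` rather
  than suppressed. Subgroup levels with fewer than 5 events are skipped
  with a warning.
* **Calibration (Poisson representation of a Cox model)** — one record per
  subject at the truncated exit time. With predicted cumulative hazard
  Ĥᵢ = H₀(tᵢ)·exp(PIᵢ): the intercept model is an offset-only Poisson GLM
  whose MLE is α̂ = log(Σdᵢ/ΣĤᵢ) (calibration-in-the-large); the slope
  model regresses dᵢ on the prognostic index with offset log H₀(tᵢ), and
  β̂ = 1 indicates a correctly scaled index. Follow-up is truncated at the
  5-year prediction horizon before fitting. The single-record-per-subject
  variant is used; split-follow-up variants exist and would refine the
  time-varying baseline, at the cost of expanded data. When only the
  group-level mapping is available, PIᵢ = log(−log S_g(5)) and
  H₀(t) = t/5.
* **Person-time rate** — 100·Σdᵢ/Σtᵢ, reported to 2 decimals.
* **Score comparison** — C for both scores on the intersection of subjects
  where both are computable.

Same-day exits are shifted to half a day so log terms stay finite; report
percentages round half away from zero to one decimal.

## Synthetic cohort generator

The generator emulates the target population's *marginals*: age-band mix
(60.8% / 36.5% / 2.6% for 70–74 / 75–84 / ≥85), 75.8% male, log-normal CD4
(median 553 cells/mm³), comorbidity prevalences (cancer 11.2%, CVD 13.3%,
cirrhosis 3.0%, HCV 4.7%, HBV 1.3%), eGFR band mix (3.5% / 30.0% / 66.5%),
sex-specific haemoglobin giving ~21.5% anaemia, BMI ~N(24.3, 3.6²) giving
~5.4% low BMI, and lab distributions matched to reported medians/IQRs.
Creatinine is obtained by inverting the CKD-EPI equation at a target eGFR.
Missingness is MCAR: 65.9% of albumin values absent and 31.7% of weights
dated outside the ±12-month window (so the windowed BMI mode reproduces
~68% completeness while the unrestricted mode is complete); other labs are
~99% complete. A configurable fraction of screened-but-ineligible records
(age <70, no in-window CD4, HIV-2) is appended — the default reproduces a
92.0% inclusion fraction.

Survival is exponential with hazard h₀·exp(λ·score), where the score is the
packaged Dat'AIDS total computed from the generated covariates. The
defaults λ = 0.105 and h₀ = 0.00925/year were solved from the four group
predictions (group survival S ≈ exp(−5·h₀·e^{λ·s}) at the groups' typical
scores), so group-level calibration checks are meaningful and
self-generated cohorts recover slope ≈ 1, intercept ≈ 0. Censoring
combines the administrative cap min(5 y, study end − entry) with an 11%
loss-to-follow-up fraction censored uniformly on (0, 5]. Everything is
deterministic given the seed; outputs are the exact CSV schemas the loader
consumes.

Covariates are drawn independently — the joint dependence (e.g. CD4 ×
anaemia) in real cohorts is unknown to this package, so passing tests
demonstrate correctness of the pipeline's mechanics and statistics, not
realism of covariate correlation structure. A consequence of independence
is a flatter risk-group distribution than real cohorts show. Under the
administrative censoring pattern (entries up to end-2017, study end 2019),
the default cohort accrues roughly 150–170 deaths per 1330 subjects —
above the ~100-event minimum usually quoted for external validation, but
below the event counts a real cohort with worse-than-predicted mortality
would produce; simulations that need more events should raise `n` or `h0`.

## Problem sizes used in tests

The suite validates statistics on small exact fixtures (hand-computed KM
steps, 3-subject concordance, closed-form calibration), on ~100 random
fixtures of n ≤ 50 against brute-force oracles, and on simulated cohorts of
n = 2000–5000 for parameter recovery; the end-to-end run uses the default
n = 1330. These sizes keep every Monte-Carlo check several standard errors
inside its tolerance while the whole suite runs in well under a minute of
statistical computation.

## Known limitations

* The two reconstructed score assets (above) are not clinically faithful.
* No competing risks, time-updated scores, or time-dependent C indices.
* Jackknife C intervals are approximate for small event counts.
* The eGFR banding compares exact values at boundaries (59.6 is "30–59");
  banding of rounded values would differ at the margin.
* The MCAR missingness default cannot probe bias from informative
  missingness; the generator exposes the rates but not an MNAR mechanism.
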