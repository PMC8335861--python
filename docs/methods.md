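# Methods

## Outcome: YLD scoring as a DALY measure

Each of 13 chronic conditions carries a disability weight `W_j ∈ [0, 1]`
(0 = full health, 1 = death).  A person diagnosed with condition *j* for
`T_j` years contributes `W_j · T_j` years lived with disability; the
person-wave total is the plain sum over conditions.  No age-weighting,
time-discounting, or multiplicative comorbidity adjustment is applied, in
line with post-2010 burden-of-disease practice, and comorbidity is additive
because the total is defined as a sum.  The conditions are chronic and
essentially non-fatal in this age band, so the YLD total is used directly
as the DALY outcome; years of life lost (YLL) are out of scope.

The weight registry is fixed: hypertension 0.36 (a China-specific,
multi-source estimate — far above typical GBD hypertension weights; the
registry is swappable via CSV for sensitivity work, but no sensitivity
analysis is claimed), diabetes 0.015 (WHO 2004), cancer 0.288, chronic
pulmonary disease 0.225, hepatic disease 0.0645 (mean of decompensated
liver cirrhosis, lower limit 0.123, and viral hepatitis 0.006), heart
disease 0.008, stroke 0.07, kidney disease 0.104, gastric disease 0.209,
emotional and mental illness 0.265, memory-related disease 0.322,
arthritis/rheumatism 0.080, asthma 0.036.  Hyperlipidemia appears in the
14-condition questionnaire but carries no weight and is excluded.  Four
entries are composites (unweighted means of two GBD health states); numeric
component values are stored only for the hepatic entry, whose source states
them — for the others only the component labels are recorded, and the
mean-of-components consistency check applies whenever numeric components
are present.

**Duration conventions.**  `T_j` can be measured from the recorded
diagnosis year (`diagnosis_year`, the default) or from the first wave at
which the diagnosis appears in the data (`first_report`).  Survey
self-reports do not distinguish the two cleanly, so both are supported and
the convention used is recorded in the output metadata.  Durations are
floored at zero.

## Covariate coding

* **Birth cohort**: four bands coded 1–4 and entered as a continuous
  score.  Default bands are 1942–1947, 1948–1953, 1954–1959, 1960–1964; an
  alternative set (1942–1946, 1947–1953, …) is selectable because the two
  conventions circulate for these data.  Out-of-span birth years are
  excluded with a logged count.
* **Age centering**: `age_c = age − median(age)` within cohort, over all
  observed person-waves; the median uses the lower of the two central order
  statistics on even counts (any consistent convention is acceptable; this
  one is recorded in the codebook).  Centering separates within-person
  aging from between-cohort level differences.
* **Education**: three levels (illiterate / elementary / middle school and
  higher), fixed at the baseline-wave value per person, expanded to two
  indicators with middle-or-higher as reference.
* **Income**: base-10 logarithm of per-capita household income with a
  configurable positive floor (default 1 currency unit) for nonpositive
  values.  Base 10 makes a per-capita income of 20,000 correspond to a log
  income of 4.30, the scale on which such survey descriptives are usually
  reported.
* **Expenditures**: four amounts (hospitalization and doctor-visit,
  out-of-pocket and total) are median-split on the pooled sample (per-wave
  optional), ties assigned upward (value ≥ median → 1); the two
  out-of-pocket ratios enter as continuous controls.
* **Attrition indicator**: every record of a person who dies or is lost
  before the final wave is flagged 1 (a single combined dummy by default; a
  died/lost split is available).  The indicator is a pragmatic
  pattern-mixture correction for selective dropout, not a joint model of
  dropout and outcome.

Coding is idempotent — all derived columns are recomputed from raw fields —
and every rule applied is written to a machine-readable codebook.

## The growth-curve model

Level 1 (within person, repeated measures):

    y_ij = β0j + β1j·age_ij + β2j·age²_ij + e_ij,   e_ij ~ N(0, σ²_e)

Level 2 (between persons):

    β0j = r00 + r01·cohort_j + (controls) + u0j
    β1j = r10 + r11·cohort_j + r12·SES_j + r13·cohort_j·SES_j + u1j
    β2j = r20 + r21·cohort_j + r22·SES_j + r23·cohort_j·SES_j + u2j

Substitution yields a Gaussian linear mixed model whose fixed effects are
age, age², their products with the moderators, and the person-level
controls (gender, SES main effects, marital status, expenditure controls,
health behaviours, and the died/lost indicator — the intercept model
carries the SES main effects alongside cohort, matching the reported model
layout even though the schematic intercept equation lists only cohort).
The default random structure is intercept + age slope: reported variance
components for these data show exactly one slope variance and one
covariance, implying the random curvature u2j was dropped in estimation;
a 3×3 intercept+slope+curvature option remains available.

**Estimation.**  The fitter profiles the likelihood in the lme4 style:
with Λ the lower-triangular Cholesky factor of the random-effect covariance
relative to σ²_e, the per-person marginal covariance is
σ²_e(I + Z_j ΛΛ' Z_j'), and for fixed Λ both the GLS fixed effects and
σ̂²_e are closed-form, so the optimiser (L-BFGS-B; data-driven start from
an OLS between/within variance decomposition, fixed fallback starts used
when the first start converges on a boundary) searches only the q(q+1)/2
Cholesky entries.  Per-person algebra is reduced to q×q problems with the
Woodbury identity, making a 60,000-row fit take seconds.  The Cholesky
parameterisation enforces positive semi-definiteness by construction;
boundary solutions (a diagonal entry collapsing to zero) are flagged.
Convergence requires the optimiser's relative-tolerance criterion
(ftol 1e-12, gtol 1e-7 on the deviance surface); the achieved gradient norm
is reported.

ML is the default so that −2LL/AIC/BIC comparisons across different
fixed-effect sets are coherent; REML is available by flag, and
`compare_fits` refuses to compare REML fits with different fixed effects.
The parameter count for AIC/BIC is fixed effects + random (co)variances +
residual variance (recorded in the result metadata; other software counts
only covariance parameters, so information criteria are comparable within
this package, not across packages).  Inference is large-sample Wald z —
symmetric 95% CIs and two-sided p-values, no degrees-of-freedom
correction.  Standard errors for the variance components come from the
observed information (central-difference Hessian of the profile likelihood
on the variance scale).

**Missing covariates** are completed by chained equations (statsmodels
`MICEData`); the outcome is never imputed.  The m completed fits are pooled
by Rubin's rules (estimates averaged; total variance = within +
(1 + 1/m)·between; Barnard–Rubin degrees of freedom).

## Synthetic cohorts

Mode A generates person-level disease histories: ~15,000 persons by
default, waves 2011/2013/2015/2018, four birth cohorts mixed roughly
15/30/28/27%, ~20% urban, cohort-graded education and log-income
distributions, and absorbing annual-hazard onset processes per disease
(h(age) = base·exp(slope·(age−60)), starting at age 40 so diagnoses can
predate baseline).  Hazard defaults were set once so that baseline mean
DALYs sit near 1.1 years under the default weight registry.  Between-wave
death and loss probabilities default to values inside the 0.07–6.8%
per-wave range typical of such surveys.  One record per person per wave;
interview-month jitter is not modelled (age = wave year − birth year).

Deliberate simplifications: no household structure or survey weights, no
remission (ever-diagnosis is absorbing), incomes constant within person,
onset hazards do not depend on SES by default, and the wave-on-wave rise of
mean scored DALYs is shallower than the steep early growth seen in real
self-report data (which partly reflects reporting dynamics no hazard model
of true onset reproduces).  Passing tests on these panels therefore
establish correctness of the pipeline and estimator, not realism of every
marginal feature of survey data.

Mode B attaches a continuous outcome drawn exactly from the growth model —
fixed effects on the coded covariates, per-person random effects from a
given covariance, i.i.d. residuals — to a coded design panel.  Outcomes are
not truncated at zero by default (the fitted model is an unconstrained
linear mixed model); truncation is an explicit flag.  Named presets bundle
published coefficient sets (model1/model2/model3 and the male/female
stratified variants) so recovery experiments can use printed estimates as
simulation truth.

**Informative dropout.**  For testing the died/lost correction, mode B
supports a pattern-mixture MNAR mechanism: exit odds between waves tilt
with the person's systematic (covariate-driven) next-wave outcome level,
and persons destined to exit have their outcome shifted upward by a
configurable amount — dropouts carry a higher burden than completers, the
premise under which the attrition dummy is a sensible correction.  A purely
outcome-logit dropout was considered and rejected: selection acting through
the random intercept is largely integrated out by likelihood-based
estimation, leaving the dummy nothing to correct (and making it a mild
collider adjustment instead).

## Simulation experiment sizes

The test suite runs the recovery experiment at 15,000 persons (single
replication, estimates checked within 3 Monte-Carlo SEs of truth),
interval-coverage at 500 persons × 200 replications, quadratic-vs-linear
selection at 2,000 persons × 100 replications, and the attrition-bias
comparison at 1,000 persons × 100 replications, holding the covariate
design fixed across replications and redrawing random effects, residuals
and dropout — standard conditional-on-X simulation, which is also what the
coverage and bias statements condition on.

## Known limitations

* The weight registry reflects one published valuation; the hypertension
  weight in particular dominates scored totals.
* The attrition dummy is a coarse correction; no joint or selection model
  is provided.
* Wald inference is asymptotic; small-sample df corrections (Satterthwaite,
  Kenward–Roger) are not implemented.
* Information criteria use this package's parameter-count convention and
  include all likelihood constants.
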