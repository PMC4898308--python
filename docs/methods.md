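# Methods

This note records the statistical model, the generator's assumptions, the
numerical choices, and the limits of what the simulation-based tests can
show. It documents how quantities are computed; every number quoted in the
README is produced by the code itself.

## Cohort definition

Eligibility mimics an EHR-derived CKD stage 3–5 cohort: two or more
ambulatory serum-creatinine measurements whose estimated GFR falls below
60 mL/min/1.73 m², separated by at least 90 days (a deterministic reading of
"three months"; calendar-month arithmetic is avoided). Inpatient draws are
discarded before qualification to guard against acute kidney injury
contaminating the baseline. With more than two low measurements, *any*
qualifying pair at least 90 days apart suffices, and the index date is the
earlier member of the earliest such pair. eGFR uses the re-expressed
4-variable MDRD equation, `175 · SCr^−1.154 · age^−0.203 · 0.742[female] ·
1.212[black]`, taking the recorded creatinine as already calibrated — no
recalibration map is modeled. Subgroups (hypertension, diabetes, chronic
viral disease, severe CKD = eGFR strictly < 30) are deliberately
non-exclusive, mirroring how disease-management panels overlap.

## Synthetic cohort generator

One row per patient, an index-visit snapshot. Covariates are drawn from
configured marginals: truncated-normal age (≥18) and eGFR (bounded below 60
for the stage 3–5 default, below 30 for the severe-CKD profile; the
configured mean/SD parameterize the latent normal, so the realized mean sits
slightly below it under truncation), categorical race and insurance,
Bernoulli comorbidities coupled through an exchangeable latent Gaussian
copula (default correlation 0.25 — the overlap among comorbid subgroups in
real panels is heavy, but its mechanism is not identified, so the copula
parameter is exposed rather than asserted). Dipstick proteinuria is ordinal
(none/trace, 1+, 2+, ≥3+) from a cumulative-logit model whose location
shifts with eGFR (default slope 0.5 per SD below the mean), so severe CKD
shows heavier proteinuria. Category probabilities published as whole
percentages that total 101% are stored renormalized to sum to one.

Event times come from two independent cause-specific proportional-hazards
laws (Weibull with shape 1 — exponential — by default):
`H_k(t | x) = rate_k · t^shape_k · exp(lp_k(x))`, with log-linear covariate
effects centered at the configured means. Each cause's relative hazard is
additionally normalized to mean 1 in-sample, so the configured baseline
rates (defaults 0.0087 ESRD and 0.0346 death per person-year) retain their
marginal meaning under nonzero effects; coefficients are unaffected. The
observed record is `time = min(T_ESRD, T_death, C)` with the cause code, and
the latent `true_t_*` / `true_lp_esrd` columns are retained purely so that
simulation truths stay computable — analysis code never reads them.
Administrative censoring is uniform on (1.75, 15.75) years, emulating a long
accrual window with a fixed ascertainment date; under the default rates this
puts the median observed follow-up near 6.6 years
(`exp(−0.043·6.6)·P(C>6.6) ≈ 0.5`).

Missingness targets proteinuria and the labs (defaults 28.3%, 15.1%, 5.9%,
1.9%, 1.8% for proteinuria/cholesterol/calcium/albumin/hemoglobin). Under
MAR, each cell's masking probability is a logistic function of standardized
age and eGFR only — variables that are never masked — with the intercept
solved by root-finding so the mean probability equals the target exactly;
the probability is computed before the value is consulted, which is what
makes the mechanism missing-at-random by construction. Outcome columns are
never masked.

**What the generator does not emulate:** longitudinal creatinine
trajectories and repeated labs, the diagnostic-code layer behind comorbidity
flags, non-proportional or time-varying effects, measurement error in labs,
and informative (outcome-dependent) censoring. Tests passing on these
cohorts show the *estimators and plumbing* behave as designed under the
stated generating laws; they do not certify performance on real EHR data.

## Cox engine

Coefficients maximize the partial likelihood; lifelines provides the initial
optimum (with step-size damping retries for near-separated designs) and a
final in-house Newton polish on the Breslow-ties likelihood tightens it
until every score component is below 1e-8 or the relative log-likelihood
change is below 1e-9. The covariance is the inverse observed information at
that optimum, and the baseline cumulative hazard is the Breslow estimator —
increment d/Σ exp(lp) over the risk set at each distinct event time — which
reduces exactly to Nelson–Aalen at null coefficients and shares one risk set
across tied events. Synthetic event times are continuous, so ties arise only
in constructed inputs.

Design contract: continuous covariates enter linearly, centered at training
means; categorical covariates are reference-coded against the largest
training category (dipstick proteinuria against none/trace); the
eGFR×proteinuria interaction multiplies centered eGFR by each non-reference
proteinuria indicator. Race-ethnicity keeps all five levels. The contract is
frozen inside the `CoxFit` (serializable to JSON) and re-applied verbatim on
validation data; an unseen categorical level is an error naming the level,
and a rank-deficient design is an error naming the offending columns.
Predicted risk is `1 − exp(−Λ₀(t)·exp(lp))`; the baseline is flat beyond the
last training event time, and horizons beyond training follow-up warn.
Death is censoring throughout (cause-specific hazard); a subdistribution
(Fine–Gray) variant is out of scope, so predicted "risk" is a net-risk
quantity whose interpretation assumes censoring conditionally independent
given the model covariates.

## Multiple imputation

Chained equations, m = 10 chains by default, 10 sweeps each, least-missing
variable first, initial fill drawn from the observed marginals. Continuous
variables use Bayesian linear regression (normal-inverse-chi-squared
posterior draw, ridge 1e-6 for conditioning) followed by predictive mean
matching with 5 donors, the donor chosen by a seeded draw — so imputed
values are always observed values and skewness is respected. Binary and
ordinal variables use (multinomial) logistic models refit on a bootstrap
resample — the resample supplies the parameter-uncertainty draw — and
sampled from predicted class probabilities; predictors are standardized for
solver stability. When the table carries the survival outcome, the
predictor set includes the ESRD event indicator and the Nelson–Aalen
cumulative-hazard transform of follow-up time, the standard device for
keeping censored outcomes in imputation models. Training and validation
sets are imputed with independent chains and seeds. The exact predictor
matrix a given study would use is not identifiable from a published
analysis; here it defaults to all covariates plus the outcome terms and is
configuration.

Rubin's rules: pooled estimate is the mean; total variance
`W + (1 + 1/m)·B`; 95% intervals use Rubin's small-sample t degrees of
freedom `(m−1)(1 + W/((1+1/m)B))²`, collapsing to the normal quantile when
B = 0. The same arithmetic pools performance metrics, with per-imputation
variances supplied by the bootstrap.

## Evaluation metrics

At horizon t each subject is a case (observed ESRD by t), control (under
observation beyond t) or ambiguous (censored before t, weight 0). Weights
are IPCW from the Kaplan–Meier estimate of the censoring survival function
with event roles reversed: cases 1/G(T−), controls 1/G(t). The AUC is the
cumulative-case/dynamic-control variant (matching the "progressed within the
time frame" framing of the risk-distribution displays), computed as a
weighted Mann–Whitney sum in O(n log n) with ties counted one half; with no
censoring it equals the classical Mann–Whitney statistic exactly. The
prediction error is the IPCW Brier score with the full sample size in the
denominator.

PCF follows subjects from the top of the predicted-risk distribution; the
captured-case mass as a function of the followed population fraction is
piecewise linear, with risk-tied groups at the q boundary contributing pro
rata (so a random ranking captures exactly q in expectation). The default
estimator counts observed IPCW case mass; a model-based variant (expected
events = sum of predicted risks) is available for comparison, since both
forms exist in the risk-concentration literature and a published analysis
rarely says which was used — the IPCW adaptation here is a documented
choice, not an asserted reproduction. PNF inverts the PCF curve on a grid
(step 0.001, matching two-decimal reporting); an unreachable p returns 1.0
with a warning. Bootstrap SEs resample subjects with replacement (default
B = 200), re-estimating the censoring KM within each resample; resamples
with no cases are redrawn, capped. Whether a published SE is a pooled
bootstrap or an asymptotic formula is usually unstated; both the pooled
bootstrap default and the plug-in per-imputation variance are exposed.

Risk-distribution summaries report Gaussian-KDE densities of predicted risk
for progressors and non-progressors plus the q80/q90 cutoffs (20th/10th
weighted percentiles of progressor risk); capturing more progressors
requires the lower cutoff, so q90 ≤ q80 always.

## Pipeline

The cohort is split once, before imputation: training 2/3, validation 1/3,
stratified on full-cohort eGFR quintiles (the bins are a design choice;
"stratified on eGFR" does not pin them down), ⌈2/3·size⌉ per stratum,
singleton strata to training with a warning. The published description
mentions 2-fold cross-validation loosely but then describes a single
split-sample validation; the split-sample reading is implemented. Models
are refit within each subgroup's training members, with the full cohort as
a fifth "subgroup". For each of the m imputation pairs: fit, freeze,
predict at each horizon, evaluate per subgroup; metrics and log hazard
ratios are Rubin-pooled. A subgroup×horizon cell with no validation cases
(or a failed subgroup fit) is flagged unavailable and the run continues.
Every stage derives its seed from the master seed, so the full pipeline is
replay-identical; no validation subject can influence a fitted coefficient
because fits only ever see training tables.

## Verification design and problem sizes

The verification suite runs at desk scale, with sizes chosen to keep
Monte-Carlo error well inside the asserted tolerances: exact oracles
(Mann–Whitney, plain Brier, hand-computed KM weights and Breslow increments)
on 1,000 small random instances; brute-force partial-likelihood maximization
on an enumeration of ≤6-subject tie-free instances (near-boundary optima
|β| ≥ 4 are excluded — there the MLE is effectively infinite); 95% CI
coverage of generating log hazard ratios over 200 cohorts of n = 2,000 with
the acceptance band 90–99%; IPCW PCF(0.2) against an uncensored
million-subject truth (tolerance 0.02), using a configuration with
covariate-independent death so censoring is exactly ignorable — the clean
condition for an estimator-consistency check; MI recovery of pre-masking
lab means at n = 5,000, m = 10 within 2 pooled SEs; and the AUC-vs-PCF
dissociation between two population profiles at n = 6,000.

The two profiles encode the qualitative contrast between a concentrated-risk
and a diffuse-risk population: the "hypertension-like" profile keeps the
full stage 3–5 eGFR range (49.0 ± 10.7) with a modest event rate (11.6 per
1000 PY); the "severe-CKD-like" profile compresses eGFR below 30
(20.1 ± 7.4), spreads proteinuria, and raises the rate to 56.6 per 1000 PY.
Profile log hazard ratios are calibrated so a fitted base model
discriminates at the levels observed for such populations (AUC ≈ 0.90–0.97
concentrated, ≈ 0.80–0.87 diffuse); given those discrimination levels, the
PCF gap is emergent — a large case fraction plus compressed predictor
variance spreads risk across the diffuse group, capping what any top-q
strategy can capture, while AUC stays high in both.

## Known limitations

Net-risk predictions ignore the competing force of death, which is
substantial in severe CKD; a cumulative-incidence formulation would change
absolute risks (not rankings within a horizon). The IPCW correction assumes
censoring independent of outcome given nothing (marginal KM); with strongly
covariate-dependent death this is an approximation, and a covariate-adjusted
censoring model would be the next step. The MICE implementation covers the
variable types present here (continuous, binary, small ordinal) and is not
a general imputation framework. Bootstrap SEs ignore split-sample
variability (the split is fixed by design, matching frozen-transport
validation practice).
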