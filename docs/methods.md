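# Methods

This note records the modelling assumptions, defaults and numerical choices
behind `rvometals`, and what the synthetic-data checks do and do not
establish about analyses of real cohort data.

## Cohort derivation

The raw table is one participant per row under NHANES field codes.
Derivation applies, in order: the age filter (≥ 40 years, inclusive), RVO
outcome coding, exclusion of participants without an outcome or without a
complete blood-metal panel (both counted in the flow report), covariate
algorithms, and the log10 transform of metal concentrations.

* **Outcome coding.** A participant is an RVO case iff any of the four
  ophthalmic grading codes (OPDDBVO, OPDDCVO, OPDSBVO, OPDSCVO) is ≥ 2.
  A central-vein code ≥ 2 classifies the case as CRVO even when a branch
  code is also positive (central takes precedence).  A participant with no
  positive code and *any* missing code is treated as outcome-missing and
  excluded: partial grading cannot confirm the absence of RVO.  This
  conservative rule is a design choice; the alternative (any non-missing
  code suffices) would keep slightly more controls.
* **Covariate algorithms.**  All laboratory thresholds are inclusive (≥):
  hypertension — any SBP ≥ 140 / DBP ≥ 90 mmHg over up to three readings,
  self-reported diagnosis, or antihypertensive medication; diabetes —
  self-report, HbA1c ≥ 6.5%, insulin/oral agents, or medication list, with
  a *borderline* category from self-report that the models merge into the
  reference group; hyperlipidemia — self-report, LDL ≥ 160 / total
  cholesterol ≥ 240 / triglycerides ≥ 200 mg/dL, or lipid-lowering
  medication; smoking — never (< 100 lifetime cigarettes), former, current.
  A covariate with no observed determinant stays missing in the cohort and
  the affected rows are dropped **per model** (complete case), not at build
  time.
* **Detection limits.**  Concentrations below a configured LOD (or
  non-positive) are substituted with LOD/√2, the usual convention for
  assay floors; with no LOD configured, non-positive values are an error
  rather than silently dropped.  Units are taken as given (Pb μmol/L,
  Cd/Hg nmol/L); no conversion is performed.

## Baseline comparisons

Continuous variables: Mann–Whitney U with midranks, tie-corrected variance
and continuity correction; exact enumeration when both groups have ≤ 8
observations and no cross-group ties.  Summaries report both mean ± SD and
median (IQR).  Categorical variables: chi-square — Yates-corrected for 2×2
tables, plain Pearson for larger tables, no exact-test fallback for sparse
cells.  This combination reproduces the published baseline p-values of the
motivating cohort from its printed counts (verified in the test suite to
two significant figures).

## Logistic core

A small Newton/IRLS solver is shared by all model fits, including the WQS
bootstrap loop where thousands of three-predictor refits make per-call
overhead the binding cost.  Convergence: max |score| < 1e-8 or relative
log-likelihood change < 1e-10, capped at 100 iterations, with step-halving.
Wald covariance from the inverse observed information.  Separation is
flagged (not silently reported): diverging coefficients (max |β| > 100), a
near-perfect fit (log-likelihood within 1e-8·n of zero), or a flat
likelihood direction (Wald variance > 1e6, the quasi-separation signature)
set `converged=False`, and the OR-level helpers raise.  The test suite
cross-checks coefficients, standard errors and likelihoods against an
independent maximum-likelihood implementation and against the closed-form
2×2 cross-product ratio.

## Dose-response

* **Tertiles** use linear-interpolation percentiles at 33⅓/66⅔; values
  equal to a cut go to the lower tertile, making assignment deterministic
  and order-independent under ties.  T2 is retained in the model; T3 vs T1
  is reported.
* **RCS** uses the standard restricted cubic basis (k knots → k−1 columns,
  cubic terms normalised by the squared outer-knot span, linear tails).
  Default 4 knots at the 5/35/65/95th percentiles of log10 concentration —
  the common default when a knot layout is not otherwise specified — and a
  25th-percentile reference; both are config-exposed.  The curve grid spans
  the 1st–99th percentiles and always contains the reference point, where
  OR = 1 with zero CI width by construction.  The "dose-response
  significance" statement is operationalised as a Wald test of the k−2
  nonlinear coefficients, emitted with the curve.  The default adjustment
  set is age + sex + BMI (the fully adjusted covariate set remains
  available).

## Weighted quantile sum

The procedure is described in the README.  Choices worth recording:

* **Quantile count** defaults to quartiles (q = 4), the standard WQS
  convention; quantile cuts are linear-interpolation percentiles and a
  value equal to a cut falls in the lower quantile (consistent with the
  tertile rule), so the transform is invariant to monotone rescaling of a
  metal.
* **Normalization.**  Two defensible conventions exist for turning
  bootstrap coefficients into weights.  The default normalises each
  resample's coefficient vector to unit L1 norm and averages the signed
  vectors; its absolute sum is ≤ 1, with equality iff each metal's sign is
  stable — a useful stability diagnostic in itself.  The alternative
  (`normalization="mean-coef"`) L1-normalises the mean coefficient vector
  and always has absolute sum 1.  Published signed weight sets whose
  absolute sums fall below 1 are consistent with the first convention,
  which is why it is the default; both are first-class.
* **Split.**  Simple random 80/20 by default; an outcome-stratified option
  exists because with a rare outcome (tens of cases) an unstratified split
  can leave a partition without cases, which is reported as an explicit
  error rather than silently refit.  Test-set quantile cuts come from the
  full training partition, so the score is one deterministic function of
  the final weights.  Resamples whose logistic fit fails (no cases drawn,
  separation, non-convergence) are dropped and counted in
  `n_boot_failed`.
* No covariates enter the WQS fits by default; a covariate list is
  accepted.

## Transcriptomic screen and qPCR

DEG-table intersection is a set operation on gene identifiers with Venn
counts; direction concordance is reported but not required.  The candidate
filter requires, jointly: strict dose-monotonicity across NC → 10 μM → 30
μM in either direction (ties break monotonicity — every published exemplar
triple is strictly monotone, and both directions occur); maximum
normalized count strictly greater than 1; and membership in a supplied
literature-curated eye-gene list (curation is an input, not computed).

2^−ΔΔCt normalises the target gene to GAPDH per sample, centres on the
control-group mean ΔCt, and reports the summary fold 2^(−mean ΔΔCt).  The
control group's *geometric* mean fold is 1 by construction (the arithmetic
mean exceeds 1 under noise, by Jensen's inequality).  Treated vs control is
compared with a Student's t-test by default (Welch optional), and p-values
are emitted on both the fold and ΔΔCt scales since the published analysis
does not say which scale was tested.  Zero-variance groups (noiseless
worked examples) short-circuit to p = 1 (equal means) or p = 0.

## Synthetic-data generators

`simulate_cohort` emulates the study-frame table: ages truncated-normal on
[40, 85] (the analytic population is 40+; the age filter is exercised with
hand-built tables), realistic covariate prevalences, metals multivariate
log-normal on the log10 scale (defaults approximating observed blood
levels: Pb ~0.10 μmol/L, Cd ~5 nmol/L, Hg ~8 nmol/L, modest positive
correlation), and a latent Bernoulli outcome whose logit is linear in
log10 metals and covariates.  The intercept is found by bisection so the
marginal prevalence matches the target (default 32/5415 ≈ 0.0059, the
motivating study's rate); an unreachable target is an explicit error.
Cases map to the four ophthalmic codes via a random subtype (30% central)
and eye; controls get code 1 throughout.  Missingness is MCAR per variable
group (defaults: 21% of fundus gradings, 3% of metal panels, matching the
observed exclusion flow).  Raw determinant codes are generated so the
cohort algorithms recover the latent covariates exactly — verified as an
invariant.

Known departures from real NHANES data: no survey design (strata, PSUs,
weights), no informative missingness, no measurement error in labs, exact
rather than approximate recoverability of covariates, and independence of
metals from covariates.  Passing recovery tests therefore demonstrates
*software correctness of the estimators under the stated generative
model*, not robustness to the messiness of the real survey.

`simulate_expression` draws log10-normal baseline abundances and applies
per-step fold changes (uniform in [1.5, 3] per dose increment) to
designated monotone genes; multiplicative log-normal noise with a given CV
(0 gives exact expected counts).  One consequence worth knowing: a "flat"
gene with independent noise across the three conditions is strictly
monotone with probability exactly 1/3 regardless of the noise magnitude
(exchangeability), so the monotone filter's false-pass rate on null genes
is 1/3 of the abundance-passing set, not ~0; only exact ties (zero noise)
or replicate-level testing would change that.  `simulate_qpcr` shifts the
treated target Ct by −log2(fold), so relative quantification recovers the
configured fold exactly at zero noise.

## Problem sizes and reproducibility

Every stochastic routine takes an explicit seed and is bit-reproducible
under it (WQS weight vectors are additionally invariant to metal column
order up to floating-point summation order, ~1e-9).  The test suite runs
recovery simulations at n = 50,000 (single-metal OR, 100 replicates),
n = 200,000 (prevalence calibration), and 50-seed WQS recovery at
n = 20,000 with 100 bootstrap resamples per fit — enough for stable weight
ordering, since the weight is a mean over resamples; the 1,000-resample
default is kept for analyses.  Statistical assertions use pre-registered
seeds with binomial-calibrated bounds (e.g. nominal-coverage checks accept
down to a ~3.7σ shortfall) so they detect genuine miscalibration rather
than sampling luck.

## Limitations

* Survey-weighted estimation is out of scope; estimates are unweighted,
  as in the motivating analysis.
* Wald intervals can undercover with very few cases (tertile models with
  ~30 cases); no Firth penalisation is provided, and separation is
  surfaced as an error rather than corrected.
* The WQS score regression on a 20% test partition of a rare-outcome
  cohort has little power: at the motivating scale (~6 cases in the test
  partition) non-significant score coefficients are the expected outcome
  even when one mixture component is truly causal.  Weight ordering is a
  far more sensitive readout at that scale.
* DEG calling, enrichment analysis, and eye-annotation curation are
  upstream/external inputs, deliberately not reimplemented.
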