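# Methods

## The design

The package implements a one-sample Mendelian randomisation (MR) study of
BMI and ordinal well-being outcomes in two cohorts of different ancestry
and structure. Genetic variants associated with BMI serve as instruments:
because genotypes are fixed at conception, a score built from them is (by
assumption) unconfounded with the environmental and behavioural factors
that distort ordinary regression. The four conditions for a valid causal
estimate are the usual ones — relevance (the score predicts BMI, checked
via stage-1 F and incremental R²), independence (no common cause of score
and outcome), exclusion restriction (the score affects well-being only
through BMI), and correct specification of the exposure–outcome
relationship. The non-linear machinery exists to probe the fourth.

Two cohort styles are orchestrated by `pipeline.run_study`:

* **region-stratified-meta** — every (sex × recruitment region) stratum is
  fitted separately with region-specific covariates, and stratum estimates
  are pooled to all/urban/rural/sex summaries by inverse-variance fixed
  effects, with heterogeneity reported as Cochran's Q and
  I² = max(0, (Q−df)/Q)·100. This is the design for a multi-region cohort
  with related individuals and internally estimated variant weights.
* **joint** — direct fits on all/sex/urban/rural subsets, for a cohort
  scored with externally published weights where no meta-analysis is
  needed.

Ordinal outcomes (0–3 health and life satisfaction, 0–5 happiness) are
modelled as numeric responses in linear models, so effects are in outcome
units per SD of BMI; the recoding schemes in `geno_io.recode_outcome` map
questionnaire labels onto these scales, merging the very rare "Very
unsatisfied" category into "Unsatisfied" and treating "Do not know" /
"Prefer not to answer" on the happiness item as missing.

## Genetic risk scores

`GRS_w = Σ βᵢdᵢ` and `GRS_s = n·GRS_w/Σβᵢ` (the identity
`GRS_s·Σβ = n·GRS_w` holds exactly per individual and is tested). Scale
does not affect TSLS estimates — stage 1 absorbs it — so the standardised
score is the default instrument.

Allele orientation regresses rank-inverse-normal-transformed BMI jointly on
all variants per sex. RINT uses Blom's offset, Φ⁻¹((r−3/8)/(n+1/4)) with
average ranks for ties: the prevailing convention where no offset is
specified. "The sex with the largest effect decides" is interpreted as
largest *absolute* effect, since sign conflicts are precisely the case the
rule exists for. Weight estimation then regresses *raw* BMI on all oriented
variants jointly plus principal components (12 by default), on the
unrelated subset only; a per-variant mode exists because the joint/marginal
choice is not observable from score behaviour in unlinked data (variants
are simulated without LD, where the two coincide in expectation).

Block jack-knife: unrelated individuals are permuted by a seeded shuffle
into `n_blocks` (default 100) near-equal blocks; block *b*'s members are
scored with weights estimated on all unrelated individuals outside *b*;
related individuals get full-unrelated-sample weights. The partition rule
(seeded random permutation) is a design choice; any exchangeable partition
satisfies the contract that no individual's phenotype informs their own
weights, which the tests verify structurally by perturbing one phenotype
and observing an unchanged own-block weight row.

Variants that are multiallelic or have MAF < 0.01 (strict inequality) are
excluded before scoring.

## Causal estimators

**TSLS.** Stage 1: exposure (standardised to the analysis sample's SD, or
a fixed external SD if supplied) on GRS_s plus covariates. Stage 2: outcome
on the stage-1 fitted exposure plus the same covariates. The coefficient
covariance is σ̂²(X̂ᵀX̂)⁻¹ with σ̂² computed from residuals against the
*observed* exposure — the standard instrumental-variable variance; naive
stage-2 OLS standard errors are anticonservative and are not offered. With
one instrument and no covariates TSLS collapses to the Wald ratio
(reduced-form slope over first-stage slope), an identity tested to 1e−10.
A stage-1 F below 10 (configurable) emits a warning, not an error, since
per-stratum fits in small strata legitimately have modest F.

**Fixed-effects meta-analysis.** wᵢ = 1/SEᵢ², pooled β = Σwβ/Σw, pooled
SE = 1/√Σw, Q = Σw(β−β̄)² with heterogeneity P from the χ² upper tail on
k−1 degrees of freedom. I² is floored at 0.

**Fisher z.** z = (β₁−β₂)/√(SE₁²+SE₂²), two-sided P via the normal
survival function, which stays accurate far below 1e−300. Standard errors
are recovered from printed 95% CIs as (upper−lower)/(2·1.96), enabling
cross-cohort tests from published tables alone
(`pipeline.estimate_from_printed`).

## Non-linear analyses

**Fractional polynomials.** The exposure is divided by its sample mean
before powering — BMI is strictly positive, so no shift is needed, and the
scaling constant is stored in the fitted model. p = 0 denotes the natural
log and a repeated FP2 power p contributes (x^p, x^p·ln x), the standard
FP construction. FP1 fits all 8 powers, FP2 all 36 combinations (28
distinct unordered pairs + 8 repeated); both attach the full AIC table.
AIC = 2k − 2ℓ with the Gaussian likelihood profiled at the MLE variance
and k counting intercept, slope terms, and covariates but not the
variance — any consistent convention works for within-sample comparison,
and this one matches common practice (it agrees with statsmodels' OLS
AIC). FP1 at p = 1 is an affine reparametrisation of plain linear
regression and FP2 at (1, 2) spans the same column space as the quadratic
fit; both identities are tested numerically. Quadratic fits centre the
exposure before squaring to reduce collinearity, with the centre stored.
`select_by_aic` breaks exact ties toward fewer parameters, then lower
powers, and refuses to compare models fitted on different samples.

**Control function.** Stage 1 regresses the exposure on the score and
covariates and retains the residual r; stage 2 regresses the outcome on
exposure, exposure², covariates, and r. Including r absorbs the part of
the structural error correlated with the exposure, so the stage-2 exposure
coefficients are causal estimates; the coefficient on r measures the
confounding itself and is ≈ 0 when none is simulated. With `degree=1` the
quadratic column is dropped and the linear coefficient equals TSLS exactly
(tested to 1e−8 relative). Wording note: descriptions of this method
sometimes state stage 1 as "instrument regressed on exposure"; the
direction implemented — exposure on instrument — is the only one that
yields usable exposure residuals.

Default standard errors are a nonparametric bootstrap over individuals
(500 seeded replicates re-running both stages), because the generated
regressor r invalidates naive OLS standard errors in general. An analytic
`naive_se` mode exists for exploratory work and for large replicate loops;
at the instrument strengths the generator produces (stage-1 F ≈ 300–400 at
n = 20,000) the first-stage estimation contribution is small and the
analytic quadratic-term test holds its nominal level empirically (the
calibration suite measures its type-I error across 1,000 replicates).

## The synthetic cohort generator

`simdata.simulate_cohort` draws independent biallelic genotypes (binomial
dosages, MAF uniform on (0.05, 0.45)), a standard-normal confounder U, and
builds

    z   = Σ βg·d + c_x·U + N(0, σ_x),     BMI = 23.7 + 3.5·z
    y*  = m_r·β₁·x_std + β₂·x_std² + c_y·U + N(0, σ_y)

where x_std is BMI standardised to cohort SD and m_r an optional
region-specific multiplier on the causal slope used to exercise the
heterogeneity machinery. The ordinal outcome discretises y* at empirical
quantile cutpoints, so configured category prevalences are honoured at any
noise level; cutpoints are recorded in the ground truth.

Defaults are chosen to resemble a large East Asian biobank cohort: BMI
23.7 (3.5) kg/m², 57.2% female, 43.7% urban, 27.7% related, ten
recruitment regions (regions are themselves urban or rural and an
individual's urban flag is their region's type), 4-level ordinal
prevalences 11.6/44.3/27.0/17.1%, and per-allele effects of 0.05 SD across
20 variants giving a score that explains roughly 1.5–2% of BMI variance
(F in the hundreds at n = 20,000). Confounder loadings default to 0.5 on
each side, producing an OLS bias of ≈ +0.26 per SD — large enough that a
calibrated instrument visibly defeats it.

What the generator does **not** emulate: linkage disequilibrium between
variants, population stratification, family structure (relatedness is a
flag only, not a kinship matrix), assortative mating, dynastic effects,
measurement error in BMI, and informative missingness. Passing tests
therefore certify the estimators and the pipeline mechanics under the
stated generative model, not robustness to those real-data complications.

## Calibration problem sizes

The Monte-Carlo suites run at n = 20,000 per replicate: 200 replicates per
true effect for TSLS bias/coverage, 100 for control-function recovery, and
1,000 for the quadratic-term type-I error — sizes at which Monte-Carlo
error is small relative to the tolerances being checked while a full
calibration pass completes in minutes on one CPU. The cross-cohort Fisher
z contrasts need no simulation at all: their inputs are the published
summary estimates.

## Known limitations

* Ordinal outcomes as numeric responses is a linear-model convention;
  ordinal-logit alternatives are out of scope.
* No pleiotropy-robust estimators (MR-Egger, weighted median) and no
  reverse-direction MR.
* The bootstrap resamples individuals independently; clustered or
  family-resampling schemes are not implemented.
* Fractional polynomials are limited to degree 2, and localised non-linear
  MR (piecewise/doubly-ranked) is not implemented.
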