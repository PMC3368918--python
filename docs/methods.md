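# Methods

`vitdmr` re-implements, as tested code, a Mendelian-randomization (MR)
analysis of plasma 25-hydroxy-vitamin D (25-OHD) and colorectal cancer (CRC)
risk in a Scottish case-control study (2,001 cases / 2,237 controls with
measured 25-OHD; up to ~5,449 genotyped).  The subject-level data were never
deposited, so the package pairs the analysis code with a synthetic cohort
generator whose ground truth is known, plus the study's published count
tables, which pin down the desk-scale results exactly.

## The causal model

Four SNPs associated with circulating 25-OHD serve as instruments Z:
rs2282679 (*GC*) and rs6013897 (*CYP24A1*) in the downstream "metabolism"
arm of the vitamin D pathway, rs12785878 (*DHCR7*) and rs10741657 (*CYP2R1*)
in the upstream "synthesis" arm.  Genotypes are coded as raising-allele
dosages 0/1/2 (each counted allele raises 25-OHD); three unweighted allele
scores (overall, upstream, downstream) sum dosages across SNPs.  The MR
assumptions are the usual three: Z affects the phenotype X (checked by the
first-stage partial F, with F < 10 flagged as weak); Z is independent of
confounders (checked by the instrument/confounder balance table); Z affects
disease only through X (not testable internally; the generator can violate
it deliberately via the `pleiotropy` option for robustness studies).

Five estimators of the causal effect ψ (log-odds of CRC per ng/ml 25-OHD)
are implemented:

1. **Control function** (two-stage residual inclusion) — OLS of X on Z,
   then logistic regression of Y on the first-stage fitted values *and*
   residuals; the residual coefficient absorbs unmeasured X–Y confounding.
   The causal OR is exp(coefficient of the fitted values).
2. **Two-stage** — the same without the residual term.
3. **Wald ratio** — (log-odds coefficient of Y on Z) / (linear coefficient
   of X on Z); delta-method CI by default.
4. **Multiplicative structural mean model (MSMM)** — G-estimation solving
   Σᵢ (Zᵢ − Ẑᵢ) Yᵢ exp(−ψXᵢ) = 0; exp(ψ) is a risk-ratio-scale parameter
   and is labelled as such.
5. **Logistic structural mean model (LSMM)** — double-logistic G-estimation:
   fit the association model logit P(Y=1|Z,X) by ML, then solve
   Σᵢ (Zᵢ − Ẑᵢ) expit(logit P̂ᵢ − ψXᵢ) = 0.

With covariates, Ẑ is the OLS projection of Z on them (plain centering
otherwise), and the same covariates enter every stage.

### Numerical choices

G-estimating equations are solved by a grid scan over ψ ∈ [−2, 2] per ng/ml
(81 points) to bracket a sign change — the functions are smooth but not
globally monotone, since extreme ψ is dominated by single subjects with
extreme exposure — followed by Brent refinement to 1e−8, doubling the
interval up to twice when no bracket is found; no sign change anywhere is
reported as non-identified with the endpoint values.  The MSMM exponentials
are computed on centred exposures with a positive rescaling to avoid
overflow.  Logistic likelihoods are maximized by Newton–Raphson with
step-halving; fitted log-odds beyond ±60 are reported as separation
(non-estimable).  Inner simulation/bootstrap loops use this in-package
solver (cross-checked against statsmodels to 1e−7 in the tests); the
user-facing association models use statsmodels GLM.

Confidence intervals for the control-function, two-stage, MSMM and LSMM
estimators are nonparametric subject-level bootstrap percentile intervals
(2,000 resamples by default) re-running every estimation stage per resample;
the Wald ratio uses the delta method by default with bootstrap optional.
Bootstrap resamples that fail (separation, unidentified equation) are
dropped; beyond 20% failures the interval is refused rather than reported.
Bootstrap is seeded and bit-for-bit reproducible.

## Observational layer

25-OHD is standardized for month of blood draw (each month stratum recentred
to the grand mean; strata with fewer than two observations are left
uncentred with a warning), dichotomized at the 10 ng/ml deficiency
threshold, and divided into quintiles at the 20/40/60/80 linear-interpolation
percentiles of the pooled case+control distribution, left-closed at each
lower bound.  Odds ratios come from cross-product 2×2 tables with Woolf CIs
(Haldane–Anscombe 0.5 correction on zero cells, recorded in the result) or
from logistic models in three adjustment tiers: crude; model I (age, sex);
model II (model I + deprivation index, energy, smoking, BMI, NSAID use,
family history, physical activity), fitted on complete cases so the
effective n shrinks across tiers, as in the study.  Multi-level covariates
(smoking, activity) enter as indicator sets; deprivation as a continuous
index.  The quintile trend test is the Wald test of a linear-in-category
score; genotype × 25-OHD interaction is a 1-df likelihood-ratio test between
nested logistic models.  All p-values are two-sided; Wald CIs throughout.

## Synthetic cohort generator

The generator emulates the study design: a prospective population (default
200,000) with

    X = μ + Σⱼ βⱼZⱼ + season(month) + γᵤₓ·U + ε,   ε ~ N(0, σ²), U ~ N(0,1)
    logit P(Y=1) = α₀ + ψ·X + γᵤᵧ·U

followed by retrospective ascertainment of 2,001 cases and 2,237 controls
without replacement.  Genotypes are i.i.d. Binomial(2, pⱼ) — Hardy–Weinberg
by construction, no linkage disequilibrium.  The latent confounder U is kept
in the output for oracle checks.  Covariates (age, sex, deprivation, energy,
smoking, BMI, NSAID, family history, activity) are drawn independently of
everything, encoding the MR balance assumption; AJCC stage, symptom group
and time-to-recruitment group exist for cases only.  Optional MCAR
missingness per field is off by default.

Default parameters are calibrated to the study's printed margins, since it
published neither allele frequencies nor per-allele ng/ml effects:

* pⱼ = 0.713 / 0.805 / 0.400 / 0.808 from the control genotype counts
  (approximations, as flagged in the code);
* βⱼ back-calculated from the printed per-SNP first-stage F statistics via
  βⱼ = sqrt(Fⱼσ̃²/(n·2pⱼ(1−pⱼ))) at n = 4,238 and season-free residual SD
  σ̃ = sqrt(σ² + γᵤₓ²) ≈ 7.3, giving 0.695 / 0.733 / 0.533 / 0.199 ng/ml per
  allele — per-allele deficiency ORs of ~0.83–0.98 in simulation, matching
  the published 0.88–0.98 range;
* μ = 9.5 ng/ml so the cohort mean is ~12.4 with ~40% deficient, as
  published; σ = 7; seasonal month effects are a 5 ng/ml-amplitude sinusoid
  peaking in August (~40% of the mean — the strong seasonality the
  standardization step removes);
* the default disease model is a *confounded null*: ψ = 0 with γᵤₓ = 2,
  γᵤᵧ = −0.9, reproducing the study's observational inverse association
  (crude OR ≈ 0.8 per SD in simulation) with no causal effect — the
  scenario the study's own MR result is consistent with.

The printed F statistics are mutually inconsistent as population values (the
four single-SNP noncentralities sum to ~41 while the overall-score F prints
16.5; each is one noisy realization), so no single DGP can match all seven.
The default panel matches the per-SNP values; the power-analysis
configuration instead rescales the betas so the overall score's expected F
is 16.5, the design figure the power claim rests on.

Concentrations are floored at 0 ng/ml (a plasma concentration cannot be
negative); with the default parameters ~6% of values sit at the floor,
mimicking the pile-up of unmeasurably low winter values at northern
latitudes.  The floor slightly attenuates first-stage slopes relative to the
nominal βⱼ; IV estimates are unaffected because the disease model acts on
the floored exposure.

What the generator does **not** emulate: right-skew of real 25-OHD,
linkage disequilibrium, population stratification, genotyping error,
covariate–exposure correlations, and outcome-dependent participation. Tests
passing on this DGP therefore validate the estimators' statistical
properties, not robustness to those complications.

## Power analysis

Power is estimated by full-pipeline simulation (not a closed-form
approximation): simulate the study design, run the chosen IV estimator, and
count replicates whose 95% CI excludes OR = 1.  The study-scale
configuration uses n = 2,001/2,237, the rescaled panel with expected overall
F = 16.5, and a true protective effect equal to the published
top-vs-bottom-quintile OR of 0.47 interpreted per SD of 25-OHD — the study
printed no unambiguous continuous-scale effect, and the quintile contrast is
its clearest effect estimate; the per-ng/ml ψ is ln(0.47) divided by the
DGP's season-free SD (≈7 ng/ml).  With the control-function estimator this
yields power ≈ 0.24 (MC-SE 0.025 at 300 replicates; the Wald ratio with its
conservative delta CI gives ≈ 0.15) — far below 0.8, quantifying why a null
MR result at this sample size cannot rule out an effect of the observed
magnitude.

## Problem sizes used in the tests

The test suite runs every simulation study at sizes chosen to keep the whole
suite interactive while leaving Monte-Carlo error well inside the asserted
tolerances: CI coverage at 300 replicates of n = 10,000 with 200 bootstrap
resamples; confounding-removal at 300 replicates of n = 50,000 (point
estimates only); parameter recovery at 200 replicates of n = 20,000; power
at 300 replicates of the full study design.  The bootstrap default of 2,000
resamples applies to one-shot analyses, not to the replicated studies.

## Known limitations

* The structural-mean-model estimating equations follow the standard MSMM /
  double-logistic LSMM forms; the study's supplementary material was not
  machine-readable, so exact agreement with its supplementary tables cannot
  be verified.
* Case-control ascertainment makes the first stage a retrospective-sample
  regression (as in the study); a controls-only first stage is available via
  the data subset but is not the default.
* The logistic-scale causal OR is non-collapsible: even a correct estimator
  recovers the conditional ψ only approximately from marginal fits, which is
  why recovery tests carry a ±0.02 OR-scale allowance.
* Continuous ORs are per ng/ml; the study's continuous observational OR
  (0.76) is on an unstated scale, so no per-unit comparison is attempted —
  a per-SD rescaling is a one-line transformation (`or ** sd`).
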