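# Methods

This note documents the statistical model behind `alcmr`: what the
synthetic-cohort generator simulates and why, what each estimator computes,
the numerical choices, and the limits of what the simulation can show about
real cohort data.

## The causal model the cohorts implement

Each simulated individual has genotypes at m unlinked SNPs drawn under
Hardy-Weinberg equilibrium at the scenario's minor-allele frequencies.
Dominant SNPs enter every equation through a carrier indicator (0/1),
additive SNPs through the allele count (0/1/2) — generation and analysis use
the same coding, so recovery tests are interpretable.

Alcohol intake, in equivalent glasses of wine per week, follows a
zero-inflated truncated-normal hurdle:

    latent = μ0 + β_sex·male + β_smk·current_smoker + Σ_j γ_j·code_j(g_j)
             + κ_X·U + ε,      ε ~ N(0, σ_X²),  U ~ N(0, 1)
    intake = max(latent, 0), forced to 0 for never/former drinkers
             (independent labels with probabilities p_never, p_former)

U is a single standard-normal latent confounder standing in for the
socioeconomic/lifestyle factors a real analysis cannot fully measure. All
downstream effects are expressed per **drink per day** (= glasses_week / 7).

The mediator (adiposity-like, kg/m² scale) is linear in drinks/day plus
optional direct SNP effects (its own instruments), which is what makes the
multivariable-MR design identifiable. The continuous outcome
(systolic-blood-pressure-like, mmHg) is linear in drinks/day, mediator,
confounder, age, sex and optional per-SNP pleiotropy, with N(0, σ_Y²) noise.
The binary outcome is Bernoulli through a logit link on the same kind of
linear predictor; the intercept is solved by centring the predictor so the
marginal prevalence equals `baseline_prevalence` (exactly so when all effect
paths are zero).

### Default calibration

The default scenario targets the published structure of a large UK cohort's
MR analysis sample. Three intake anchors are matched *under the generator's
own model* (truncated-normal mixture over sex and smoking cells, zero
inflation p_never + p_former = 6.5%) by nested Brent root-finds:

| anchor | target | solved parameter |
|---|---|---|
| dominant-carrier fraction | 4.4% | MAF q = 1 − √(1 − 0.044) ≈ 0.0223 |
| wildtype mean intake | 8.2 glasses/wk | intercept μ0 ≈ −1.12 |
| wildtype intake SD | 9.5 glasses/wk | residual σ_X ≈ 12.52 |
| carrier mean intake | 6.1 glasses/wk | carrier effect γ₁ ≈ −3.58 (latent) |

Matching the printed SD as well as the means is what makes the full-sample
(n = 337,484) ANOVA F of the carrier first stage land near its published
value (~700–720) as a consequence of the calibration rather than a tuned
constant. The 24 small additive SNPs get frequencies 0.10–0.45 and effects
0.20–0.40 glasses/week per allele (≈1% of intake variance jointly) — the
published source reports no per-SNP effects, so these are design choices
sized to give a usable multi-SNP instrument at simulation-scale n.

Other defaults: 46.3% male (+5.7 glasses/wk), smoking never/former/current =
54.8/35.1/10.1% (current +2.5 glasses/wk), age N(57, 8), Townsend-like SES
N(0,1); confounding κ_X = +2 glasses/wk per SD of U with U loading −5 mmHg
on the continuous outcome and +0.3 log-odds on the binary one — signs chosen
so naive regression of the continuous outcome is biased *downward*, giving
the confounded-vs-MR contrast something to detect. True causal effects:
+2.65 mmHg and log(1.26) per drink/day; binary baseline prevalence 4.6%.
These calibration targets are documented as calibration of the simulation
truth, not as a reproduction of any data analysis.

Scenario variants: `null_scenario` (same instruments/confounding, zero
effects), `confounded_null_scenario` (stronger negative confounding; shows
spurious protective dose categories), `mediation_scenario` (15 strong intake
SNPs at 2.0 glasses/wk/allele + 10 mediator SNPs at 0.8 kg/m²/allele,
intake→BMI a = 1.2 kg/m² per drink/day, BMI→outcome b = 0.15 log-odds per
kg/m², zero direct effect — instruments deliberately stronger than the
default so the mediated path a·b is detectable at n = 20,000),
`hemorrhagic_stroke_scenario` (rare outcome, large effect; see Limits).

## Estimators

* **Wald ratio** β_GY/β_GX; first-order se by default because it makes the
  single-SNP IVW reduction exact; second-order (delta) se available.
* **IVW** fixed-effect with weights β²_GX/se²_GY, equivalent to
  zero-intercept WLS of outcome betas on exposure betas; Cochran's Q with
  df = m−1; multiplicative random-effects se inflation max(1, √(Q/df))
  behind a flag. Estimate and Q are invariant to flipping any SNP's effect
  allele.
* **2SLS** via explicit two stages with the standard variance correction
  (residuals recomputed with observed exposure). First-stage F below 10
  (configurable) attaches a weak-instrument warning, never a failure.
* **Two-stage binary** by predictor substitution (linear stage 1, logistic
  stage 2); the procedure is recorded in the estimate's diagnostics because
  one-sample binary MR has several conventions and results differ in their
  estimand (see Limits).
* **MVMR** zero-intercept WLS of per-SNP outcome betas on the exposure-beta
  matrix, weights 1/se²_GY, fixed-effect ses from the weighted normal
  equations. Rank-deficient exposure matrices (e.g. an all-zero column) are
  an informative error: with one exposure MVMR reduces exactly to IVW, which
  is the tested degenerate case.
* **Cochran's Q across strata** on the precision-weighted mean; log-OR scale
  for binary outcomes. **Holm** step-down (and Bonferroni) with running-max
  monotonicity, cross-checked against statsmodels.

One-sample fits take a covariate matrix; the default observational
adjustment sets are `minimal` = {sex, age} and `full` = {sex, age, current
smoking, SES, BMI}. The replicate-study fast path omits measured covariates:
the instruments are independent of them by construction, so IV consistency
is unaffected, and large replicate studies stay fast. Hot paths (OLS, 2SLS,
per-SNP linear scans, vectorised per-SNP Newton logistic) use direct linear
algebra and are pinned against statsmodels (OLS, IV2SLS, Logit) in the test
suite; observational models and second-stage logistic fits use statsmodels
itself.

## Harmonization policy

Outcome summary statistics are matched to the exposure's effect alleles by
SNP id. Swapped alleles (directly or through strand complements) flip the
outcome beta and complement its frequency. Palindromic A/T and C/G SNPs are
resolved purely by allele frequency — labels cannot identify the strand —
when both frequencies fall outside the ambiguity window [0.42, 0.58]
(configurable), and are dropped otherwise (or always, under the `drop`
policy). Incompatible allele pairs are recorded as `dropped_missing`. Every
input SNP receives exactly one action; this conservation, idempotence on
aligned data, and invariance of the pooled IVW estimate under a full
allele/sign flip of the outcome file are tested invariants.

## Numerical choices

CI multiplier 1.96 (normal approximation) everywhere. Weeks/year 52.18,
months→weeks 4.345. Default serving sizes (g ethanol): wine 16.8, beer/cider
pint 16, spirit measure 8, fortified wine 11.2, alcopop 12 — explicit
configurable stand-ins; an alternative profile with 16.66 g/glass makes
7,127 g/year ↔ 8.2 glasses/week exactly. Dose bins are right-closed
((0,1], (1,2], (2,3], (3,∞) drinks/day) with the reference at zero. The
J-shape classifier orders point estimates only (no significance filter):
flat if all |estimate| < ε (default 0.01), monotone if ordered including the
reference, J-shape if some moderate category ≤ 0 while the top exceeds all
moderate ones, below-reference J if the top also stays < 0. The "current
non-drinker" reference either includes former drinkers (`all_zero`, default)
or drops them (`never_only`). One global seed spawns per-stage substreams
(genotypes / exposure / outcomes / analysis stages), so runs are
bit-reproducible and adding a stage does not disturb earlier draws.

Replicate-study problem sizes were chosen so each check's Monte-Carlo error
is small relative to the quantity examined: type-I error at n = 20,000 ×
500 replicates, continuous recovery/coverage at n = 50,000 × 600, binary
recovery at n = 100,000 × 200, mediation at n = 20,000 × 100.

## What passing tests do and do not show

The generator reproduces the *first two moments* of the published intake
distribution and the carrier contrast, a real confounding structure, and
logit-linked disease outcomes. It does **not** reproduce: the right-skewed
shape of real intake (a truncated normal matching mean 8.2 / SD 9.5 puts
~37% of mass at zero, far above the ~8% of real non-drinkers), reporting
error, linkage disequilibrium or population structure (SNPs are independent;
no PCs are needed or simulated), time-to-event outcomes (binary status at a
fixed horizon replaces incidence analysis), selection/"healthy cohort"
effects, or effect heterogeneity beyond an optional sex interaction. Passing
recovery tests therefore demonstrates estimator correctness under the stated
model, not robustness to everything real data can do.

Two estimand caveats are worth stating precisely:

1. **Weak instruments.** At simulation-scale n the default 24-SNP set is
   individually weak (per-SNP F ≈ 10–20 at n = 50,000). One-sample IVW and
   over-identified 2SLS then drift toward the confounded regression (tested
   directionally over an F grid); *two-sample* IVW instead attenuates toward
   zero. Just-identified single-SNP 2SLS is approximately median-unbiased
   even when weak, which is why the weak-instrument trend test uses an
   over-identified design.
2. **Non-collapsibility / marginalization of the logit link.** Two-stage and
   Wald-type binary estimators target a *population-averaged* genotype-group
   contrast, not the conditional log-OR the generator uses as truth. The gap
   grows with the effect size and with how much the exposure distribution's
   shape (not just location) differs between genotype groups. At OR 1.26 per
   drink/day the asymptotic gap is ~3% (recovered mean OR ≈ 1.30 at
   n = 100,000); at OR 2.25 with the same intake dispersion the two-stage
   estimand is ~40% above the conditional truth, so the rare-outcome
   scenario documents rather than hides this mismatch and is excluded from
   headline recovery outputs.

## Known limitations

Besides the distributional limits above: no LD pruning/clumping or variant
QC (the generator emits clean, independent SNPs); no proxy-SNP lookup for
instruments missing from an outcome dataset; harmonization matches on SNP id
only (no positional liftover); MVMR assumes the exposure-beta matrix is well
conditioned — heavily correlated instruments will inflate its standard
errors long before the rank check trips; and the drink-record inverter
produces integer counts, so gram targets are met only to within half a
serving of the last-assigned beverage per week (flagged, never silent).
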