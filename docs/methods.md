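# Methods

## Problem setting

An MR-pheWAS asks, for one instrumented exposure, "what does this exposure
causally affect?" rather than "what affects this outcome?". A weighted
allele score built from externally estimated SNP-exposure effects serves
as the instrument; because genotypes are fixed at conception, an
association between the score and an outcome (given the usual IV
assumptions) indicates a causal effect of the exposure. The package
implements the full workflow — phenome preparation, scanning, multiplicity
control, IV follow-up and pleiotropy-robust two-sample estimators — and a
synthetic-cohort generator so that the whole chain can be validated
against known ground truth.

## Synthetic cohort

The generator emulates the *structure* of a large adult biobank, not any
particular dataset: its outcome distributions are stand-ins chosen for
analytic tractability, since the real phenome's distributions are not
public.

* **Genotypes.** `n_snps` (default 97) independent SNPs,
  `d ~ Binomial(2, f)` with `f ~ U(0.05, 0.5)`. No linkage disequilibrium
  is simulated (a documented non-goal).
* **Exposure.** On the standardized latent scale,
  `z = g_c + c·U + σ_e·ε`, where `g_c` is the centred weighted genetic
  value, `U ~ N(0,1)` a confounder with loading `c = 0.3`, and `σ_e`
  completes the variance to 1. Default per-allele effects are scaled so
  the score explains `score_r2 = 1.8%` of exposure variance — the
  instrument-strength regime of a BMI score in a several-hundred-thousand
  participant cohort (F scales as n·R²/(1−R²), so n = 20,000 gives
  F ≈ 370 and n = 334,968 would give F ≈ 6,100). The observable exposure
  is `27 + 4.75·z` kg/m², so 1 SD of score predicts
  `4.75·√0.018 ≈ 0.64` kg/m².
* **Confounding through the exposure residual.** Outcomes are confounded
  via `v = c·U + σ_e·ε`, the exposure's entire non-genetic residual
  (standardized), with loading `delta = 0.5`. Putting the confounder on
  the residual rather than on `U` alone is deliberate: conditional on the
  first-stage residual the liability noise is exactly `N(0,1)`, so the
  control-function probit's estimand equals the generating coefficient —
  parameter recovery is exact in expectation, while the naive
  (observational) fit is biased by `delta`. With a confounder only
  partially captured by the residual, the probit coefficient would be
  attenuated by the leftover latent variance and no generator-free oracle
  would exist.
* **Outcomes.** Continuous: `y = θ·z + δ·v_std + N(0,1)`; the
  omitted-variable bias of a naive OLS is then `δ·√(1 − score_r2)` in
  closed form, which the tests exploit. Binary and ordered outcomes
  threshold the same liability at empirical quantiles (prevalence
  `U(0.15, 0.5)` for binary; bands 40/30/20/10% for ordered). Unordered
  outcomes follow a three-category multinomial logit on an
  age/confounder/sex mix (an exposure term enters one category's utility
  when causal). Categorical-multiple fields emit sparse ICD-like code
  strings with independent code prevalences `U(0.02, 0.2)`; they are null
  by construction and exist to exercise the expansion rules. A fraction
  `causal_fraction` (default 10%) of the continuous/binary/ordered/
  unordered fields receives the causal effect (default 0.1 SD outcome per
  SD exposure); the truth table records every field's effect.
* **Published weights.** The instrument panel's weights are the true
  per-allele effects, optionally perturbed with `weight_noise_sd` noise
  to emulate the sampling error of an external discovery GWAS.
* **Covariates and missingness.** Age `U(40, 69)`, sex Bernoulli(0.5),
  standard-normal PCs. By default covariates carry no outcome effects, so
  covariate adjustment is testable as a near-no-op; missingness is
  injected completely at random at a configurable rate (informative
  missingness is out of scope).

What passing tests on this generator do *not* show: robustness to LD
between instruments, realistic ICD code co-occurrence, selection/collider
effects, or non-linear exposure-outcome shapes.

## Rule engine

Field typing follows the published rule classes: integer/continuous
fields default to the continuous data type unless they have fewer than
`distinct_value_threshold` (default 20) distinct values (then ordered
categorical; exactly two values → binary); categorical-single fields are
binary with two levels, otherwise ordered/unordered per the dictionary's
coding flag (a missing flag is treated as a dictionary defect and raised);
categorical-multiple fields expand to one binary outcome per observed
code, coding any occurrence at or after baseline as 1. Binary outcomes
need `min_cases` (default 10) in the minor category, guarding against
unstable logistic fits. The exact thresholds used by the original
automated tool live in its own configuration files, so both are exposed
as configuration with these defaults. The inverse normal transform uses
tie-averaged ranks and the offset `(r − ½)/m`, a symmetric, deterministic
choice; constant vectors are rejected. A-priori-excluded fields are
dropped before typing; exposure-linked fields are scanned but excluded
from the multiplicity count, and stage counts are logged at every step.

## Scan

One regression per derived outcome, complete cases per outcome, score as
the independent variable. The multinomial test reports a single
likelihood-ratio p across all category contrasts so every outcome has one
rankable p-value (the per-category coefficient of largest magnitude is
logged); the proportional-odds and multinomial fits fall back to a
degenerate flag on non-convergence rather than aborting a scan. QQ data
use expected quantiles −log10(i/(n+1)). `bulk_linear_pvalues` provides a
vectorized covariate-free linear path for large calibration studies; it
is verified against the per-outcome model.

## Multiplicity

* Bonferroni: α/n.
* Effective tests: Li–Ji estimator
  `T = Σ 1(|λ| ≥ 1) + (|λ| − ⌊|λ|⌋)` over eigenvalues λ of the Spearman
  correlation matrix (pairwise-complete, because phenome missingness makes
  listwise deletion infeasible); unordered phenotypes, for which rank
  correlations are undefined, are excluded and added back in the
  denominator: threshold α/(T + U). The simpler Nyholt variant is
  available via `method="nyholt"`.
* FDR: largest rank k with `p(k) < α·k/n` (strict inequality as the
  procedure is usually quoted; `strict=False` gives the textbook
  Benjamini–Hochberg `≤`, and the two are distinguished by a test).
  With no qualifying rank the threshold falls back to α/n and is logged.

## IV follow-up

The two-stage probit is the Rivers–Vuong control function: OLS of
exposure on score and covariates, then a probit of the outcome on
exposure, covariates and the first-stage residual. This differs from a
full-information conditional-MLE implementation; both are consistent
under the liability model, and the simulations here validate the
control-function form directly. SEs default to a nonparametric
participant bootstrap (500 reps, seeded) since plug-in stage-2 SEs ignore
first-stage noise; `se_method="plugin"` is used in the pipeline defaults
and validation studies, where problem sizes make the bootstrap's cost
unjustified and the plug-in SEs are verified against bootstrap SEs on
clean data. The odds-ratio approximation is `exp(1.6·β)` with a Wald CI,
reported per raw exposure unit or per SD (`scale`). The worry score is a
complete-case count of four binary items (0–4) fitted with a
proportional-odds model. The discovery/replication split removes only
participants *directly* related to a discovery member (no transitive
closure), mirroring the usual kinship-pruning convention.

## Two-sample estimators

* **Wald ratios**: first-order delta SEs `se_y/|b_x|`; the second-order
  term is omitted (instruments here are strong; a config hook exists).
* **IVW**: zero-intercept WLS, weights `1/se_y²`; multiplicative
  random-effects SE inflation `√(Q/df)` when Q exceeds its df.
* **MR-Egger**: WLS with intercept after orienting all exposure betas
  positive; residual variance floored at 1 (multiplicative random
  effects). Slope = causal estimate; intercept tests directional
  pleiotropy.
* **I²GX**: `max(0, (Q_GX − (L−1))/Q_GX)` on the exposure betas; values
  below 0.9 flag regression-dilution concern for Egger.
* **SIMEX**: exposure betas perturbed with `N(0, λ·se_x²)` on
  λ ∈ {0, 0.5, 1, 1.5, 2} (1000 reps/λ by default), mean Egger slope per
  λ, quadratic extrapolation to λ = −1. The grid and extrapolant are
  standard defaults; the reported SE is the plain Egger SE (a documented
  approximation). Seed-reproducible.
* **Weighted median**: interpolated 50% point of the cumulative
  normalized inverse-variance weights over ordered ratios; parametric
  bootstrap SE (1000 reps default — the SE method is a declared stand-in,
  as no analytic form is canonical).
* **Mode-based estimator**: Gaussian kernel density over the ratios,
  bandwidth `φ × 0.9·min(sd, IQR/1.349)·L^(−1/5)` (modified Silverman),
  evaluated on a 10,000-point grid spanning mean ± 5 SD; ties take the
  smallest grid argmax. φ defaults to 0.75; diagnostic density curves for
  φ ∈ {0.5, 0.75, 1} are exportable. Weighted variant weights each point
  by inverse ratio variance.
* **Heterogeneity test** between disjoint instruments:
  `z = (β_a − β_b)/√(se_a² + se_b²)`, two-sided normal p (identical to a
  1-df chi-square).

## Instrument handling

Scores are standardized with the in-sample population SD (mean 0, SD
exactly 1). Missing dosages are mean-imputed per SNP before scoring
(config-exposed) so the score is defined for every participant.
Harmonization flips dosages (d → 2−d) when the local effect allele is the
published other allele; strand-ambiguous A/T and C/G SNPs are flagged and
excluded under strict mode. The weak-instrument gate (F < 10) warns
rather than errors, since the F statistic is a reported quantity, not a
filter.

## Validation problem sizes

The simulation studies in `tests/test_acceptance.py` and
`scripts/acceptance.py` use sizes chosen as the smallest that make the
Monte-Carlo bands informative: FDR control uses 200 replicates × 500
outcomes at n = 1,000 through the vectorized linear path; scan
calibration uses one null cohort of 520 mixed-type outcomes at n = 2,000
through the full regression engine; IV probit recovery uses 100
replicates at n = 50,000 with plug-in SEs; dual-instrument consistency
uses 200 replicates at n = 3,000 with 97 SNPs. Deterministic quantities
(threshold and flow arithmetic, WLS closed forms, Li–Ji corner cases,
SIMEX limits) are checked exactly.

## Known limitations

No LD modelling or clumping; no genotype imputation or upstream genetic
QC (principal components are consumed as given covariates); flat code
expansion without ICD hierarchy semantics; no non-linear exposure
effects; no selection/collider-bias simulation; permutation-based FWER
and q-values are out of scope.
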