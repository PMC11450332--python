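# Methods

## The causal question and the estimation model

The pipeline performs one-sample Mendelian randomization with a dichotomized
exposure (overweight, mean BMI in [25, 30) at ages 75–85, versus normal
weight, [18.5, 25)) and a binary outcome (lifespan ≥ 85 years). Genetic
variants in eight obesity/BMI candidate genes (ADIPOQ, FTO, LEP, LEPR,
INSIG2, MC4R, PCSK1, PPARG) serve as instruments. Because few single
variants satisfy all three IV assumptions, the candidate pool is expanded
with *composite SNPs*: every unordered pair of QC-passing variants, with the
summed minor-allele dosage recoded 0/1→0, 2→1, 3/4→2. The recoded value is
the composite's minor-allele count by definition; composite dosages are
never re-aligned to the in-sample minor allele, even when their coded-allele
frequency exceeds 0.5 (which requires dependent constituents — it cannot
happen for two independent Hardy–Weinberg variants, whatever their MAFs).

Three pairing scopes are exposed (`all_pairs`, `between_genes`,
`within_genes`); the default pairs all QC-passing candidate variants with
each other. Pruning for linkage disequilibrium is applied to the final
candidate set, composites included, rather than to constituents first.

## Instrument screening

For each candidate dosage vector $d$ on the retained cohort:

* **Relevance** — logistic `exposure ~ d` *and* linear `mean BMI ~ d` must
  both be significant at `alpha` (default 0.05, the screening threshold for
  all assumption tests), and instrument strength must satisfy
  `F = ((n-k-1)/k) · r²/(1-r²) > f_min` (default 10, k = 1). For unrelated
  samples r² is the max-rescaled (Nagelkerke) R²: Cox–Snell
  `1 − exp(2(ll₀−ll₁)/n)` divided by its upper bound `1 − exp(2·ll₀/n)`.
  For family samples, a logistic mixed model (variational
  `BinomialBayesMixedGLM` with a family random intercept) supplies response
  residuals, and r² is the squared correlation between residuals and
  dosage — the simple-regression R², identical whichever variable is
  regressed on which. If the mixed model fails, the fallback is a
  fixed-effects logistic fit with cluster-robust errors, with a warning.
* **Independence** — confounders are identified once per cohort as the
  covariates significant in logistic `outcome ~ exposure + covariates`
  (any dummy level significant ⇒ the covariate is); each candidate is then
  tested against each identified confounder (OLS on dosage for continuous,
  chi-square contingency for categorical). Any association fails the
  candidate.
* **Exclusion** — logistic `outcome ~ d + exposure + confounders`, fitted
  for both exposure codings (binary and continuous mean BMI); the dosage
  coefficient must be non-significant in both.
* **LD pruning** — greedy: while any retained pair has squared dosage
  correlation ≥ `r2_max` (default 0.3), the highest-r² pair is processed
  and its member with the larger exposure-association p removed; ties break
  by r², then lexicographically larger id. The postcondition (all retained
  pairwise r² < threshold) is re-asserted by direct recomputation.

No multiple-testing correction is applied across candidates by default
(Bonferroni is available as an option). A `gwas` mode prepends an
exposure-association scan with covariates, keeping candidates at p < alpha.

## Estimators

Per qualified IV j, two univariate logistic regressions *without covariates*
give `betaX_j` (log-odds of exposure per coded allele) and `betaY_j`
(log-odds of outcome), with Wald standard errors; fits with separation
(|beta| > 15 or se > 30) drop that IV with a warning. Ratio estimates
`theta_j = betaY_j / betaX_j` carry first-order delta-method standard errors
`seY_j / |betaX_j|` (the contribution of seX is second-order and vanishes
under the null).

* **IVW**: inverse-variance weighted mean; algebraically identical to WLS of
  betaY on betaX through the origin with weights 1/seY² (asserted to 1e-10
  in tests).
* **Penalized IVW**: each IV's Cochran-Q contribution
  `Q_j = w_j (theta_j − theta_IVW)²` maps through the χ²₁ upper tail to
  `q_j`, and weights are scaled by `min(1, 20·q_j)` (penalty factor
  configurable). Reported as the primary estimate when standard IVW is not
  significant.
* **Weighted median**: the interpolated 0.5-cumulative-weight point of the
  ordered ratios (midpoint convention `s_j = cumsum(w) − w_j/2`); standard
  error by seeded parametric bootstrap (default 1,000 draws of
  betaX, betaY from normals at their standard errors). Note the midpoint
  convention means splitting an IV into two half-weight copies is only a
  no-op when the split atom does not straddle the crossing segment.
* **MR-Egger**: IVs oriented so betaX ≥ 0 (joint sign flips, to which all
  estimators are equivariant), then WLS `betaY ~ 1 + betaX` with weights
  1/seY². The slope is the causal estimate; an intercept CI covering 0 is
  the no-directional-pleiotropy verdict.
* **E-values**: per-IV odds ratio `exp(theta_j)` is converted to a risk
  ratio — default `sqrt(OR)`, appropriate because the outcome (surviving
  past 85) is common; a rare-outcome identity conversion is the
  alternative — then `E = RR + sqrt(RR(RR−1))` (RR < 1 first inverted), and
  the average/min/max over IVs reported.

P-values and 95% CIs are normal-theory throughout. The overall verdict
follows the rule: IVW p < 0.05 *and* Egger intercept CI covering 0. With
fewer than three IVs only IVW runs. The one-sample adjustment some external
MR packages apply is left as a documented no-op hook: the literature
phrasing is too vague to pin down a formula, and the estimators above are
computed exactly as defined.

### What the IVW estimator estimates here

With a dichotomized exposure, the ratio of marginal logistic coefficients
does not converge to the data-generating conditional log-odds `theta_true`.
Score-equation algebra for weak effects gives
`betaX ≈ Cov(d, X) / (p(1−p) Var d)` and `betaY ≈ theta·Cov(d, X)/Var d`,
so `theta_j → theta_true · p(1−p)` (p the overweight prevalence) — an
attenuation by the exposure's Bernoulli variance; with strong instruments
and boundary-concentrated BMI distributions the factor moves toward 1. The
calibration experiments therefore measure bias and CI coverage against the
estimator's own large-sample limit, computed by direct simulation at
n = 150,000, rather than against `theta_true`. Against that limit the
estimator is unbiased with nominal coverage, and under `theta_true = 0` the
limit is exactly zero, so type-I error is meaningful unmodified.

## Synthetic cohorts

The generator emulates the structure the analysis assumes. One
`numpy.random.Generator` seeded from the config drives all draws in a fixed
order (genotypes, covariates, family intercepts, BMI noise, BMI measurement
ages/noise, enrollment ages, outcome, event ages), so config + seed is
byte-reproducible.

* Genotypes: per-SNP allele-level Bernoulli draws at a MAF uniform in
  `maf_range` (default (0.2, 0.4)), i.e. Hardy–Weinberg proportions;
  optional correlated blocks (allele copying with probability
  `ld_block_rho`) exist only to exercise LD pruning; optional uniform
  missingness.
* Mean BMI = 21.75 (midpoint of the normal range, so both exposure groups
  are populated) + Σ beta_main·dosage + Σ beta_interaction·(recoded pair
  dosage, consecutive disjoint pairs by default) + confounder terms +
  family random intercept + N(0, `bmi_noise_sd`, default 2.5 kg/m²).
  Repeated measures (default 3) at ages uniform in [75, 85] add
  `bmi_measure_noise_sd` (default 0 — no published measurement-error value
  to emulate).
* Confounders act on *both* BMI and the outcome log-odds (that is what
  makes them confounders), entering linearly in their integer codes;
  marginal covariate distributions default to plausible cohort frequencies
  and are configurable.
* Outcome: Bernoulli with log-odds `0.2 + theta_true·overweight +
  confounder terms + pleiotropy terms` (direct dosage→outcome effects give
  MR-Egger and the exclusion test positive controls). Survivors are
  censored alive at ages ≥ 85; deaths occur uniformly in [76, 85), so the
  binary outcome is always determinable and exact ages matter only to the
  Kaplan–Meier output.

What the generator does *not* emulate, hence what passing tests do not
show: realistic LD structure, genotype sharing within families (the family
effect is an environmental BMI intercept only), age trends in BMI within
the window, informative censoring, genotyping batch effects, or population
stratification beyond two synthetic PC covariates.

### Reference conditions for validation experiments

Calibration experiments use 32 SNPs (4 per gene) with per-allele BMI
effects of alternating sign ±0.6 kg/m², MAF in (0.2, 0.4) and residual BMI
sd 2.0 — signs alternate so the genetic burden leaves mean BMI near the
normal/overweight boundary, and the magnitude puts single-SNP instrument
strength near F ≈ 20–30 at n = 5,000, comfortably above the F > 10 bar.
Problem sizes: parameter recovery uses 100 replicates at n = 5,000 with 30
instruments against an n = 150,000 reference; type-I error uses 500
replicates; Egger pleiotropy recovery uses 200 replicates of 100
summary-statistic instruments; screening uses 20 replicates at n = 10,000
with 10 valid and 10 pleiotropic (0.25 log-odds per allele) planted
instruments.

## Survival and descriptives

Kaplan–Meier curves per exposure group use delayed entry at
max(enrollment age, 75); an individual entering exactly at an event age is
treated as entering just before it (implemented as a 1e-9 year nudge), and
individuals whose event precedes entry are excluded with a count.
Confidence bands are lifelines' default log-log (exponential Greenwood).
The descriptive table reports mean (sd) ages and n (%) characteristics per
sex × race stratum, including empty strata, with per-variable missing
counts; percentages are over the stratum's non-missing values.

## Numerical choices and degenerate inputs

* Logistic fits: Newton, falling back to BFGS (500 iterations) on failure;
  separation is detected post hoc by coefficient/se magnitude.
* QC filters (variant call rate 0.95, individual call rate 0.95, MAF 0.01,
  HWE exact p 1e-6 — configurable stand-ins for published protocols) are
  iterated to a fixed point, which makes the operation idempotent; the HWE
  exact test uses founders only when pedigree information identifies them.
* Monomorphic candidates fail screening with an explicit reason; an empty
  qualified set aborts MR with the stage named, after writing the partial
  report flagged incomplete.
* The pipeline seed expands into per-stage substreams via
  `SeedSequence([seed, stage_index])`, so standalone stage reruns reproduce
  the monolithic run exactly.
* Age window [75, 85] is closed on both ends; BMI bins are half-open at 25
  and 30. Individuals censored alive before 85 are excluded
  (`outcome_undetermined`) — their outcome is unknowable.
* Missing dosages drop individuals pairwise, per instrument.

## Known limitations

Two-sample and multivariable MR, MR-PRESSO, colocalization, VCF input,
non-integer dosages, and higher-order (triplet+) composites are out of
scope. The weighted-median standard error is bootstrap-only. The
assumption-test alpha has no published value to match and is a design
default. Real-data QC beyond the four threshold filters (batch effects,
relatedness inference, population structure) must happen upstream.
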