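# Methods

`prscohort` compares the germline polygenic risk of two cancer cohorts —
a small "case" cohort of exceptional responders and a larger "control"
cohort of typical cancer patients — using previously published PRS
weight sets. This note records the statistical model each stage
implements, the defaults and why, what the synthetic generator does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## The score and its normalization

For a weight set with variants *i = 1..n*, the raw score of sample *s*
is

    PRS_s = Σ_i w_i · X_si

with `X_si` the count (0/1/2) of the *effect* allele. VCF dosages count
ALT alleles, so each model variant is oriented first: effect = ALT uses
the dosage as-is; effect = REF uses `2 − dosage`; any variant whose
allele pair does not match the genotyped REF/ALT pair is excluded and
reported. Palindromic (A/T, C/G) sites are matched exactly, with no
strand flipping — deterministic, at the cost of missing strand-swapped
encodings — and are counted in the orientation report so a user can
audit them.

Scores are normalized with the **control** cohort's mean and SD, so 0
is "the average typical cancer patient" and logistic slopes read as
log-odds per control SD. Control-anchored (rather than pooled)
standardization pins the interpretation of 0; a pooled mode exists for
sensitivity analysis. Residual missing dosages (after QC) are replaced
by the control-cohort mean dosage of the variant, keeping the fill-in
independent of case status; a skip-variant mode is deliberately off by
default because it changes the score scale per sample.

## Quality control

* **Genotype quality**: genotypes with GQ ≤ 20 are set missing (the
  retention rule is strictly GQ > 20). Records without a GQ annotation
  are not masked — a filter cannot be applied to absent data.
* **Imputation quality**: variants annotated with R² ≤ 0.8 are dropped;
  unannotated variants are treated as directly genotyped and retained.
  This treatment of unannotated variants is an assumption, flagged here
  because upstream pipelines differ.
* **Call rate**: variants observed in < 90% of samples are removed
  (exactly 90% is retained).
* **Hardy–Weinberg**: the exact (Levene–Haldane) two-sided test at
  α = 0.001, computed on the observed genotypes of the combined
  case+control sample after the shared-variant intersection. Combined
  testing is a single reproducible rule appropriate to a
  jointly-genotyped comparison; per-cohort testing is a config switch.
  The conditional probabilities of all heterozygote counts compatible
  with the allele margin are evaluated by the standard ratio
  recurrence, started at the distribution mode so intermediate values
  cannot overflow; configurations with probability equal to the
  observed one are included in the p-value (ties use ≤).
* **Shared variants**: both cohorts are restricted to the variant keys
  present in each before any comparison.
* **Multiallelic records** are rejected by default (counted in the read
  log); a naive per-ALT split is available. Sex chromosomes are
  excluded at read time by default.

## Ancestry check

PCA on the mean-imputed, centered dosage matrix (full SVD, so results
are deterministic). Because the original exclusion of divergent samples
was a visual call, the package substitutes a reproducible rule: a
sample is flagged when its robust z-score — (score − median) /
(1.4826·MAD) — exceeds 6 on either of the first two components. The
threshold is configurable; 6 is deliberately far in the tail so that
only gross ancestry divergence (the intended target) is flagged, not
ordinary within-cohort spread. This rule is a stand-in for the
original visual judgement, not a reconstruction of it.

## Control matching

Controls are downsampled so organ-site proportions match the cases.
Integer allocations use largest-remainder (Hamilton) apportionment:
quota = total·case_s/Σcase, floors first, remaining units to the
largest fractional parts, ties broken lexicographically. This scheme
deterministically reproduces the published matched-subset sizes
(106/57/41/33/33/24/24/16/16/16/8×6 = 414 against case counts
13/7/5/4/4/3/3/2/2/2/1×6), which is the reason it was adopted; no claim
is made that it is the original authors' code. Within strata, sampling
is uniform without replacement from label-sorted candidates, so the
draw depends only on the plan, the pool content and the seed.

## Association statistics

* **OR per SD**: intercept+slope logistic regression of case membership
  on the normalized score, no covariates (the study design argues
  ancestry and demographics are already matched). Wald CI
  `exp(β ± 1.96·se)` and two-sided Wald p. Complete separation is
  detected (non-convergence or |β| > 15) and raised as an error rather
  than reported as a number.
* **Skewness**: `b1 = [(1/n)Σ(x−x̄)³] / [(1/(n−1))Σ(x−x̄)²]^{3/2}` —
  note the mixed 1/n and 1/(n−1) denominators; this matches the
  convention of the R `normtest` family rather than the pure moment
  estimator. Normality is tested by Monte Carlo: n_sim (default 2000)
  standard-normal samples of the observed size, add-one p-value
  `(1 + #{|b1_sim| ≥ |b1_obs|})/(n_sim+1)`, two-sided by default
  (one-sided available) and seeded.
* **Per-variant tests**: effect-allele counts over non-missing
  genotypes (totals 2 × observed samples), two-sided Fisher exact test
  summing hypergeometric configurations no more probable than the
  observed table. Probability comparisons are done on exact integer
  numerators (`math.comb`), so ties are handled exactly and no
  floating-point slack enters the definition; `fisher_pvalue_grid`
  evaluates every table for fixed per-cohort totals in one pass, one
  conditional diagonal at a time. Benjamini–Hochberg step-up q-values
  correct across variants. Allele-count (2n) tables are the default;
  carrier-count tables are a config mode.
* **Co-occurrence**: a sample "carries" a variant when its effect
  dosage ≥ 1; entry (i, j) is the proportion of samples carrying both
  variants, so the diagonal is the per-variant carrier proportion.
  Missing genotypes count as non-carriers and remain in the denominator
  by default (logged); the cohort difference matrix is case − control,
  bounded in [−1, 1]. Heatmap ordering is presentation only and never
  changes values.

## Survival

Controls are split at the empirical 10% and 90% score quantiles
(linear-interpolation order statistics, NumPy's default "type 7") into
low/middle/high genetic-risk groups; samples with unknown vital status
are excluded. Kaplan–Meier curves use the product-limit estimator
(via lifelines); the log-rank test is computed directly with the
pooled-tie hypergeometric variance so per-group observed and expected
event counts are available (they are cross-checked against lifelines in
the test suite). By default only the low and high groups are compared;
a three-group test is a config switch.

## The synthetic generator

The generator emulates the *statistical* structure the analysis
assumes, not any real dataset:

* Genotypes: independent loci, frequencies uniform on (0.05, 0.5),
  diploid draws Binomial(2, p) — exact HWE, no LD. Published weight
  sets have LD structure; nothing here tests robustness to it.
* Weights: normal(0, 0.1), 66 variants by default (the size of the
  smallest weight set the pipeline targets).
* Case membership: logistic liability — a pool (default 6× the final
  cohort sizes) is scored, pool-standardized, and each sample becomes a
  case with probability `expit(α + β·z)`, with default β = ln 2.66 per
  SD. α is calibrated by bisection so the *expected* case yield is
  twice the requested cohort (`case_oversample = 2`); cases and
  controls are then uniformly subsampled to exact sizes. Uniform
  subsampling of each outcome class preserves the logistic slope
  (standard retrospective-sampling invariance), so the oversampling
  affects yield reliability, not the estimand; with expectation exactly
  equal to the target, roughly half of all draws would fall short and
  error out.
* Skew: `skew_mixture = (fraction, shift)` leaves `fraction` of cases
  in the baseline component and moves the remaining cases up by
  `shift` pool-SD. The shift is realized by redrawing those samples'
  genotypes from exponentially tilted allele frequencies
  (`p′ = p·e^{θw}/(p·e^{θw}+1−p)`, θ solved so the mean score shift is
  exact), keeping genotypes and scores consistent. With (0.3, 2.0) the
  case distribution is left-skewed (theoretical mixture skewness
  ≈ −0.27): most cases sit high with a minority low tail, the
  asymmetry the comparison is designed to detect. Note that a mixture
  this shape is a *small* skew signal at n = 51; the test suite
  measures the detection rate rather than assuming it.
* Encoding realism: half the variants (configurable) are written with
  the effect allele as the VCF REF, so the orientation/flipping path is
  always exercised.
* Planted QC failures: exact counts of R² = 0.5 annotations,
  call-rate failures (missingness pushed just above 10%), one
  all-heterozygote HWE violation, and GQ = 15 genotype-quality
  failures at a configurable rate — all recoverable by the QC report,
  which is what the QC tests assert.
* Survival: exponential event times per cohort (default medians 12.77
  and 2.89 years for cases/controls) with independent exponential
  censoring calibrated so ~92% / ~64% are alive at analysis.
* Phenotypes: organ sites from the 16-site case mix, sex ≈ 39% male,
  age ≈ N(64, 9) — used for matching and stratification plumbing only.

All randomness derives from one master seed through named substreams
(model / genotypes / phenotypes / survival / qc), so stage-level tests
do not depend on which other stages run.

What passing tests therefore show: the estimators are unbiased and
correctly calibrated *when the generating model holds* (independent
HWE loci, logistic link, exponential survival). They do not show
robustness to LD, ancestry admixture beyond the planted-outlier shift,
genotyping batch effects, or non-proportional hazards.

## Problem sizes used in validation

Calibration checks run at the study scale the pipeline targets — 51
cases vs 414 controls, 66 variants — with 300–1000 replicates for
means, coverage and error rates (Monte-Carlo SE on a 95% coverage
estimate at 500 replicates is about 1%). Exact-test agreement with
enumeration oracles is verified exhaustively for all Hardy–Weinberg
configurations with n ≤ 50 and all Fisher tables with per-cohort
allele totals ≤ 60.

## Known limitations

* No LD awareness anywhere: weight sets are treated as independent
  variants (consistent with applying published scores, but the
  generator cannot probe LD sensitivity).
* No liftover: chromosome/position mismatches between model and VCF are
  simply non-matches; the package assumes one genome build.
* The ancestry rule is internal clustering only — no reference-panel
  projection.
* Matching is stratum-exact on organ site (optionally sex); no
  propensity or survival-time matching.
* The logistic model is unadjusted by design; confounding beyond the
  matched covariates is out of scope.
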