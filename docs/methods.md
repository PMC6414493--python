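# Methods

This note records the statistical models implemented in `polyhazard`, the
assumptions behind them, the choices made where the design was genuinely
open, and what the synthetic cohorts do and do not establish about real
data.

## Cohort generator

The generator (`synthetic_cohort`) emulates the structure of a late-onset
Alzheimer's case/control genotyping study.

**Genotypes.** Variants live in LD blocks. Per block, each individual's
two haplotypes are drawn from a latent AR(1) Gaussian process with lag-1
correlation ρ (`within_block_corr`, default 0.8) and thresholded at each
variant's MAF quantile; the dosage is the haplotype sum. This yields
Hardy–Weinberg genotype frequencies per variant, monotonically decaying
dosage r² within a block (ρ = 0.95 between adjacent variants with MAF 0.3
induces dosage r² ≈ 0.62), and independence across blocks. No claim is
made that this matches human LD maps; it provides *tunable, seedable* LD
so that clumping with the 1000 kb / r² ≤ 0.1 rule is exercised. Variants
are spaced 10 kb apart (1-based positions) on one synthetic chromosome,
so a 1000 kb window spans 100 variants.

**APOE-like locus.** Encoded as two allele-count variables (ε2, ε4
copies), not a six-genotype factor, matching how the scores consume it.
Default frequencies 0.08 / 0.15 and per-allele log hazard ratios
−0.47 / +1.03 — the published APOE values — with the constraint
ε2 + ε4 ≤ 2 enforced by drawing per-haplotype alleles from
(ε2, ε4, ε3) ~ (0.08, 0.15, 0.77).

**Onset ages.** A Weibull proportional-hazards model on the age scale:
with linear predictor η (causal SNP dosages, APOE counts, sex, 3 PCs),
onset is T = λ(−ln U / e^η)^{1/k}, baseline shape k = 6 and scale λ = 90
years. Assessment ages are Normal(72, 8) truncated at 0. Case iff
T ≤ assessment age; controls are right-censored at assessment. Defaults
give roughly 15–25% cases and onset ages concentrated in the 60s–80s —
the right *range* for a late-onset study, chosen a priori, not fitted to
any dataset. Covariate defaults (sex +0.2, PCs +0.1/+0.05/+0.02 on the
log-hazard) provide mild confounding for the adjustment machinery to
remove.

**Birth-cohort block.** A fraction (default 0.765) of controls is
re-assessed at exactly age 45, mimicking a population panel recruited at
a fixed age. Because the rule applies to *controls*, eligibility is
restricted to controls whose latent onset lies beyond 45 so status is
preserved. This makes the added censoring status-conditional and
therefore mildly informative: measured on the default generator it
attenuates a true unit coefficient to ≈ 0.92. That is a property of the
emulation (a deliberate mirror of the awkward real design, where one
would likewise worry about the age-distribution mismatch — hence the
age ≥ 55 sensitivity filter), not of the estimators; the
estimator-recovery study therefore runs with this block disabled.

**Onset imputation.** 8% of cases (default) have onset blanked and only
the assessment age kept; `impute_age_at_onset` fills onset as assessment
− 5 years and flags the row. The 5-year offset is the conventional mean
lag between onset and last assessment in this design. Cases with no age
information at all are dropped with a warning. Imputation introduces
measurement error in event times (slight attenuation), accepted as part
of the emulated procedure.

## Association scans

Each SNP is tested twice, always adjusted for sex + 3 PCs, with missing
dosages mean-imputed per variant:

- **logistic** regression of case/control status (no age term); log OR
  per effect-allele copy. Fits use Newton/IRLS (statsmodels backend);
  separation and non-convergence are flagged and those variants excluded
  from weights rather than penalized.
- **Cox** regression with age as the time axis — onset age for cases
  (events), assessment age for controls (censored); log HR per copy.
  Entry is at age 0 (no left truncation), consistent with the simple
  (age, status) usage the pipeline mirrors.

The Cox engine (`_cox`) maximizes the partial likelihood with the Efron
tie correction (Breslow behind a flag) by Newton's method with
step-halving; convergence at |Δ log-lik| < 1e-8, cap 50 iterations; the
log-likelihood path is monotone by construction and the maximized value
is stored for nested LR tests. It matches `lifelines.CoxPHFitter` to
1e-5 on betas/SEs and 1e-6 on the log-likelihood in the test suite.
Wald P-values are exactly 2Φ(−|β/SE|) throughout.

**QC.** A variant is dropped iff MAF < 0.1, missingness ≥ 0.05 (boundary
inclusive), HWE P < 1e-6, or — when an imputation INFO column is supplied
— INFO < 0.4. HWE is the 1-df chi-square goodness-of-fit test computed on
**controls only** (cases are enriched at truly associated loci), a
standard GWAS convention recorded on the QC report; monomorphic variants
return (χ² = 0, P = 1).

## SNP selection

Greedy clumping: visit variants by ascending P (ties broken by
chromosome, then position, for reproducibility); keep a variant iff its
dosage r² with every already-kept variant on the same chromosome within
1000 kb (center-to-center) is ≤ 0.1. r² is the squared Pearson
correlation of dosages over pairwise-complete individuals, computed on
the discovery-subset genotypes (the only genotypes in hand; no external
reference panel). The full variant set is pruned **once**, then the
threshold grid (P ≤ 5e-8 … 0.5, inclusive) is applied to the pruned set,
so selections are nested across thresholds. An exhaustive-pair
brute-force reference reproduces the greedy output exactly on random
instances (acceptance study).

## Scores

Weighted sums of effect-allele dosages; APOE rows are keyed to the
allele-count columns. Allele alignment: a weight whose effect allele
matches the cohort's coded allele contributes w·d; matching the other
allele contributes w·(2−d) (flip flag); anything else is dropped and
reported. Missing dosages contribute the variant's mean dosage (keeps
the score scale comparable across individuals); individuals missing APOE
counts are excluded from APOE-involving variants. Dosages are **not**
MAF-centered — the score is the plain weighted allele count.

"Adjusted for covariates and then standardized" is implemented as
**residualize-then-z-score**: each raw score is regressed on an intercept
+ sex + 3 PCs by least squares and the residual scaled to mean 0, SD 1
over the analysis sample (tolerance 1e-8 in tests). The alternative
reading — covariates only inside the Cox model — remains available
because the evaluation model always includes the covariates anyway; the
residualization additionally removes score–covariate correlation from
the reported per-SD effect.

**Published weight table.** The packaged table ships the 31 SNPs plus
APOE ε2/ε4 with three weight columns (log HR; log OR from the full and
from the leave-one-cohort-out meta-analysis) exactly as printed, including the
sign disagreements between the log-HR and log-OR columns for several
SNPs (their effect-allele codings were evidently not harmonized in the
source). The loader validates structure (2 + 31 rows, finite numeric
weights), not signs; alignment is the consumer's responsibility. The
analysis drivers show the consequence honestly: applied verbatim against
a single fixed coding, the two weight sets produce only weakly correlated
scores, whereas weights derived in one coding (the cross-validation
pipeline) give correlations near 1 at strict thresholds.

## Evaluation

`evaluate_score` fits age ~ score term(s) + sex + 3 PCs by Cox
regression; `lr_nested_test` compares nested fits on identical rows via
2Δ log-lik against χ² with the parameter-count difference (identical
models return statistic 0, P 1). The PH diagnostic is the
Grambsch–Therneau score test on scaled Schoenfeld residuals with the
Kaplan–Meier time transform (the default behavior of the standard R
diagnostic); per-term and global statistics. It agrees with lifelines'
implementation to ~0.02 in P on shared examples, and its measured
operating characteristics (acceptance study: n = 4000, 20 seeds) are
type-I ≈ nominal under PH and power ≈ 1 against a built-in sign-reversal
violation (effect +β before age 65, −β after, simulated by piecewise
inversion of the cumulative hazard).

Kaplan–Meier quantile curves: individuals are binned at the empirical
5/25/75/95 percentiles of the evaluated sample's standardized score
(right-closed; ties fall to the lower bin), one KM curve per bin
(lifelines estimator). In-sample quantiles were chosen over external
ones because every reported evaluation is within one analysis sample.
The ε3/ε3 subgroup keeps individuals with zero ε2 and zero ε4 copies;
scores there are rebuilt and re-standardized within the subgroup, and
only the SNP score is evaluated (the APOE score is constant by
construction).

## Cross-validation and subsampling

"Fivefold cross-validation" over random 75/25 splits is implemented as
**5 repeated seeded stratified 75/25 splits** (the printed discovery/
validation counts in the source design are not a disjoint 5-fold
partition); a strict disjoint stratified k-fold mode exists behind
`strict_kfold` but is not the default. Per repetition: both scans on
discovery; clumping priority P-values from an external summary-statistics
table when provided, else from the discovery logistic scan; per
threshold, PHS (Cox betas) and PRS (logistic betas) built, adjusted and
standardized in validation and evaluated by Cox. Reported per threshold:
mean/SD of validation betas, mean P, mean PHS–PRS Pearson correlation;
thresholds empty in a fold are NA-reported. All randomness flows from the
run seed through `numpy.random.SeedSequence`, so reruns are
bit-identical. The subsample analysis draws stratified 20–100% fractions
with a fixed weight table and re-evaluates; fraction 1.0 reproduces the
direct full-sample evaluation exactly.

## Verification studies and problem sizes

The acceptance battery (`polyhazard.benchmarks`, driven by both
`tests/test_acceptance.py` and `scripts/acceptance.py`) uses sizes chosen
to keep Monte-Carlo error well inside the asserted bands while the whole
battery completes in a few minutes on one core:

- clumping oracle: 50 random 200-SNP / 20-block instances;
- recovery: n = 5000, 60 independent SNPs (one per block), 12 causal with
  log-HR ~ N(0, 0.12), 10 seeds; independence keeps the marginal
  per-allele log-HR equal to the generating coefficient up to negligible
  non-collapsibility attenuation, and the birth-cohort block and onset
  imputation are disabled (see above) so the estimand is the generating
  parameter;
- null calibration: 1000 independent null SNPs at n = 2000 for the KS
  uniformity check (independent SNPs because KS assumes independent
  P-values); 1000 replicates at n = 300 for the nested-LR size;
- threshold-grid pattern: n = 4500, 800 SNPs in 80 blocks, eight SNPs in
  distinct, well-separated blocks with per-allele log-HR ±0.5 (fixed
  magnitude so every true effect clears the genome-wide threshold and
  looser thresholds add only noise), 5 repeated splits; monotonicity is
  asserted up to a small pre-set slack (0.01 on betas, 0.005 on
  correlations) covering fold noise between near-identical adjacent
  selections;
- PH diagnostic: n = 4000, 20 seeds under PH and under the sign-reversal
  generator with τ = 65 (within the observed event-age range).

## What passing tests do and do not show

The synthetic cohorts share the real design's *statistical skeleton* —
censoring pattern, APOE-scale effects, LD with tunable decay, threshold
grids — but not human allele-frequency spectra, realistic LD maps,
population stratification beyond Gaussian PCs, genotyping error, or
competing mortality. Passing the battery shows the estimators,
selection rules and pipeline plumbing are correct and calibrated under a
proportional-hazards world; it does not certify predictive performance
on any real cohort.

## Known limitations

- Left truncation (delayed entry) is not modeled; all subjects enter at
  age 0 on the age axis.
- The controls-only fixed-age-45 rule is mildly informative censoring by
  construction (quantified above).
- Per-variant Cox scans refit the covariates for every SNP (no score-test
  shortcut); adequate at the package's scale, slow at biobank scale.
- The PH diagnostic implements the classic score test, not the newer
  refit-based variant of the R diagnostic (≥ 3.0).
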