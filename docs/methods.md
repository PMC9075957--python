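# Methods

`poenet` infers networks through which parent-of-origin effects propagate:
from reciprocal-cross allelic and total expression counts, through
allele-specific expression (ASE) and differential-expression (DE) detection,
ASE → DE edge prediction, phenotype association, and
imprinting-by-imprinting epistasis in an advanced intercross, plus the
single-cell statistics used to follow candidate genes along a
differentiation trajectory. This note records the models, the parameters
that matter, and the design choices made where the procedure was genuinely
open.

## The reciprocal-cross model

Two inbred lines, L and S, are crossed in both directions. In the F1, every
animal is genetically identical up to the parental origin of each allele, so
any expression difference between the reciprocal crosses (LxS vs SxL,
maternal parent first) isolates parent-of-origin effects from allele
identity. Allelic bias of a gene in a sample is

    L_bias = L / (L + S),

the fraction of its reads carrying the L haplotype. An imprinted gene sits
near 1 in the cross where its expressed allele is the L allele and near 0 in
the reciprocal cross; a biallelic gene sits near 0.5 in both. The POE score,

    score = mean L_bias(SxL) − mean L_bias(LxS),

runs from −1 (fully maternally expressed) through 0 (biallelic) to +1
(fully paternally expressed). Per-context scores (sex × diet) are also
available because a gene can be paternally expressed in one context and
maternally in another, cancelling in the pooled score.

## Synthetic data

The generator (`poenet.simulate`) produces every input the pipeline
consumes, with ground truth attached:

- **Design.** 2 crosses × 2 sexes × 2 diets × `n_per_cell` animals. The
  defaults mirror the emulated study: 12 per cell (96 F1 animals, 48 per
  cross) for the full cohort, 4 per cell (32) for expression analyses, and
  1002 animals for the advanced intercross.
- **Allelic counts.** Total depth per gene × sample is negative binomial
  (default mean 100, dispersion 0.1 — RNA-seq depth is overdispersed, and
  the analysis is insensitive to this choice). The L count is beta-binomial
  with mean bias μ (0.5 unless planted) and dispersion ρ, parameterized
  α = μ(1−ρ)/ρ, β = (1−μ)(1−ρ)/ρ so that ρ = 1/(1+α+β). Default ρ = 0.01,
  well inside the ρ < 0.05 regime a complex library exhibits.
- **Expression.** Negative binomial with log-linear effects. A planted DE
  gene with log2 fold change f has means baseline·2^(±f/2) in the two
  crosses. Edge targets add `coupling · z` to their log mean, where z is the
  standardized realized log1p expression of the upstream ASE partner — the
  generative analogue of the regression the network stage fits. Default
  baseline 500, NB dispersion 0.05.
- **Intercross.** Each parental haplotype is a first-order Markov chain
  along a chromosome with switch probability 0.5(1 − exp(−2·ld_decay·d))
  for distance d in Mb: approximately `ld_decay` switches per Mb at short
  range, saturating at independence. Genotypes are ordered
  maternal|paternal strings. Phenotypes are sex + diet + sex:diet + planted
  β3·score_A·score_B + Gaussian noise, with effects in noise-SD units.
- **Cells.** Poisson counts per cell from its cluster's mean profile, with
  a marker whose mean rises monotonically across ordered clusters.

What the generator does *not* emulate: mapping bias and read-level
artifacts, within-domain correlation of allelic bias across genes, batch
effects, library-composition differences beyond what TMM absorbs, and
zero-inflation beyond Poisson/NB sampling. Passing tests therefore
demonstrate correctness of the statistics under the stated models, not
robustness to those real-data pathologies — which is exactly why the
pipeline retains permutation-based error control rather than analytic
corrections.

## ASE detection

Totals are upper-quartile normalized (per-sample scale = 75th percentile of
nonzero totals, rescaled to geometric mean 1) and genes must reach a
normalized depth of 20 in every sample; requiring the floor in all samples
(rather than on average) keeps every retained gene informative in every
context, at some cost in sensitivity for unevenly covered genes.

Parent-of-origin dependence is tested by ANOVA under the most complex of
four nested conditional models whose every conditioning cell holds ≥ 2
informative samples: `L_bias ~ Cross`, `+ Cross:Sex`, `+ Cross:Diet`, or the
full `+ Cross:Sex + Cross:Diet + Cross:Sex:Diet`; a gene with < 2 samples in
either cross is untestable. Because each of these models spans exactly the
cell means of a factor partition (cross; cross×sex; cross×diet;
cross×sex×diet), the omnibus F-test against the intercept is computed as a
one-way ANOVA over that partition. All terms contain cross, so the omnibus
test is the parental-origin test; the exact contrast was an open choice and
the omnibus is the most conservative one that uses the full model.

Significance is controlled by permutation: each iteration shuffles the full
(cross, sex, diet) label tuple independently per gene — implemented as a
per-gene permutation of the L_bias values against the fixed design, which is
the same test — and model selection plus testing is rerun. The empirical
FDR at threshold t is

    FDR(t) = [#null ≤ t / N_null] / [#real ≤ t / N_real],

clamped to [0, 1], with ties at t counted as significant. A gene is called
at FDR ≤ 0.1 *and* a POE score beyond the two-sided α = 0.01 critical values
of the score permutation null. Library complexity is checked by
maximum-likelihood beta-binomial fits (Nelder–Mead over (log α, log β),
method-of-moments start); ρ < 0.05 indicates a complex library, and
degenerate all-one-allele data returns a boundary flag instead of failing.

## Differential expression

TMM scale factors follow the standard definition: reference = sample whose
upper quartile of depth-scaled counts is closest to the mean; per sample, a
precision-weighted mean of gene-wise log2 ratios after rank-trimming 30% of
M and 5% of A on each side; factors rescaled to geometric mean 1. The
implementation agrees with edgeR's `calcNormFactors` to ~1e-6 on shared
input (frozen cross-check in the test suite) and with a plain brute-force
restatement to 1e-8. Genes must reach a normalized count of 10 in all
samples of at least one sex × diet context and enter testing only in
contexts where they pass.

Five NB log-linear models are fitted per gene with an effective-library-size
offset: `~Cross`, `~Cross:Sex`, `~Cross:Diet`, `~Cross:Sex:Diet`, and the
full additive-interaction form. Each is a cell-means model over its factor
partition, fitted by per-cell Newton iterations with a single common
dispersion estimated by maximum Cox–Reid adjusted profile likelihood shared
across genes (tagwise shrinkage is deliberately out of scope; a single
dispersion is reproducible and adequate at these design sizes). The
likelihood-ratio test compares each model against the matched environmental
null — the same partition with the cross dimension removed (intercept; sex;
diet; sex×diet) — so sex and diet main effects are never mistaken for cross
effects. All (gene, model) p-values are pooled into one Storey q-value
calculation (λ grid 0.05–0.95, cubic-spline extrapolation at λ → 1, clamped
to (0, 1]); a gene's q is its smallest pooled q, and the DE call requires
q ≤ 0.1 and a largest-magnitude context fold change ≥ 1.5.

## Network edges

A candidate edge regresses a DE gene's expression on an ASE gene's
expression, that gene's L_bias, sex, diet, and sex:diet. Edge strength is
the mean held-out MSE (MTE) over 10 cross-validation folds stratified by
(cross, sex, diet), with fold assignment keyed to sample ids so it is
invariant to sample order and deterministic under the seed. Edge
significance is the Gaussian likelihood ratio n·log(RSS_reduced/RSS_full)
for dropping the two ASE predictors; its p-value is taken from the exact
finite-sample F null of the monotone-equivalent statistic, because the
χ²(2) limit is visibly anticonservative at n = 32 (the χ² reference remains
available via `p_method="chisq"`).

The genome-wide null shuffles context rows (one permutation) and the paired
(ASE expression, L_bias) columns (an independent permutation) and re-tests
every candidate edge; which variables the original shuffle permuted jointly
was unstated, and this choice breaks the edge association while preserving
all marginals. Per-iteration α = 0.05 critical values are tracked and the
run may stop once the SD of the last five is below 1% of their level; a
fixed 500-iteration schedule with 759 tests per iteration pools exactly
379,500 null observations. π0 is estimated from null-calibrated p-values,
q-values on the real LRT p's are scaled by it, and the MTE critical value is
the α = 0.01 quantile of the null MTE pool; an edge needs q ≤ 0.1 and
MTE ≤ critical value. Because MTE is an absolute error, the pooled critical
value is only meaningful when candidate genes are on comparable scales
(log-transformed expression); recovery tests therefore plant couplings at
matched marginal variance.

## Phenotype association

Phenotypes are log10-transformed iff Shapiro–Wilk rejects normality at
α = 0.05 on the raw values *and* the log scores a higher Shapiro–Wilk p
(the original gate said only "when necessary"; this is the recorded
operationalization). Sex, diet, and sex:diet are residualized out by least
squares, leaving the cross effect. Gene–phenotype Pearson correlations are
computed on complete cases, q-valued in one pool, and carried forward when
|r| ≥ 0.5 and q ≤ 0.05. Cross-generation validation uses a percentile
bootstrap (5000 resamples of size 10 with replacement, 90% interval;
degenerate resamples are redrawn and counted — percentile rather than BCa,
matching the plain description), one-way ANOVAs under three genotype codings
(cross: LL 0, LS −1, SL +1, SS 0; paternal allele: LL 0, LS 1, SL 0, SS 1;
mitochondrial ancestry of F2 cohorts), and a product-predictor regression
phenotype ~ a·b that is powered for interaction-only signals.

## Epistasis

Each marker's imprinting score codes the ordered maternal|paternal genotype
as LL → 0, LS → +1, SL → −1, SS → 0: homozygotes carry no parental-origin
contrast and the heterozygote sign records which parent transmitted L.
Candidate markers lie within ±1.5 Mb of a gene's geometric center. After
the covariate screen (Shapiro–Wilk-gated log10, then residualization on
sex + diet + sex:diet), epistasis is the partial test of the product term in

    R_pheno ~ BDE_imp + ASE_imp + BDE_imp:ASE_imp

fitted by ordinary least squares (the phenotypes are continuous residuals,
so the identity-link Gaussian GLM is the stated model). Permutations
shuffle whole animals — rows of the score matrix — preserving within-animal
linkage among markers and every marker's marginal score distribution
exactly; FDR uses the same null/real ratio as the ASE stage at 0.1. When a
gene's window holds several markers, all marker pairs are tested and
corrected together.

## Single-cell statistics

QC keeps cells with 500–3000 detected genes and 1000–30,000 counts (both
ranges inclusive) and, because detected genes should covary smoothly with
depth, removes cells whose residual from a penalized-spline fit of features
on counts is more than 3 SD from the mean residual (linear fallback, with a
warning, when the spline degenerates — e.g. zero residual variance).
Normalization is ln(1 + 10,000·count/cell total).

Cluster-resolution selection uses two marker statistics: the count variance
Cσ̄ (mean across clusters of the SD of marker expression over *expressing*
cells; clusters with < 2 expressing cells are skipped, so padding with
non-expressing cells changes nothing) and the percent-expressing variance
(the spread of per-cluster expressing fractions — a per-cluster percentage
is a scalar with no within-cluster SD, so the SD is taken across clusters;
this reading of an ambiguous formula is recorded here). The chosen
resolution is the lowest whose Cσ̄ is within 5% of the minimum and whose
successor changes it by less than 5% (one-step look-ahead plateau); a
strictly decreasing sequence returns the last resolution with a warning.

Trajectory DE between two clusters uses a pluggable two-group test
(rank-sum built in; a MAST-style hurdle test satisfies the same contract),
Bonferroni correction over the genes actually tested, and an effect filter:
|log2FC| ≥ 0.3 *or* pct.Δ ≥ 0.4, where pct.Δ = |pct2 − pct1|/max(pct1, pct2)
is reported as a magnitude so the filter is symmetric in cluster labels
(undefined when neither cluster expresses the gene). Cluster assignment is
a pluggable contract; the built-in PCA + k-means default exists only so
resolution selection runs without external graph-clustering tooling.

## Numerical choices and degenerate inputs

- Zero residual variance in an ANOVA returns a boundary p (0 if group means
  differ, else 1) with a flag rather than an error.
- Empirical FDR is clamped to [0, 1]; it is *not* monotone in the threshold
  and no monotonicity is asserted. Undefined ratios (no real test at t) are
  flagged NaN.
- q-values are monotone in p by construction (cumulative minimum on the
  sorted sequence).
- Constant predictors, constant score vectors, rank-deficient covariate
  designs, and all-zero samples produce explicit `untestable` flags or
  errors naming the offending term.
- All seeds are derived from a master seed via `SeedSequence.spawn` and kept
  below 2^31; fixing the seed fixes every output bit-exactly.

## Problem sizes

Calibration and recovery suites run at: 400–1000 genes × 32 samples with
5 permutation iterations for ASE (20 seeds), 250–500 genes for DE
calibration, 500 simulated tests for each uniformity check, intercrosses of
300 animals for null calibration and 1002 (the study cohort) for power, and
2000 genes for dispersion recovery. These sizes give stable Monte-Carlo
estimates at the stated tolerances; the permutation bookkeeping at the
fixed 500 × 759 schedule is computed exactly rather than by running half a
million regressions.

## Known limitations

- The NB dispersion is a single common value; strongly gene-specific
  dispersion would mis-calibrate individual genes (the pooled q-value and
  fold-change filter absorb much of this at the stated design sizes).
- The pooled MTE critical value assumes comparably scaled candidate genes.
- The covariate screen residualizes linearly; genuinely non-additive
  sex × diet × genotype structure would leak into the epistasis test.
- Pseudo-genome construction consumes only homozygous-alternative calls and
  normalized anchored indels; complex or heterozygous records are rejected
  rather than guessed at. Features straddling deletions are truncated to
  the surviving interval — the original handling was unstated, and this is
  the recorded choice.
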