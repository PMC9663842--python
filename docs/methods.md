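# Methods

This note records the statistical models implemented in `perifat`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer should know
about.

## Phenotype comparison

Each fat-percentage trait is compared between sexes with a pooled-variance
two-sided Student *t* test, preceded by an Anderson–Darling normality check
per sex and an F test of variance equality. The Anderson–Darling p-value
uses the estimated-parameters case with the small-sample correction
`A*² = A²(1 + 0.75/n + 2.25/n²)` and the standard piecewise formula
(D'Agostino & Stephens); on spot checks it reproduces R `nortest::ad.test`
to nine decimals. Significance is declared at p < 0.05.

## Differential expression

Counts are normalised with median-of-ratios size factors (rescaled to
geometric mean 1). Genes are pre-filtered on FPKM: a gene is kept when its
mean FPKM reaches 0.2 in males **or** females — the group mean, not every
sample, so single dropouts do not discard a gene.

Per-gene NB dispersion is estimated by method of moments on normalised
counts after removing the sex-group means, `α = max(10⁻⁴, (s² − m̄)/m̄²)`.
No empirical-Bayes shrinkage is applied; the estimator is transparent but
noisy at n = 6 + 6, which is why the Wald statistic

```
log2FC = log2((mean_F + ½) / (mean_M + ½)),    W = log2FC / SE
```

(delta-method SE from per-sample NB variances `μ/sf + αμ²`) is referred to
a Student *t* with n − 2 degrees of freedom rather than a normal: the
variance in the denominator is itself estimated from the same 12 samples,
and the t reference keeps the null rejection rate at p < 0.05 near 5%
where the normal reference is visibly anti-conservative (~8%). The
pseudocount of 0.5 normalised counts keeps fold-changes finite for
sex-exclusive transcripts. Positive log2FC means higher in females.

DEGs require FDR < 0.05 and |log2FC| > 2 (strict inequalities);
integration candidates require only |log2FC| > 1.

## Co-expression networks and DcoExp modules

Networks are built per sex on log-scale expression of the filtered genes:
signed adjacency `a_ij = ((1 + r_ij)/2)^β`, with β the smallest power in
1..20 whose binned scale-free fit reaches R² ≥ 0.8 with negative slope
**and** mean connectivity ≥ 1 (without the connectivity guard the fit
spuriously improves on unstructured data as the network empties; fallback
β = 12). Topological overlap follows the standard formula with unit
diagonal.

Modules come from average-linkage clustering of 1 − TOM. Because no single
static cut height worked across clean, noisy and mixed inputs, the cut is
chosen from a small candidate set — merge-height quantiles 0.3–0.7 plus
the midpoint of the largest upper-half jump in merge heights — scored by
the number of clusters that qualify as modules: ≥ 30 genes and mean
within-cluster Pearson correlation ≥ 0.5. The coherence bound is the
discriminating ingredient: chance clusters of unrelated genes reach mean
correlations near 0.3 at 12 samples while genuinely co-regulated blocks
sit near 0.7. Ties go to the cut assigning more genes, then to the lower
(purer) cut.

Assignments are refined for up to 20 iterations by reassigning each gene
to the module eigengene (first PC of the standardised member matrix, unit
variance, sign tied to mean expression) it correlates with best; ties keep
the current label, modules dropping below 30 genes dissolve to grey, and
grey genes only join a module when their best eigengene correlation
reaches 0.7 — detection stragglers are recovered without sweeping noise
into modules.

DcoExp calling: for every module pair across sexes, a one-sided Fisher
exact test of gene-set overlap against the shared background, BH-adjusted
within each direction; a module is *specific* (DcoExp) when no other-sex
module overlaps it at FDR < 0.05. Module–trait links are Pearson
correlations between eigengenes and fat-percentage traits computed
strictly within the module's own sex, significant at p < 0.05.

## Differential methylation

Contexts (CG, CHG, CHH) are processed independently throughout. Group
methylation means are smoothed by pooling reads over all same-context
sites within a 500 bp window (±250 bp) on the same chromosome. Site
dispersion φ is a beta-binomial method-of-moments estimate pooled over
sexes around each sex's smoothed mean, clamped to [10⁻³, 0.5]. The Wald
statistic contrasts the smoothed female and male means; each group
variance is the φ-inflated binomial variance of the *same* pooled
estimator (summing `n(1 + (n−1)φ)` over the window's site–sample pairs),
which keeps the test calibrated (null p < 0.05 rate ≈ 5–7%). DMLs are
sites at p < 0.001.

DMRs: candidate sites at p < 0.01 are clustered when consecutive
candidates lie ≤ 100 bp apart; proto-regions bounded by their first and
last candidate are kept when length ≥ 50 bp, the span holds ≥ 3 analysed
sites and ≥ 50% of them are significant; surviving regions merge when
fewer than 50 intervening bases separate them (gap = start₂ − end₁ − 1,
strict < 50). Group means per DMR are unweighted means of the span's raw
read-pooled per-site fractions. The 500 bp smoothing window and the 100 bp
clustering gap are configuration keys; the remaining thresholds are the
published rule set. Dispersions are not shrunk toward a genome-wide trend,
and opposite-strand CpGs are not collapsed.

Annotation assigns the overlapping gene (largest overlap, ties to the
lexicographically smaller id) and labels the DMR with the '/'-joined
feature classes it touches, in precedence order Promoter (TSS ± 1000 bp,
strand-aware) > Exon > Intron; DMRs outside every gene are Intergenic and
take the nearest gene by edge distance. Whether a published "number of
methylated cytosines" counts all analysed sites in the span or only the
significant ones is ambiguous; this implementation reports all analysed
sites and carries the significant count separately.

Global context summaries report per-sex mean and SD of read-pooled site
fractions and Cohen's D with the pooled-SD denominator
`√((sd_F² + sd_M²)/2)`.

## Multiblock sparse PLS-DA

The outcome is a centred two-column class indicator. For each component,
every block's loading starts at the leading right singular vector of
`XᵀY` and is updated iteratively from the design-weighted sum of the other
blocks' scores plus the outcome score, soft-thresholded to the keepX
largest entries (exact zeros elsewhere), normalised, until the maximum
score change falls below 10⁻⁶ (cap 100 iterations, non-convergence warns).
Blocks deflate on their own scores; the default design is fully connected
with weight 1. `ncomp` is capped at the data rank with a warning. Missing
methylation features are mean-imputed before z-scoring, and zero-variance
features are dropped and logged.

With keepX = all features, the single-block case reduces to dense PLS-DA:
the component-1 loading equals the leading eigenvector of `XᵀYYᵀX` (tested
against an explicit eigendecomposition).

Evaluation: per block and component, AUC = U/(n₁n₂) folded above 0.5, with
two-sided significance from the normal approximation
`z = (U − n₁n₂/2)/√(n₁n₂(n+1)/12)` with midrank tie correction — the only
form that reproduces p = 0.0039 for a perfect untied 6 vs 6 separation.
The combined two-component AUC projects the score pair onto the
class-mean-difference direction. Cross-block correlations are Pearson
correlations of the blocks' per-component scores.

DMR–gene pairing keeps (gene, DMR) pairs where the DMR's assigned gene is
among the selected genes; a `strict_within` mode restricts to DMRs
physically overlapping the gene. The overlap refit re-estimates the model
on paired features only.

## Enrichment

All over-representation tests are hypergeometric upper tails with BH
adjustment (enriched at FDR < 0.05). QTL enrichment uses the category
counts among overlapped QTLs against the whole database (per-trait and
per-type; the background can optionally be restricted per type). Term
grouping computes Jaccard coefficients between term gene sets —
disregarding enrichment status — and cuts an average-linkage tree at a
user-chosen cluster count, as the published tree gives no cut rule.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical* structure the analysis assumes
for 6 + 6 lambs at desk scale: NB counts (gamma–Poisson, gene dispersions
0.05–0.3, size factors log-uniform 0.7–1.4) with the sex effect split
±log2FC/2 so library depth stays sex-balanced; module genes follow latent
factors on the log2 scale with configurable within-sex correlation, active
in one sex or both; methylation is beta-binomial
(`Beta(μ(1−φ)/φ, (1−μ)(1−φ)/φ)`, φ = 0 → binomial) around context
baselines calibrated to the published global means/SDs (CG 0.6 ± 0.25,
CHG 0.2 ± 0.17, CHH 0.15 ± 0.12) at Poisson coverage (default 20×, 5% of
site–sample pairs may be uncovered); planted DMRs are non-overlapping runs
of sites 10–40 bp apart whose sex means differ by the drawn delta, half
of them placed inside planted genes by default; traits are linear in the
linked module's latent factor plus Gaussian noise. Default problem sizes —
2 000 genes, 4 000/1 200/1 200 sites, a 3 × 10 Mb genome, 30 DMRs — keep
every stage at seconds scale while leaving room for interval logic.

Not emulated: read-level artefacts (mapping, bisulfite conversion error),
the half-sib family structure of the real lambs, chromosome-specific
effects (no X dosage model), and the genome-scale site density of real
WGBS. Passing tests therefore demonstrate that the *procedures* recover
planted effects under the assumed models, not that the models capture
every property of the real data.

Benchmark problem sizes: the DcoExp planted-module property is evaluated
at 12 samples per sex because correlation-network module detection at 6
per sex is intrinsically unstable — a shared module detected in only one
sex is indistinguishable from a sex-specific one, which is plausibly part
of why the real study reports dozens of "specific" modules. The DE, DML,
DMR and integration benchmarks run at the study's own 6 + 6.

## Known limitations

- The NB dispersion and beta-binomial φ estimators are unshrunk; power at
  n = 6 + 6 is below what an empirical-Bayes pipeline would achieve.
- The module-coherence bound (mean correlation ≥ 0.5) can drop genuinely
  co-regulated but weakly correlated modules in real data; it is a
  configuration key.
- The AUC here is in-sample (as in the published analysis), not
  cross-validated; with 12 samples and hundreds of features, AUC = 1 is
  expected whenever strong effects exist and should not be read as an
  estimate of out-of-sample accuracy.
- Fisher DcoExp "specificity" is absence of evidence of overlap; modules
  missed by detection in one sex inflate it.
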