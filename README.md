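# perifat

Integrated methylome + transcriptome analysis of sex differences in ovine
perirenal fat, built as a reproducible, fully tested pipeline exercised on
synthetic data with planted effects.

## The scientific problem

Male and female suckling lambs deposit fat differently, which matters for
carcass and meat quality. A 6-male / 6-female design profiling the same
perirenal fat with RNA-seq and whole-genome bisulfite sequencing (WGBS) can
ask which genes, methylation marks and co-expression programmes distinguish
the sexes, and whether those candidates sit inside quantitative trait loci
(QTL) already linked to fatness traits. `perifat` implements that analysis
chain end to end:

1. **Phenotype statistics** — Anderson–Darling normality per sex, F test
   of variance equality and a pooled-variance Student *t* on fat-percentage
   traits.
2. **Differential expression** — FPKM filtering (drop genes below 0.2 in
   both sexes), median-of-ratios size factors, a negative-binomial Wald
   contrast of females vs males (positive log2FC = higher in females),
   Benjamini–Hochberg FDR, DEGs at FDR < 0.05 and |log2FC| > 2, and a
   wider candidate set at |log2FC| > 1.
3. **Co-expression** — per-sex signed WGCNA-style networks
   (adjacency `((1 + r)/2)^β`, topological overlap, average-linkage
   clustering with a k-means-style eigengene refinement); cross-sex module
   overlap by one-sided Fisher exact tests; modules with no significant
   counterpart in the other sex (FDR ≥ 0.05 for every pair) are
   *differentially co-expressed* (DcoExp) modules.
4. **Differential methylation** — window-smoothed beta-binomial group
   means per CG/CHG/CHH context, method-of-moments site dispersion, a Wald
   test per cytosine (DML at p < 0.001), and rule-based DMR calling:
   cluster sub-0.01 sites, require length ≥ 50 bp, ≥ 3 sites, ≥ 50%
   significant, merge regions closer than 50 bp; DMRs are annotated as
   Promoter/Exon/Intron/Intergenic against gene models with nearest-gene
   assignment.
5. **Multi-omics integration** — multiblock sparse PLS-DA (the DIABLO
   construction) linking an mRNA block (FPKM of |log2FC| > 1 candidates)
   and a methylation block (per-DMR mean methylation) to sex, two latent
   components; variable selection, DMR-to-gene pairing, an
   overlap-restricted refit and AUC evaluation with Mann–Whitney
   significance.
6. **Enrichment** — QTL interval overlap and hypergeometric trait/type
   enrichment, generic term (GO-style) enrichment and Jaccard-similarity
   term grouping.

A synthetic-data generator (`perifat.simulate`) emulates the
post-quantification products of the real design — negative-binomial counts
with planted sex log2 fold-changes, beta-binomial methylation calls with
context-specific baselines (CG ≈ 0.6, CHG ≈ 0.2, CHH ≈ 0.15) and planted
DMRs placed inside planted genes, sex-specific co-expressed blocks, and
traits correlated with module activity — together with a ground-truth
table, so every stage is testable without any download.

## Worked example

```python
import numpy as np, pandas as pd
from perifat import (SimulationConfig, simulate_experiment,
                     SexDifferentialExpression, fpkm)
from perifat.expression import filter_low_expression
from perifat.io import ExpressionCountMatrix
from perifat import methylation as me, integration as integ

cfg = SimulationConfig(n_genes=400, n_sites={"CG": 2000, "CHG": 400, "CHH": 400},
                       de_fraction=0.08, de_log2fc_range=(3.0, 3.0),
                       dmr_count=25, dmr_delta_range=(0.4, 0.4),
                       dmr_in_gene_fraction=0.8, module_spec=[], trait_spec={},
                       seed=1)
counts, calls, genes, qtls, meta, truth = simulate_experiment(cfg)

f = fpkm(counts)
kept = filter_low_expression(f, meta.sexes)
sub = ExpressionCountMatrix(counts.counts.loc[kept], counts.gene_length_bp.loc[kept])
res = SexDifferentialExpression(sub, meta.sexes).fit()
print(res.summary(3).round(3))
#         gene_id  log2fc  lfcse  wald_stat  p_value  fdr
# G00245   G00245  -2.972  0.096    -30.819      0.0  0.0
# G00255   G00255  -3.073  0.264    -11.628      0.0  0.0
# G00353   G00353  -2.988  0.298    -10.025      0.0  0.0
```

The planted |log2FC| = 3 genes come back with estimates near ±3 and tiny
FDR; 32 genes pass the DEG rule and 34 the |log2FC| > 1 candidate rule.
Continuing into methylation and integration:

```python
dml = me.DifferentialMethylation(calls, meta.sexes).fit()
dmrs = [me.annotate_genomic_context(d, genes) for d in dml.call_dmrs()]
dmr_ids = [f"{d.interval.chrom}:{d.interval.start}-{d.interval.end}:{d.context}"
           for d in dmrs]
feat = pd.DataFrame({s: np.nan for s in meta.samples}, index=dmr_ids)
for did, d in zip(dmr_ids, dmrs):
    feat.loc[did] = me.dmr_mean_methylation(calls, d)

blocks = integ.build_blocks(f, res.call_candidates(), feat, meta.sexes)
fit = integ.BlockSPLSDA(blocks, ncomp=2).fit()
sel = fit.select_variables()
pg, pdm = integ.pair_dmrs_to_genes(sel["mrna"], sel["meth"],
                                   dict(zip(dmr_ids, dmrs)))
refit, ev = integ.overlap_refit(blocks, pg, pdm)
print(refit.summary().round(4))
# block  component  n_selected     auc  mann_whitney_p
#  mrna          1          15  1.0000          0.0039
#  mrna          2          15  0.5000          1.0000
#  meth          1          18  1.0000          0.0039
#  meth          2          18  0.5556          0.7488
```

All 25 planted DMRs are recovered; 15 candidate genes pair with 18 selected
DMRs, and the refit model separates males from females perfectly on both
omic blocks (AUC = 1, Mann–Whitney p = 0.0039 for 6 vs 6), with a
cross-block component-1 score correlation of 0.99.

## Command line

```bash
perifat simulate --out data/ --seed 7          # write a synthetic dataset
perifat de --counts data/counts.tsv --meta data/metadata.tsv --out de.tsv
perifat dml --calls data/methylation_calls.tsv --meta data/metadata.tsv --out dml.tsv
perifat dmr --dml dml.tsv --gff data/genes.gff3 --out dmr.tsv
perifat run --config config.yaml               # full pipeline
```

A pipeline config is YAML with an `outdir`, a `seed`, either an `inputs:`
block (counts / calls / gff / qtl / metadata paths) or a `simulate:` block
(any `SimulationConfig` field), and an optional `params:` block overriding
stage parameters (thresholds, windows, `ncomp`, ...).

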