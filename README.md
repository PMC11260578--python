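# accessout

Detection and annotation of chromatin accessibility outliers — regions whose
read counts in one or a few samples diverge sharply from the population
baseline after confounder correction.

The toolbox covers the full workflow:

- **Counting** (`accessout.regions`): merge nearby peaks (default gap
  200 bp), count aligned reads per region with a linear-time sorted sweep
  over coordinate-sorted BAMs, and apply replication filters (>= 100 reads in
  at least one sample, >= 2 reads in >= 50% of samples).
- **Normalization** (`accessout.normalization`): DESeq2-style
  median-of-ratios size factors, centered log transform, and the exact
  inverse back to the count scale.
- **Outlier detection** (`accessout.outlier`): a PCA-initialized linear
  autoencoder whose latent space is concatenated with known confounders; the
  decoder is initialized by least squares and refined once under a
  negative-binomial likelihood, with per-region bounded dispersion MLE
  (r in [0.01, 1000]); a two-sided NB test, Benjamini–Yekutieli FDR
  (per sample), log2 fold changes, Z-scores, and outlier calls
  (padj < 0.05, |l2fc| > 0.5, count or expected count >= 50).
- **Injection benchmark** (`accessout.injection`): artificial outliers
  planted on the log scale (per-direction probability 0.0005, amplitude
  sigma_j * exp(N(3,1))), naive-NB and PCA baselines, and auPRC evaluation
  over repeated masks.
- **Annotation** (`accessout.annotation`): promoter / active enhancer /
  poised enhancer / unannotated classes from H3K4me3, H3K27ac and H3K4me1
  marks plus a GENCODE GTF; proximal/distal calls; outlier-pair proximity
  enrichment (Fisher's exact); Hi-C contact scores over 5-kb bins (3x3
  neighborhood max); distance-controlled power regression; and
  activity-by-contact (ABC) scores.
- **Expression linkage** (`accessout.expression`): per-(gene, sample)
  feature tables (promoter stats, proximal / 100-kb-window max |l2fc|,
  ABC-weighted distal score) and a ranking evaluator for predicting gene
  expression outliers.
- **Synthetic fixtures** (`accessout.simulate`): NB count matrices with
  latent structure, planted outliers and truth bundles; tiny indexed BAM +
  BED alignment fixtures; a toy GTF / marks / power-law Hi-C bundle.
  Everything needed to run and test the package offline.

## Command line

```sh
# count reads per merged peak for several samples
accessout count --bam s1.bam --bam s2.bam --peaks peaks.bed --out counts.h5ad

# replication filter
accessout filter --counts counts.h5ad --high-count 100 --min-reads 2 \
    --min-fraction 0.5 --out filtered.h5ad

# outlier detection (bottleneck: integer, comma list to tune over, or 'auto')
accessout detect --counts filtered.h5ad --confounders meta.tsv \
    --bottleneck auto --alpha 0.05 --min-l2fc 0.5 --min-count 50 \
    --seed 0 --out result.h5ad --out-tsv outliers.tsv

# injection benchmark
accessout benchmark --counts filtered.h5ad --methods epiout,pca,naive \
    --q 5 --n-masks 10 --seed 0 --out bench.tsv

# functional annotation (+ optional Hi-C ABC scores and pair enrichment)
accessout annotate --peaks peaks.bed --h3k4me3 a.bed --h3k27ac b.bed \
    --h3k4me1 c.bed --gtf genes.gtf --hic contacts.tsv \
    --result result.h5ad --out annot/

# gene-level feature table for expression-outlier prediction
accessout link-expression --access result.h5ad --expr expr_result.h5ad \
    --annot annot/ --gtf genes.gtf --abc annot/abc.tsv --out features.tsv

# synthetic fixtures
accessout simulate --preset counts --seed 0 --out fixtures/
```

Counts are accepted as HDF5 AnnData (`.h5ad`) or TSV (regions as rows named
`chrom:start-end`, samples as columns). Detection results are AnnData with
layers `expected`, `pvalue`, `padj`, `l2fc`, `zscore`, `is_outlier` and
`corrected`, size factors in `obs` and dispersions in `var`. Hi-C contacts
are consumed as a 7-column BEDPE-like TSV
(`chrom1 start1 end1 chrom2 start2 end2 score`).

## Notes

- Coordinates are BED convention (0-based, half-open) internally; GTF input
  is converted on read.
- `run_epiout(..., robust_input=True)` (default) fits the model on
  leverage-clipped data so a single extreme entry cannot hijack a region's
  expectation; the NB test itself always uses raw counts. Set
  `robust_input=False` for the unguarded pipeline.
- Peak calling (e.g. MACS2) is out of scope; the package consumes its BED
  output.
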