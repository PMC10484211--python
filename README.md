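# raescan

Detection of **random allelic expression (RAE)** from haplotype-phased,
multi-tissue allele-count matrices.

For each individual, every gene's haplotype-A counts `X` and totals `N`
across tissues are tested for overdispersion: the null model is a binomial
with a single pooled probability `p = sum(X)/sum(N)` (biallelic or
consistently skewed expression — cis-eQTL-like skew and imprinting both fit
it), the alternative is a beta-binomial with mean `mu` and intra-class
correlation `rho` (random, tissue-to-tissue allelic variability). The
likelihood-ratio statistic is referred to a chi-squared distribution with one
degree of freedom, with Benjamini-Hochberg correction per individual
(default FDR 10%).

Across a cohort, per-gene significance frequencies are standardised into Z
scores and calibrated against X-inactivated (XCI) positive-control genes in
females: the Z cutoff is taken where the XCI sensitivity curve and the
autosomal specificity curve converge. Genes with `Z >= z_rae` are classed
RAE, `Z <= 0` biallelic, the remainder not categorized; classifications
replicated independently in the male and female cohorts yield the
high-confidence (hc) catalogs. An empirical false discovery rate is
estimated by resampling every observed total under a binomial null
(`X ~ Binomial(N, 0.5)`) and rerunning the full test. Genomic-context
statistics (TAD enrichment with odds ratios and Pearson residuals,
sense/antisense overlap tests, density splits, regulatory-complexity
scores, chromosome-arm positioning) operate on the classified gene sets.

A synthetic-cohort generator produces ground-truth-labelled data in the same
phASER-style dialect (`HAP_A_COUNT|HAP_B_COUNT` cells), covering balanced
biallelic, cis-skewed, imprinted-like, RAE and XCI-like genes, so the entire
pipeline is testable without protected data.

## CLI

```sh
# generate a labelled synthetic cohort
rae-scan simulate --individuals 40 --genes 500 --xci-genes 30 --seed 7 --out cohort/

# per-individual overdispersion test
rae-scan test --matrix cohort/matrices/F0000.tsv --sex female \
    --min-depth 10 --min-tissues 3 --fdr 0.10 --out calls/

# cohort aggregation, XCI-calibrated threshold, hc catalogs
rae-scan population --calls calls/ --sex-map cohort/sex_map.tsv \
    --xci xci_genes.txt --min-individuals 10 --out population/

# empirical FDR by biallelic null simulation
rae-scan fdr --matrix-dir cohort/matrices --reps 3 --seed 7 --out fdr/

# TAD enrichment of classified genes
rae-scan enrich --genes genes.bed --labels population/population_female.tsv \
    --tads tads.bed --fdr 0.10 --min-or 1.5 --out enrich/

# end-to-end: test + population
rae-scan run --matrix-dir cohort/matrices --sex-map cohort/sex_map.tsv \
    --xci xci_genes.txt --out run/
```

Every command writes its resolved configuration as `config.json` next to its
outputs; re-running from the same inputs and seeds reproduces outputs
byte-identically.

Input formats: phASER-style gene x tissue TSV matrices (`a|b` cells, empty
or `NA` for missing), BED6 / GTF gene intervals (internally 0-based
half-open), plain-text gene-ID lists, and two-column chromosome-size TSVs.

## Layout

- `raescan.ase_io` — matrix/interval/gene-set I/O, validation, depth and
  tissue filters.
- `raescan.overdispersion` — binomial and beta-binomial likelihoods,
  beta-binomial MLE, LRT, BH correction, per-individual calls.
- `raescan.population` — cohort aggregation, Z scores, threshold
  derivation, classification, sex replication, factor regression QC.
- `raescan.simulate` — synthetic cohorts with ground truth and the
  biallelic-null FDR estimator.
- `raescan.genome_context` — domain/overlap/density/complexity/position
  statistics.
- `raescan.cli` — the `rae-scan` command group.
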