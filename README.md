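# riceeco

Population-genomic analysis of rice ecotype domestication at desk scale:
sliding-window diversity and differentiation scans, reduction-of-diversity
(ROD) and F_ST outlier sweep calling, standing/new/lost variant
classification with allele-frequency differentiation, a mixed-model GWAS on
a binary ecotype phenotype with an LD-pruning-derived significance
threshold, and RPKM-ratio + haplotype candidate-gene screening. A bundled
forward Wright–Fisher simulator (selfing, bottlenecks, planted sweeps,
post-split mutations, four-condition expression tables) generates fixtures
with ground truth for recovery testing, so the whole pipeline runs without
any external data download.

## Modules

| module | contents |
|---|---|
| `riceeco.synthetic_data` | forward simulator (`SimConfig`, `simulate_dataset`), missingness injection, expression simulation, fixture writing |
| `riceeco.genotype_io` | `GenotypeMatrix`, VCF/TSV/BED readers and writers, missing-rate/MAF variant filters, ancestry-Q sample filter, panel summaries |
| `riceeco.popgen_windows` | window grids, windowed nucleotide diversity (π), Weir–Cockerham (1984) windowed F_ST (ratio-of-sums; Hudson variant behind a flag) |
| `riceeco.sweep_detection` | ROD scan, top-quantile outlier region calling with bookend merging, composite multi-signature sweep score, gene annotation, genome-fraction reporting |
| `riceeco.variation_typing` | standing/new/lost classification vs the progenitor, AFD summaries, alternative-allele frequency conventions, windowed-π rank test |
| `riceeco.ecotype_gwas` | 0/1 phenotype encoding, PLINK-style LD pruning, GRM, PCA covariates, EMMAX-style REML mixed-model scan, `-log10(alpha/n_eff)` threshold, QTL clustering |
| `riceeco.candidate_screen` | two-ratio RPKM up/down classification, region × expression candidate screen, pseudo-haplotype tables and chi-square/permutation differentiation |
| `riceeco.pipeline` | config-driven orchestration of all stages with a deterministic manifest |

## CLI

All stages are exposed under one entry point:

```sh
riceeco simulate --config sim.yaml --out fixtures/ --seed 1
riceeco filter --vcf in.vcf --max-missing 0.5 --min-maf 0.05 --out out.vcf
riceeco windows --vcf out.vcf --samples samples.tsv --stat pi --pop DW \
    --window 100000 --step 50000 --out pi_DW.tsv
riceeco windows --vcf out.vcf --samples samples.tsv --stat fst \
    --pop DW --pop2 IR-XI --out fst.tsv
riceeco sweep --scan rod --windows pi_Or.tsv --windows2 pi_DW.tsv \
    --quantile 0.99 --genes genes.bed --out sweeps.tsv
riceeco classify-variants --vcf out.vcf --samples samples.tsv \
    --eco DW --prog IR-XI --out classes.tsv
riceeco gwas --vcf in.vcf --samples samples.tsv --target DW --pcs 3 \
    --prune 50,5,0.3 --out assoc.tsv --qtl-out qtls.tsv
riceeco candidates --qtl qtls.tsv --genes genes.bed --expr rpkm.tsv \
    --out candidates.tsv
riceeco run --config pipeline.yaml        # full DAG, deterministic manifest
```

Exit codes: 0 ok, 1 user error, 2 internal error.

A minimal pipeline config:

```yaml
out_dir: runs/demo
seed: 1
simulate:
  n_chromosomes: 2
  chrom_length_bp: 2000000
  sweep_loci: [[chr1, 1000000, 200000, ecotype]]
windows: {size: 100000, step: 50000}
gwas: {target: DW, prune: [50, 5, 0.3], n_pcs: 3}
```

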