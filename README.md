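# rumenet

Analysis toolkit for rumen (gut) microbiome enterotypes in livestock cohorts,
covering the full path from a genus-level abundance table to host genetics:

- **community** — rarefaction, alpha diversity (Shannon, Simpson, InvSimpson,
  Pielou, Chao1, ACE, Fisher's alpha), Bray–Curtis distances, PCoA,
  marginal one-factor PERMANOVA.
- **enterotype** — sqrt Jensen–Shannon distances, PAM (k-medoids) clustering,
  Calinski–Harabasz model selection over k, random-forest driver-genus
  ranking under repeated cross-validation.
- **phenotype** — derived performance traits (ADG, ADFI, FCR, MBW, BMI, RFI,
  dressing percentage, relative fat weights), per-trait enterotype
  association with birthplace adjustment and BH-FDR, covariate chi-square /
  logistic / collinearity diagnostics.
- **twopart** — genus screening with Beta regression (prevalence ≥ 60%) and
  zero-inflated Beta regression (below 60%), logit mean link, precision
  parameter, BH-FDR over enterotype tests.
- **network** — enterotype-stratified Spearman partial-correlation
  co-occurrence networks, FDR edge filtering, topology metrics, and the
  specialist/generalist + direction/strength/stable edge taxonomy.
- **genetics** — SNP QC, PLINK-style LD pruning, GRM from standardized
  dosages, observed-scale REML heritability with the liability-scale
  threshold-model transform, Haseman–Elston genetic correlations, binary
  GWAS score tests with genomic inflation λ and Bonferroni/suggestive
  thresholds, clr transform, SNP→genus effect models.
- **coloc** — hypergeometric signal overlap, cross-signal LD, and Bayesian
  colocalization via Wakefield approximate Bayes factors (PP.H0–PP.H4).
- **synthetic** — a seeded generator for every input the pipeline consumes:
  Dirichlet-multinomial genus tables with planted enterotypes and driver
  genera, HWE genotypes with block LD, liability-threshold binary
  phenotypes at a chosen heritability, and confounded performance traits.

## CLI

All functionality is exposed through the `rumenet` entry point:

```bash
rumenet simulate --out-dir data/ --n-samples 200 --seed 1
rumenet community alpha --input data/abundance.tsv --out alpha.tsv --seed 1
rumenet enterotype fit --input data/abundance.tsv --out-prefix ent --seed 1
rumenet enterotype drivers --input data/abundance.tsv \
    --assignments ent.assignments.tsv --out drivers.tsv
rumenet twopart --input data/abundance.tsv --assignments ent.assignments.tsv \
    --metadata data/phenotypes.tsv --out twopart.tsv
rumenet network build --input data/abundance.tsv --out edges.tsv
rumenet genetics qc --vcf data/genotypes.vcf --out qc.vcf
rumenet genetics h2 --vcf qc.vcf --phenotypes data/phenotypes.tsv
rumenet genetics gwas --vcf qc.vcf --phenotypes data/phenotypes.tsv --out gwas.tsv
rumenet coloc --trait-a statsA.tsv --trait-b statsB.tsv --out coloc.json
```

Run `rumenet <group> --help` for the full option list of any subcommand.

## Notes

- All randomness is driven by explicit seeds; fixture files written by
  `rumenet simulate` are byte-identical across runs with the same seed.
- Genotype I/O is plain-text VCF v4.2 (GT field) via cyvcf2; tables are TSV.
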