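# crosstrait

Cross-trait genetic-correlation analysis from GWAS summary statistics, as a
tested, reusable Python package. It covers the full desk-scale workflow for
asking whether two case-control traits share genetic architecture:

- **`sumstats_io`** — read/validate/harmonize summary-statistics tables
  (INFO/MAF/reference filters, strand-ambiguity and allele-flip resolution,
  HLA exclusion), genotype QC (call rate, MAF, exact Hardy–Weinberg test),
  and genomic inflation (λ, λ₁₀₀₀).
- **`ldsc`** — LD scores from a reference panel; univariate, cross-trait and
  stratified (partitioned-heritability) LD-score regression with
  delete-one-block jackknife standard errors.
- **`meta`** — fixed-effects inverse-variance meta-analysis with Cochran's Q
  and I².
- **`pleiotropy`** — correlated-variant sets (r² / EM-based D′) around
  sentinel SNPs and the region-wide Bonferroni cross-trait scan, including
  the packaged published risk-locus table as a worked example.
- **`enrichment`** — variant-set enrichment against peak intervals via
  MAF/set-size–matched permutation nulls, plus a cell-type-specificity
  score.
- **`smr`** — summary-data Mendelian randomization with the HEIDI
  heterogeneity test separating pleiotropy from linkage.
- **`synthetic_data`** — generators for every input (block-LD panels,
  bivariate GWAS with known h²/Rg/sample overlap, cis-eQTL loci, peak
  fixtures), so the whole pipeline is testable without any downloads.
- **`cli`** — a `crosstrait` command orchestrating the stages from one YAML
  config.

## Command line

Each stage is a subcommand sharing `--config`, `--seed`, `--outdir` and
`--log-level`; upstream stages are enabled automatically:

```bash
crosstrait scan --outdir out             # pleiotropy scan of the packaged locus table
crosstrait rg --seed 3 --outdir out      # simulate -> munge -> ldsc -> cross-trait fit
crosstrait all --config my.yaml --outdir out
```

Every run writes its resolved config and a `report.json` next to the
outputs; identical config and seed reproduce the report byte for byte.

## Notes

- Summary statistics are tab-separated with header
  `SNP CHR BP A1 A2 BETA SE Z P N_CAS N_CON MAF INFO`; foreign headers are
  mapped with a dialect dictionary.
- BED intervals are 0-based half-open; SNP positions are 1-based. The
  conversion happens once, at the overlap query, and is covered by
  dedicated boundary tests.
- Heritability estimates are reported on the observed scale; no
  liability-scale conversion is performed.
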