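# dtmr — drug-target Mendelian randomization

A pipeline for drug-target Mendelian randomization from GWAS summary
statistics: cis-instrument selection near a target gene, allele
harmonization, two-sample MR estimation (Wald ratio, fixed-effects IVW,
weighted median, Egger regression, Cochran's Q), Bayesian colocalization
over the five standard hypotheses, and absolute-risk extrapolation — plus a
synthetic-data module that generates every input with known ground truth.

## Layout

| module | purpose |
|---|---|
| `dtmr.gwas_io` | TSV summary-statistics I/O with column mapping and row validation |
| `dtmr.instruments` | gene-window extraction, tri-biomarker concordance filter, greedy LD clumping |
| `dtmr.harmonize` | effect-allele alignment, palindromic-SNP exclusion, inhibition orientation |
| `dtmr.mr` | Wald / IVW / weighted-median / Egger estimators and heterogeneity testing |
| `dtmr.coloc` | per-SNP approximate Bayes factors and H0–H4 posterior enumeration |
| `dtmr.simulate` | seeded synthetic GWAS panels, LD matrices, coloc scenarios, study fixture |
| `dtmr.pipeline` | YAML-driven orchestration of the full study |
| `dtmr.cli` | `dtmr` command-line entry point |

## CLI

Generate a complete synthetic study (summary-stat TSVs, LD matrix, config):

```sh
dtmr simulate --out demo --seed 1            # selection-cascade study fixture
dtmr simulate --out demo --kind panel --n-snps 20 --theta-true 0.02
```

Run the full analysis from a config file:

```sh
dtmr run --config demo/study.yaml --out demo/results
```

Outputs under the result directory: `report.json` (full structured report),
`estimates.tsv`, `selection_report.tsv`, `exclusions.tsv`, `coloc.json`.
Re-running with the same config and seed reproduces `report.json`
byte-for-byte.

Colocalize two regional tables directly:

```sh
dtmr coloc --trait1 a.tsv --trait2 b.tsv --out coloc.json
```

## Input format

Tab-separated UTF-8 with one header row; canonical columns
`rsid chrom pos ea nea eaf beta se pval n` (missing values `NA` or empty).
Arbitrary source headers can be mapped via the `columns` entry of each table
in the study YAML. LD matrices are square TSVs with an `rsid` index column.

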