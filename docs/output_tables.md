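# Output tables

All tables are tab-separated text written by the pipeline (`trioscan run`) or
by the corresponding library functions.

## `scan_results.tsv` — one row per SNP

| column | meaning |
| --- | --- |
| `snp_id` | marker name |
| `chrom`, `pos_bp` | chromosome label and 1-based position |
| `allele_a`, `allele_b` | A1/A2 as read from the input; distortion signs are relative to `allele_a` |
| `n_informative_offspring` | offspring contributing transmission information (inclusive counter) |
| `n_informative_sires`, `n_informative_dams` | distinct heterozygous parents with ≥1 Mendelian-consistent offspring |
| `n_mendel_errors` | trios excluded at this SNP as Mendelian-inconsistent |
| `skip_reason` | empty when analysed; otherwise why the SNP was not fitted |
| `log10_bf_<model>` | log10 Bayes factor vs the Mendelian null, per model (`allelic_overall`, `allelic_parent_specific`, `genotypic`) |
| `dic_<model>` | deviance information criterion per model |
| `pattern` | winning label: overall / stallion / mare / additive / heterosis / additive+heterosis / genotypic |
| `pattern_tie` | true when the DIC gap to the runner-up is within the margin (simplest model taken) |
| `trd_magnitude` | absolute posterior mean of the winning label's parameter |
| `log10_bf` | log10 Bayes factor of the winning model |
| `decisive` | `log10_bf` > 2 (BF > 100, Jeffreys decisive) |
| `above_null_threshold` | magnitude exceeds the gene-drop empirical-null threshold |
| `passes_region_criteria` | all four cascade gates passed |

## `regions.tsv` — one row per called region

| column | meaning |
| --- | --- |
| `chrom`, `start_bp`, `end_bp` | bounds = min/max member SNP positions |
| `n_snps` | member count (≥ the configured minimum, default 2) |
| `pattern` | shared pattern label of the members |
| `magnitude_min`, `magnitude_max` | range of member |TRD| magnitudes |
| `snp_ids` | comma-separated member SNP ids |

## `cascade_report.tsv`

Per-gate counts over analysed SNPs: `analyzed`, `decisive_bf`,
`above_null_threshold`, `informative_offspring`, `trd_magnitude`, `pass_all`.

## `qc_report.tsv`

Counts of input variants, variants failing each QC criterion
(`non_autosomal`, `low_call_rate` — a variant failing both is counted under
each), and variants passing.

## `annotation_snps.tsv` / `annotation_regions.tsv`

Per cascade-passing SNP (or region): the genes intersecting the ±window, with
coordinates and `overlap_class` (`overlapping` = gene contains the SNP
position, `proximal` = elsewhere in the window).

## `manhattan.tsv`

`chrom`, `pos_bp`, `log10_bf`, `pattern` for analysed SNPs — a minimal export
for external plotting.

## `manifest.json`

Package version, seed, the full configuration echo, and per-stage record
counts; `trioscan.pipeline.run_from_manifest` re-runs a pipeline from it.
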