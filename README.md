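# mpratag

Analysis pipeline for tag-based (barcoded) reporter assays that compare the
transcriptional activity of allele pairs — e.g. ancestral vs derived variants
of transcription-factor binding sites cloned upstream of a minimal promoter.

The pipeline goes from raw construct-sequencing reads and per-sample tag
counts to per-variant activity statistics:

1. **variant library** (`mpratag.library`) — allele-pair table (TSV) and the
   reporter construct set (two constructs per variant plus positive/negative
   controls).
2. **tag processing** (`mpratag.tags`) — extract 20-nt tags between fixed
   anchor sequences, associate tags with constructs by exact insert match in
   plasmid-sequencing reads, count whitelist tags per
   (cell line, replicate, assay) sample, and pool counts per construct.
3. **activity statistics** (`mpratag.stats`) — per replicate,
   `ln(((d_RT+ − d_RT−)/(a_RT+ − a_RT−)) / (d_DNA/a_DNA))`: RT− background
   subtraction, derived/ancestral RNA ratio, plasmid-DNA molar-ratio
   correction. Robust (median ± 3·MAD) replicate QC, one-sample t-tests
   against 0, Benjamini–Hochberg correction within each cell line, signed
   fold changes (no values between +1 and −1), cross-cell-line Pearson
   correlations, and per-variant enhancer/repressor classification.
   Vs-negative-control comparisons use the same statistic with the
   insert-less backbone in the denominator.
4. **synthetic data** (`mpratag.simulate`) — generator with known ground
   truth: lognormal molar-ratio imbalance, DNA carryover into the RNA
   channels, gamma overdispersion, injectable outlier replicates, and raw
   read synthesis; seeded and byte-reproducible.
5. **pipeline/CLI** (`mpratag.pipeline`, `mpratag.cli`) — YAML-config driven
   orchestration with a run log and deterministic TSV outputs.

## CLI

```sh
# synthetic dataset + full end-to-end run
cat > config.yaml <<EOF
seed: 11
paths:
  output_dir: out
analysis:
  alpha: 0.05
simulation:
  n_variants: 25
  n_cell_lines: 3
  n_replicates: 10
  depth_rtplus: 100000
  depth_dna: 100000
  activity_ratios: 1.0
EOF
mpratag all --config config.yaml

# individual stages
mpratag simulate  --config config.yaml
mpratag associate --reads out/association_reads.fasta --variants out/variants.tsv --out assignments.tsv
mpratag count     --reads sample.fastq --assignments assignments.tsv \
                  --cell-line SH-SY5Y --replicate 1 --assay RTplus --out counts.tsv
mpratag analyze   --counts out/sample_counts.tsv --variants out/variants.tsv \
                  --assignments out/tag_assignments.tsv --out results \
                  --alpha 0.05 --exclusions exclusions.tsv
```

`analyze` accepts tag-level count tables (`cell_line, replicate, assay, tag,
count`; requires `--assignments`) or construct-level tables
(`cell_line, replicate, assay, construct_id, count`). The exclusions TSV
(`cell_line, replicate[, construct_id]`) drops replicates unconditionally,
mirroring manually indicated exclusions.

Outputs: `results_derived_vs_ancestral.tsv` and `results_vs_negcontrol.tsv`
(n_valid, mean log ratio, t, df, p, BH q, significance, signed fold change),
`replicate_log_ratios.tsv`, `qc_flags.tsv`, `correlations.tsv`,
`classification.tsv`, a run log, and a verbatim config echo.

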