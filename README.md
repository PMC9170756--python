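# silacpipe

Analysis pipeline for triple-SILAC quantitative-proteomics experiments with a
forward/reverse labeling design. Given per-replicate heavy/medium and
light/medium channel ratios (the medium channel always carries the vehicle
control), the pipeline:

1. **Harmonizes** channel ratios to treatment/control ratios per replicate
   orientation (`ratio_processing`) and aggregates per protein (linear-scale
   mean ± SD, plus log2 ratios per replicate).
2. **Filters** to proteins quantified (both axes) in at least 2 of the
   replicates, and calls **differential expression** at an inclusive two-fold
   threshold, with one-sample t-tests on log2 ratios for the volcano table
   (`dep_volcano`).
3. **Classifies** every protein into one of nine joint response patterns
   (P1–P9) from its single-FFA and combined-treatment categories — including
   the "enhanced" (P4) and "reversed" (P6, P8) subcells — and summarizes
   counts and proportions (`pattern_classifier`).
4. Runs **gene-set over-representation** with exact hypergeometric upper-tail
   p-values and the three standard filters (p < 0.01, count ≥ 3, enrichment
   factor > 1.5), plus single-linkage Jaccard clustering of terms
   (`enrichment`).
5. Intersects a ChIP-predicted **TF-target table** (both binding scores > 0,
   TSS distance ≤ 1 kb) with the pattern groups to find "responder" genes
   (`tf_overlap`).
6. Generates fully **synthetic datasets** — quant tables with planted
   per-protein patterns, multiplicative log-normal ratio noise, per-replicate
   missingness, plus matched gene-set and TF-target fixtures — so every stage
   is testable without external data (`synthetic_data`).

## CLI

```sh
# simulate a dataset with known truth (plus gene sets / TF targets)
silacpipe simulate --n-proteins 1000 --seed 1 --n-sets 10 --out sim/

# full pipeline: harmonize -> filter -> volcano -> classify -> enrich -> tf-overlap
silacpipe run --quant sim/quant.tsv --design sim/design.yaml \
    --gmt sim/gene_sets.gmt --tf sim/tf_targets.tsv --out out/

# individual stages
silacpipe classify --quant sim/quant.tsv --design sim/design.yaml --out out/
silacpipe enrich --query genes.txt --gmt sets.gmt --out enrichment.tsv
silacpipe tf-overlap --tf tf.tsv --assignments out/pattern_assignments.tsv --out overlap.tsv
```

`run` writes `protein_summary.tsv`, `volcano.tsv`, `pattern_assignments.tsv`,
`pattern_summary.tsv`, optional `enrichment.tsv` / `tf_overlap.tsv`, and a
machine-readable `report.json` echoing every threshold applied. Thresholds
live in a YAML config (`--config`); defaults match the published analysis
parameters. Validation failures exit with code 2. Reruns on identical inputs
are byte-identical.

## File formats

All tables are UTF-8 TSV with mandatory headers: quant tables
(`protein_id, gene_symbol, replicate_id, ratio_hm, ratio_lm`), TF-target
tables (`gene_symbol, score_macs2, score_string, tss_distance_kb`), standard
GMT for gene sets, and YAML for the experiment design and config. Missing
ratios are written `NA`; gene symbols are matched case-insensitively.
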