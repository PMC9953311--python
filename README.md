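# cernet

Toolkit for circRNA–miRNA–mRNA competing-endogenous-RNA (ceRNA) network
discovery from case/control expression profiles, built around the classic
sponge-axis screening workflow:

1. **Differential expression** per omics layer (log2FC; Welch t or
   limma-style empirical-Bayes moderated t; Benjamini–Hochberg adjustment;
   strict `p < 0.05`, `|log2FC| > 1` gating by default).
2. **ceRNA assembly** — co-miRNAs/co-mRNAs via DEG ∩ predicted-target
   intersection, a multi-database support rule for miRNA→mRNA pairs
   (default: all three databases), exhaustive triplet enumeration, and an
   optional expression-direction consistency filter
   (circRNA/mRNA co-directional, miRNA opposite).
3. **PPI module detection** — a from-scratch MCODE implementation
   (degree cutoff 2, node score cutoff 0.2, k-core 2, max depth 100,
   module score > 5, haircut on) plus degree-ranked hub genes.
4. **Enrichment** — upper-tail hypergeometric over-representation against
   GMT collections, computed in log-space, BH-adjusted.
5. **Diagnostics** — single-feature ROC/AUC (Mann–Whitney identity, ties
   worth ½, auto-orientation, exact permutation p at small n) and Pearson
   correlation.

A synthetic-data module generates full fixture bundles (three expression
layers shaped 3v3 / 6v5 / 7v5, target tables with controlled
three-database overlap, a PPI graph with a recoverable dense module, gene
sets, and a ground-truth record of planted sponge axes) so the entire
chain is testable offline.

## CLI

```bash
# generate a synthetic fixture bundle with 5 planted sponge axes
cernet simulate --out-dir fixtures --seed 1

# run every stage on it
cernet run-all --input-dir fixtures --out-dir results --direction-filter

# individual stages
cernet dge --matrix fixtures/expression_m.tsv --groups fixtures/groups_m.tsv \
           --out dge_m.tsv --method moderated --p-thresh 0.05 --lfc-thresh 1.0
cernet modules --ppi fixtures/ppi.sif --out-dir mods --min-module-score 5
cernet enrich --query genes.txt --gmt fixtures/gene_sets.gmt --out enr.tsv
cernet roc --scores scores.tsv --out-prefix roc
```

`run-all` writes per-stage TSVs, GraphML/SIF network exports, and a
`report.json` whose stage counts are audited against the emitted tables.
A YAML config (`--config`) can replace the flags; see
`cernet.pipeline.PipelineConfig`.

## File formats

- expression: TSV (feature id + one column per sample, log2 scale) with a
  two-column sample→group TSV (`TAD`/`CON`); GEO series-matrix files are
  also accepted (`cernet.io.read_series_matrix`).
- targets: TSV with `source_id`, `target_id`, `database`.
- gene sets: GMT. PPI: SIF or two-column edge list. Ground truth: JSON.

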