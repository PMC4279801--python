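# lactokin

Kinetic transcriptome analysis of two *Trichoderma reesei* cellulase-producer
strains — the moderate producer NG 14 and the hyper producer RUT C30 — under
lactose fed-batch induction, rebuilt as a tested, reusable pipeline and
exercised end-to-end on a synthetic-data generator with known ground truth.

*T. reesei* is the main industrial source of cellulolytic enzymes. Comparing
how a moderate and a hyper producer respond to the same inducing lactose feed
(sampled at 1, 3, 6 and 24 h against a time-0 reference) separates genes tied
to the induction signal from genes tied to productivity, and crossing the
regulated genes with the strains' mutation catalogues points at the mutations
that plausibly matter. The package implements every computational stage of
that comparison:

- **Microarray preprocessing** — per-hybridization M/A statistics
  (M = log2 test/reference, A = mean log2 intensity), global lowess
  normalization without background subtraction, a detectability threshold at
  mean + 2 SD of the "not found" features, and orientation-corrected
  (dye-swap sign flip) probe averaging per transcript.
- **Differential expression** — per strain × time contrast: one-sample fits,
  empirical-Bayes variance moderation (posterior variance
  (d₀s₀² + d·s²)/(d₀ + d), moderated t on d₀ + d df), Benjamini–Hochberg
  adjustment, selection at FDR ≤ 5 % and |log2FC| > 1, and the
  strain-specific/shared consolidation.
- **Consensus clustering** — 30 % missing-value filter, K from the
  average-linkage Euclidean dendrogram, five random-start K-means runs
  aggregated through the gene × gene co-occurrence matrix C, final clusters
  from an average-linkage cut of (1 − C) at the 60 % co-occurrence threshold,
  and up/down direction calls.
- **RNA-seq basal comparison** — RPKM (reads × 10⁹ / (exon length × mapped
  total)) log2 ratios between the strains at time 0 under the dual filter
  |log2 ratio| ≥ 4 with average reads > 100, per cluster.
- **Mutation integration** — mutations assigned to genes whose window
  [start codon − 800 bp, stop codon + 800 bp] they hit, region-classified
  (promoter/exon/intron/terminator, strand-aware), intersected with the
  regulated genes and tabulated by cluster and lineage.
- **Functional categories** — per-cluster FunCat tabulation with the
  main-category (> 10 genes) and emphasis (≥ 2-gene lead) rules.
- **Bioprocess arithmetic** — specific productivity
  q = ΔP/(mean biomass × Δt), the Bradford→Lowry correction range (×3.5–5),
  and the ≥ 0.90 gC/gC carbon-balance check.

The synthetic generator emulates the study design (two strains × four time
points, dye-swapped duplicate hybridizations, three probes per transcript,
a nondetectable background population, negative-binomial time-0 counts with
a small set of ≥ 16-fold basal differences, and a mutation catalogue placed
inside/outside the 800-bp windows) so every stage is testable against known
truth without any download.

## Worked example

The analysis is driven by the numbered scripts under `analysis/`, which write
their tables under `results/`:

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_preprocess_arrays.py
python analysis/03_differential_expression.py
python analysis/04_consensus_clustering.py
python analysis/05_basal_rnaseq.py
python analysis/06_mutation_windows.py
python analysis/07_funcat_table.py
python analysis/08_bioprocess_metrics.py
```

With seed 1 this prints, among other things:

```
simulated 2000 genes, 540 regulated across 9 archetypes, 20 basal-shifted genes,
  165 mutations (115 inside a gene window) -> results/inputs
2000 transcripts x 16 hybridizations, 32 discarded (missing) entries
557 regulated genes in >= 1 contrast; venn {'specific_NG14': 246,
  'specific_RUTC30': 127, 'shared': 184, 'total': 557}
557 of 557 genes in 10 clusters ..., 0 unclustered
recovery ARI vs generating archetypes: 1.000
published comparison table: 22/23 rows satisfy the stated dual filter;
  discrepancies: [{'transcript_id': 79816, 'annotation': 'Putative
  transcriptional regulator GAL80', 'average_reads': 90}]
synthetic series: q = 3.98 mg/g_cell/h over 4-30 h -> corrected range
  (13.9, 19.9); carbon balance 0.95 (pass vs 0.90)
```

Reading: of 2000 simulated genes, 557 pass the FDR/fold-change selection
(the 540 planted regulated genes plus a small false-positive margin —
realized false-discovery proportion ≈ 1–2 %); consensus clustering recovers
the nine planted archetypes perfectly (adjusted Rand index 1.0); the
published 23-gene basal-comparison table re-filtered under its own stated
rule keeps 22 rows and reports the one violator (the GAL80 regulator, 90
average reads) instead of silently keeping it; and a cultivation series built
from constant q = 3.98 mg/g_cell/h inverts to exactly that value, with the
3.5–5× assay correction giving the 13.9–19.9 mg/g_cell/h range.

Equivalently, `lactokin.pipeline.run_pipeline(outdir=..., seed=1)` executes
all stages in one call and writes a manifest with input/output digests and
recovery diagnostics.

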