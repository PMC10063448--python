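# gdtcr

Analysis pipeline for tumor-infiltrating **γδ T-cell** single-cell data:
paired γ/δ V(D)J contig processing, clonotype and clonal-expansion
calling, repertoire diversity, CDR3 similarity networks, expression-side
clustering and gene-set scoring, derivation of a Vδ2⁻ transcriptional
signature, and signature-based stratification of bulk cohorts by
survival and clinical response.

It is aimed at computational immunologists working with 10x-style
single-cell V(D)J + gene-expression data of γδ T cells (e.g. from renal
cell carcinoma), and ships a first-class synthetic-data module so every
stage can be validated against planted ground truth.

## What it computes

**Contigs → cells.** Annotated contigs (10x CSV or AIRR TSV) are
filtered to productive rearrangements (six independent conditions:
full length, start codon, CDR3 present, in frame, no internal stop,
consistent V/J locus — or the upstream `productive` flag when present).
Hybrid Vα/Vδ contigs (TRAV14DV4, TRAV23DV6, TRAV29DV5, TRAV36DV7,
TRAV38-2DV8) are relabelled as delta-chain contigs when their D, J and C
genes are all TRD-locus genes. One γ and one δ contig per cell (highest
UMI count) are paired by barcode.

**Clonotypes and diversity.** Per sample, a cell's clonotype key is the
γ full nucleotide sequence concatenated with the δ sequence; a cell is
*expanded* when ≥ 2 cells in its sample share the key, else a
*singleton*. Diversity is the Gini coefficient of the clone-size
distribution,

    G = Σᵢ Σⱼ |xᵢ − xⱼ| / (2 n² μ),

0 for a perfectly even repertoire. Chain-usage tables report each δ
V-gene's share overall and within the Vδ2⁻ subset.

**CDR3 networks.** Per patient, cells with a phenotype-cluster label are
connected when the Levenshtein distance between their δ-chain CDR3
amino-acid sequences is ≤ a threshold (default 0 = identical). Reported
statistics are the number of clusters and the maximum cluster size, each
normalized by the number of cells and log₁₀-transformed.

**Expression.** Scanpy-based QC (cells < 200 genes removed; genes in
< 3 cells removed; cells kept only with < 4,000 genes, < 20,000 counts
and < 10 % mitochondrial reads), normalization to 10,000 counts per cell
with log1p, optional batch location adjustment, Leiden clustering
(resolution 0.6), expression-based Vδ2⁺/Vδ2⁻ labels (argmax over Vδ
genes), control-matched gene-set scores, Wilcoxon rank-sum differential
expression with BH adjustment, and the signature = top-20 upregulated
genes by p-value from the contrast Vδ2⁻ γδ vs pooled Vδ2⁺ γδ + αβ CD4 +
CD8 cells.

**Cohorts.** Bulk samples are scored by rank-percentile enrichment of
the signature (mean within-sample rank percentile of signature genes,
invariant to monotone per-sample transforms), median-split and compared
with a 5-year Kaplan–Meier / log-rank analysis, or compared between
responders (CR/PR) and non-responders (SD/PD) with a rank-sum test.

## Worked example

```bash
gdtcr run --demo --seed 7 --out demo_out
```

generates a synthetic three-patient repertoire (~150 γδ cells each,
power-law clone sizes, 5 % unproductive contigs), matched expression
profiles pooled with 1,550 simulated αβ reference cells, and a
150-sample bulk cohort driven by the derived signature, then runs every
stage. Selected outputs from that exact run:

* `gini.tsv` — per-patient repertoire Gini: patient1 0.558,
  patient2 0.639, patient3 0.405. Values near 0 would mean an even
  repertoire; these repertoires are dominated by a few expanded clones.
* `network_stats.tsv` — patient1: 132 eligible cells, 46 CDR3 clusters,
  largest cluster 40 cells; normalized log₁₀ values −0.458 and −0.519
  (0 would mean every cell its own cluster / one cell per cluster).
* `signature.json` — the 20 signature genes; with the planted effect the
  list is dominated by the planted `SIG…` genes plus genuinely
  Vδ2⁻-specific Vδ transcripts.
* `cohort_results.json` — median-split log-rank χ² = 54.6,
  p = 1.5 × 10⁻¹³; responder vs non-responder score medians 0.854 vs
  0.764, rank-sum p = 5.0 × 10⁻⁸. The planted hazard ratio (2.5 per SD
  of signature fraction) and response logit slope (1.0) are recovered as
  strong, correctly signed associations.

Stage-level commands (`gdtcr contigs`, `gdtcr clonotypes`,
`gdtcr network`, `gdtcr cohort`) run individual steps on explicit
inputs; the same functionality is importable from `gdtcr` as plain
functions.

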