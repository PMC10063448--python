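# Methods

This note documents the models, conventions and design choices behind
`gdtcr`, in the spirit of a statistical package's methods appendix. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Contig processing

A *productive* contig encodes a functional receptor chain. Six
independent toggles realize this (`ProductiveRules`): full-length span,
initiator ATG at the start of the assembled sequence, CDR3 detected,
CDR3 nucleotide junction length divisible by 3 (in frame), no internal
stop codon (checked in the CDR3 translation and in the frame-0
translation of the full sequence, ignoring a terminal stop), and V/J
calls from a consistent locus (hybrid Vα/Vδ segments are treated as
consistent with both TRA and TRD). When the input already carries a
definite `productive` flag it is trusted by default
(`trust_flag=True`) and the rules are evaluated only for records with an
unknown flag; rule-only evaluation is available for dialects whose flags
are unreliable. Every exclusion is recorded with a reason code so the
filter is auditable and idempotent.

Hybrid delta reassignment follows the rule: a contig whose V gene is one
of TRAV14DV4, TRAV23DV6, TRAV29DV5, TRAV36DV7, TRAV38-2DV8 (matched
case-insensitively, tolerant of `TRAV14/DV4` spellings) becomes a TRD
contig iff its D, J *and* C calls all lie on the TRD locus; an empty
call fails the condition. Only the `chain` field ever changes.

Cells with multiple productive contigs per locus are resolved by
highest UMI count, ties broken by read count then lexicographic contig
id — a deliberate convention (upstream tools do not specify one) chosen
so results are invariant to input row order. γ-only / δ-only cells are
reported as orphans and excluded from pairing.

## Clonotypes, expansion, diversity

Clonotype identity is the concatenation of the γ and δ full nucleotide
sequences, scoped per sample: identical sequences in two patients are
two clonotypes. Expansion is cell-level: a cell is expanded iff ≥ 2
cells of its sample share its key. Summaries report percentages of
cells; a clone-level table is emitted alongside because the two views
differ for skewed repertoires.

The Gini coefficient uses the pairwise mean-absolute-difference
definition G = Σ|xᵢ−xⱼ|/(2n²μ) with no small-sample correction — the
plain form is exactly testable against hand-enumerated values and is
scale-invariant. It is computed via the sorted-rank identity in
O(n log n). Paired group comparisons use the Wilcoxon signed-rank test:
exact null distribution for ≤ 25 tie-free, zero-free pairs, otherwise
the normal approximation with continuity correction; identical vectors
return p = 1 by convention rather than an error.

Chain-usage tables compute within-Vδ2⁻ shares from counts; this is
arithmetically identical to dividing the overall share by the Vδ2⁻
fraction, and the table carries both exact and rounded (1 decimal)
columns so the identity is testable to full precision.

## CDR3 networks

Networks are built per patient only — cross-patient edges are never
formed. Nodes are cells that carry a phenotype-cluster label (cells
dropped by expression QC therefore vanish from the network, which is
the intended semantics); edges join pairs at Levenshtein distance ≤
threshold. The default threshold 0 connects only identical δ-chain CDR3
amino-acid sequences; at threshold 0 construction short-circuits to
exact-match grouping, which yields the same edge set as the all-pairs
distance matrix and is O(n) rather than O(n²). Larger thresholds are
supported for exploration but are not part of default outputs.

Distances come from edlib (bit-parallel Myers algorithm); the test suite
checks it against a textbook dynamic-programming implementation on all
string pairs of length ≤ 5 over a 3-letter alphabet plus random strings,
together with the metric axioms.

Summary statistics are the number of connected components and the
largest component size, each divided by the number of cells and log₁₀
transformed. The normalization direction (clusters ÷ cells) makes both
statistics ≤ 0, with 0 attained by a fully diverse repertoire
(every cell its own cluster) and by a single-cell network.

## Expression pipeline

QC order is fixed: (1) drop cells with < 200 detected genes, (2) drop
genes detected in < 3 cells, (3) drop cells at or above any strict upper
bound — 4,000 genes, 20,000 counts, 10 % mitochondrial reads
(`MT-` prefix, configurable). Bounds are strict (`<`), so a cell with
exactly 4,000 genes is removed. Normalization scales each cell to
10,000 counts then applies log1p (natural log); raw counts are kept in
`layers["counts"]`.

Batch adjustment is per-gene location equalization (per-batch means
shifted to the grand mean) with an optional scale toggle — a simple,
exactly-testable adjustment that removes additive technical shifts
while preserving balanced biological contrasts.

Clustering is dispersion-based HVG selection (up to 2,000 genes),
scaling, PCA (30 components by default, capped by matrix rank), a
15-neighbor kNN graph and Leiden community detection at resolution 0.6
with a fixed random state. These HVG/PCA/neighbor defaults are standard
and exposed as parameters.

Vδ2 labels are the argmax over the Vδ gene list (TRDV1/2/3 plus the
five hybrid segments): TRDV2 → Vδ2⁺, any other winner → Vδ2⁻. All-zero
cells and exact ties are *unassigned* rather than arbitrarily broken,
avoiding silent misclassification; on noise-free simulations the
expression-based labels agree 100 % with contig-derived labels.

Gene-set scores use scanpy's control-matched scheme (mean expression of
the set minus the mean of a control set sampled from 25
expression-magnitude bins, 50 controls per gene by default, fixed seed).
A constant matrix scores exactly 0 and random sets center on 0.

Differential expression is a per-gene two-sided Wilcoxon rank-sum test
implemented in-package so its conventions are pinned: normal
approximation with tie correction, BH adjustment across genes, and
natural-log fold change log(mean expm1(target)+ε) − log(mean
expm1(reference)+ε) with ε = 10⁻⁹. Fold changes are clipped to ±7 only
in the display column; ranking uses unclipped values. The signature is
the top k = 20 upregulated genes by ascending raw p, ties broken by
larger fold change then gene name (deterministic under permutation);
fewer than k upregulated genes returns all with a warning.

## Cohort scoring and outcome association

External cell-type enrichment tooling is deliberately replaced by a
self-contained rank-percentile enrichment score: within each sample all
genes are ranked (average ties) and the score is the mean rank
percentile of the signature genes. The score is invariant to any
strictly increasing per-sample transform, so differently normalized
cohorts remain comparable; results are method-qualified and not claimed
numerically identical to other enrichment tools.

Median split labels samples strictly above the cohort median *high*,
at-or-below *low* (an odd cohort's median sample is low; all-equal
scores degenerate to all-low with a warning). Survival is truncated at
60 months (administrative censoring) before the Kaplan–Meier /
log-rank analysis, which is delegated to lifelines; the log-rank
statistic is χ² on 1 df. Response association compares CR/PR vs SD/PD
scores with the rank-sum test (exact for small tie-free groups) and
reports per-class medians and quartiles.

## Synthetic data

The generators define the study conditions for all recovery tests.

*Repertoire*: clone sizes are explicit or drawn from a discrete power
law (default exponent 2.5 on support 1–50, truncated to the requested
cell count); each clone draws a δ V gene from the chain-usage mixture —
default TRDV1 36 %, TRDV2 28 %, TRAV14DV4 13 %, TRAV29DV5 7 %,
TRAV23DV6 7 %, TRDV3 6 %, TRAV36DV7 3 %, the composition of a
tumor-infiltrating γδ repertoire — a γ V gene uniformly from a 6-gene
pool, and one γ and one δ sequence (ATG start, stop-free codon context,
CDR3 junction of 9–17 random non-stop codons, amino-acid view by
standard-table translation) copied verbatim to every member cell, which
guarantees clonotype identity by construction. Noise knobs: per-contig
unproductive probability (plants an internal stop and flags the
record), orphan-chain probabilities, and a probability of withholding
the productive flag (exercising rule-based re-evaluation). Hybrid-V
clones are emitted with chain `TRA` and δ D/J/C genes, as annotation
pipelines produce them, so delta reassignment is always exercised.

*Expression*: negative-binomial counts with per-gene lognormal baseline
means (shape `nb_dispersion`, variance μ + μ²/r, Poisson in the r → ∞
limit). Planted structure: per-cluster marker genes and Vδ marker genes
elevated by a log-fold effect in their assigned cluster, and signature
genes shifted by `signature_effect` in a designated subpopulation.
Optional batches add gene-wise lognormal shifts.

*Cohort*: each sample mixes background and signature-bearing profiles
with weight (the signature fraction) uniform on a configured range;
survival times are exponential with hazard λ₀·HR^z where z is the
standardized fraction and λ₀ gives a 30-month baseline median; a unit
HR is the null. Censoring marks a fixed fraction of samples and scales
their times down uniformly. Response is Bernoulli with logit linear in
z around a 30 % base rate.

What the generators do **not** model: sequencing reads, doublets,
ambient RNA, UMI saturation, mitochondrial content (simulated cells
have 0 % mito and thus always pass that bound), realistic gene–gene
correlation, or batch effects beyond additive shifts. Passing recovery
tests therefore demonstrates the correctness of the analysis logic
under the stated generative model, not robustness to every artifact of
real data.

## Reproducibility and problem sizes

One integer seed drives each generator through a single
`numpy.random.Generator`; the pipeline fans its global seed out to
per-stage seeds by fixed offsets so stages are individually
reproducible. The demo pipeline writes a manifest (parameters + SHA-256
of every artifact) that is byte-identical across runs with the same
seed.

Validation problem sizes were chosen to make the checks sharp yet quick:
noise-free repertoires of ~30–50 cells with hand-chosen clone sizes for
exact recovery; 400–500 cells × 200–400 genes for clustering (ARI > 0.9
against planted 2-cluster designs) and signature recovery (25 planted
genes, effect 1.5 natural-log units); 1,000 replicate null cohorts of
n = 100 for log-rank type-I calibration and 100 replicates of n = 200 at
HR 3 per SD for power; the demo runs 3 × 150 γδ cells plus 1,550 αβ
reference cells.

## Known limitations

* The productive-contig rules approximate upstream assembler semantics;
  exotic dialect fields (e.g. frame-shifted full-length sequences with
  valid CDR3 annotations) may be judged differently than by the
  original annotation tool.
* The rank-sum DE p-value is asymptotic; for very small groups the
  exact test (available in `gdtcr._stats.rank_sum_test`) differs.
* The log-rank test uses the asymptotic χ² reference distribution and
  is mildly anti-conservative at moderate cohort sizes (n ≈ 100); the
  acceptance script measures the realized null rejection rate.
* The cohort score treats signature genes symmetrically (no weights)
  and ignores gene–gene correlation.
* Network construction above threshold 0 is O(n²) per patient.
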