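"""Synthetic data generators with planted ground truth.

Three generators emulate the inputs of the analysis stages:

* :func:`simulate_repertoire` — paired γ/δ V(D)J contig tables with a
  planted clone-size distribution, δ-chain usage mixture and contig noise
  (unproductive contigs, orphan chains).
* :func:`simulate_expression` — cell × gene negative-binomial count
  matrices with planted subpopulations, Vδ marker genes and a planted
  gene signature shifted in one subpopulation.
* :func:`simulate_cohort` — bulk expression cohorts in which a planted
  per-sample signature fraction drives an exponential survival hazard and
  a Bernoulli response probability.

Every generator is driven by a single integer seed through one
:class:`numpy.random.Generator`, so fixtures are exactly reproducible and
each downstream stage can be checked against the planted truth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import io as spio
from scipy import sparse

from gdtcr._errors import ConfigurationError

# codons that do not terminate translation; CDR3 junctions are built from
# these so productive contigs never contain an internal stop
_STOP = {"TAA", "TAG", "TGA"}
_CODONS = [
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in _STOP
]

DEFAULT_CHAIN_USAGE = {
    "TRDV1": 0.36,
    "TRDV2": 0.28,
    "TRAV14DV4": 0.13,
    "TRAV29DV5": 0.07,
    "TRAV23DV6": 0.07,
    "TRDV3": 0.06,
    "TRAV36DV7": 0.03,
}

DEFAULT_GAMMA_POOL = ["TRGV9", "TRGV4", "TRGV2", "TRGV3", "TRGV5", "TRGV8"]

# hybrid Vα/Vδ segments are emitted with chain="TRA" (as annotation
# pipelines call them) so that delta reassignment is exercised downstream
HYBRID_V_GENES = {"TRAV14DV4", "TRAV23DV6", "TRAV29DV5", "TRAV36DV7", "TRAV38-2DV8"}

TENX_COLUMNS = [
    "barcode",
    "is_cell",
    "contig_id",
    "high_confidence",
    "length",
    "chain",
    "v_gene",
    "d_gene",
    "j_gene",
    "c_gene",
    "full_length",
    "productive",
    "cdr3",
    "cdr3_nt",
    "reads",
    "umis",
    "raw_clonotype_id",
    "sequence",
]


@dataclass
class RepertoireSimConfig:
    """Configuration for the paired γ/δ contig simulator.

    ``clone_size_law`` is either an explicit list of clone sizes summing to
    ``n_cells``, or ``None`` to draw sizes from a discrete power law with
    exponent ``power_law_exponent`` on support ``1..power_law_max_size``.
    """

    n_cells: int = 100
    clone_size_law: list[int] | None = None
    power_law_exponent: float = 2.5
    power_law_max_size: int = 50
    chain_usage: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHAIN_USAGE)
    )
    gamma_gene_pool: list[str] = field(default_factory=lambda: list(DEFAULT_GAMMA_POOL))
    frac_unproductive: float = 0.0
    frac_orphan_gamma: float = 0.0
    frac_orphan_delta: float = 0.0
    frac_flag_unknown: float = 0.0
    cdr3_length_range: tuple[int, int] = (9, 17)
    sample_id: str = "sim1"
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells <= 0:
            raise ConfigurationError("n_cells must be positive")
        total = sum(self.chain_usage.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"chain_usage proportions sum to {total!r}, expected 1"
            )
        if any(p < 0 for p in self.chain_usage.values()):
            raise ConfigurationError("chain_usage proportions must be non-negative")
        if self.clone_size_law is not None:
            if any(s <= 0 for s in self.clone_size_law):
                raise ConfigurationError("clone sizes must be positive")
            if sum(self.clone_size_law) != self.n_cells:
                raise ConfigurationError(
                    "explicit clone sizes must sum to n_cells "
                    f"({sum(self.clone_size_law)} != {self.n_cells})"
                )
        for name in ("frac_unproductive", "frac_orphan_gamma", "frac_orphan_delta",
                     "frac_flag_unknown"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.cdr3_length_range
        if not (3 <= lo <= hi):
            raise ConfigurationError("cdr3_length_range must satisfy 3 <= lo <= hi")


@dataclass
class ExpressionSimConfig:
    """Configuration for the negative-binomial count-matrix simulator."""

    n_cells: int = 500
    n_genes: int = 300
    n_clusters: int = 2
    nb_mean: float = 2.0
    nb_dispersion: float = 2.0
    n_marker_genes_per_cluster: int = 20
    marker_log_fc: float = 2.0
    planted_signature_genes: list[str] = field(default_factory=list)
    signature_effect: float = 1.0
    signature_cluster: int = 0
    vd_marker_genes: dict[str, int] = field(default_factory=dict)
    batch_labels: list[str] | None = None
    batch_log_fc: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0 or self.n_clusters <= 0:
            raise ConfigurationError("n_cells, n_genes, n_clusters must be positive")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ConfigurationError("nb_mean and nb_dispersion must be positive")
        if not np.isfinite(self.signature_effect):
            raise ConfigurationError("signature_effect must be finite")
        n_special = len(self.planted_signature_genes) + len(self.vd_marker_genes)
        if self.n_genes < n_special:
            raise ConfigurationError(
                "n_genes smaller than the number of planted genes"
            )
        if not 0 <= self.signature_cluster < self.n_clusters:
            raise ConfigurationError("signature_cluster out of range")
        for cl in self.vd_marker_genes.values():
            if not 0 <= cl < self.n_clusters:
                raise ConfigurationError("vd_marker_genes cluster index out of range")
        if self.batch_labels is not None and len(self.batch_labels) != self.n_cells:
            raise ConfigurationError("batch_labels length must equal n_cells")


@dataclass
class CohortSimConfig:
    """Configuration for the bulk-cohort simulator.

    Survival times are exponential with log-hazard linear in the
    standardized planted signature fraction; a hazard ratio per standard
    deviation of 1 is the null. The response label is Bernoulli with logit
    linear in the same standardized fraction.
    """

    n_samples: int = 100
    signature_genes: list[str] = field(
        default_factory=lambda: [f"SIG{i:03d}" for i in range(20)]
    )
    n_background_genes: int = 200
    signature_fraction_range: tuple[float, float] = (0.0, 0.5)
    signature_log_fc: float = 2.0
    hazard_ratio_per_sd: float = 1.0
    baseline_median_survival: float = 30.0
    response_logit_slope: float = 0.0
    response_base_rate: float = 0.3
    censor_rate: float = 0.2
    arm: str = "arm1"
    noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ConfigurationError("n_samples must be at least 2")
        lo, hi = self.signature_fraction_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ConfigurationError(
                "signature_fraction_range must be a non-degenerate sub-interval of [0, 1]"
            )
        if self.hazard_ratio_per_sd <= 0:
            raise ConfigurationError("hazard_ratio_per_sd must be positive")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ConfigurationError("censor_rate must be in [0, 1]")
        if not self.signature_genes:
            raise ConfigurationError("signature_genes must be non-empty")


# ---------------------------------------------------------------------------
# repertoire


def _random_cdr3(rng: np.random.Generator, aa_len: int) -> tuple[str, str]:
    """Random stop-free CDR3 junction; returns (nt, aa)."""
    codons = rng.choice(_CODONS, size=aa_len)
    nt = "".join(codons)
    return nt, str(Seq(nt).translate())


def _random_barcode(rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=16)) + "-1"


def _draw_clone_sizes(cfg: RepertoireSimConfig, rng: np.random.Generator) -> list[int]:
    if cfg.clone_size_law is not None:
        return list(cfg.clone_size_law)
    support = np.arange(1, cfg.power_law_max_size + 1)
    weights = support.astype(float) ** (-cfg.power_law_exponent)
    weights /= weights.sum()
    sizes: list[int] = []
    total = 0
    while total < cfg.n_cells:
        s = int(rng.choice(support, p=weights))
        s = min(s, cfg.n_cells - total)
        sizes.append(s)
        total += s
    return sizes


def simulate_repertoire(
    config: RepertoireSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate paired γ/δ contigs for one sample.

    Returns ``(contigs, truth)``. ``contigs`` is a 10x-dialect contig
    annotation table (one γ and one δ row per intact cell, sharing the cell
    barcode; hybrid Vα/Vδ contigs carry chain="TRA" with δ D/J/C genes).
    Cells of the same planted clone carry identical γ and δ nucleotide
    sequences. ``truth`` records, per cell, the planted clone id, δ V gene,
    expansion status and per-contig productivity and presence.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    clone_sizes = _draw_clone_sizes(config, rng)
    vd_genes = list(config.chain_usage)
    vd_probs = np.array([config.chain_usage[g] for g in vd_genes], dtype=float)
    vd_probs /= vd_probs.sum()
    lo, hi = config.cdr3_length_range

    clones = []
    for cid, size in enumerate(clone_sizes):
        vd = vd_genes[rng.choice(len(vd_genes), p=vd_probs)]
        gv = config.gamma_gene_pool[rng.integers(len(config.gamma_gene_pool))]
        g_cdr3_nt, g_cdr3_aa = _random_cdr3(rng, int(rng.integers(lo, hi + 1)))
        d_cdr3_nt, d_cdr3_aa = _random_cdr3(rng, int(rng.integers(lo, hi + 1)))
        # full contig sequence: start codon, stop-free V context, junction,
        # stop-free J context — shared verbatim by every clone member
        g_seq = "ATG" + "".join(rng.choice(_CODONS, 20)) + g_cdr3_nt + "".join(
            rng.choice(_CODONS, 10)
        )
        d_seq = "ATG" + "".join(rng.choice(_CODONS, 20)) + d_cdr3_nt + "".join(
            rng.choice(_CODONS, 10)
        )
        clones.append(
            dict(
                clone_id=cid,
                size=size,
                vd_gene=vd,
                gamma_v=gv,
                g_cdr3_nt=g_cdr3_nt,
                g_cdr3_aa=g_cdr3_aa,
                d_cdr3_nt=d_cdr3_nt,
                d_cdr3_aa=d_cdr3_aa,
                g_seq=g_seq,
                d_seq=d_seq,
            )
        )

    barcodes = set()
    contig_rows = []
    truth_rows = []
    cell_idx = 0
    for clone in clones:
        for _ in range(clone["size"]):
            bc = _random_barcode(rng)
            while bc in barcodes:  # pragma: no cover - 4^16 space
                bc = _random_barcode(rng)
            barcodes.add(bc)

            has_gamma = rng.random() >= config.frac_orphan_delta
            has_delta = rng.random() >= config.frac_orphan_gamma
            if not has_gamma and not has_delta:
                has_gamma = True  # keep at least one contig per cell

            cell_contigs = []
            if has_gamma:
                cell_contigs.append(("TRG", clone["gamma_v"], "", "TRGJ1", "TRGC1",
                                     clone["g_cdr3_nt"], clone["g_cdr3_aa"],
                                     clone["g_seq"]))
            if has_delta:
                v = clone["vd_gene"]
                chain = "TRA" if v in HYBRID_V_GENES else "TRD"
                cell_contigs.append((chain, v, "TRDD3", "TRDJ1", "TRDC",
                                     clone["d_cdr3_nt"], clone["d_cdr3_aa"],
                                     clone["d_seq"]))

            productivity = {}
            for k, (chain, v, d, j, c, cdr3_nt, cdr3_aa, seq) in enumerate(
                cell_contigs
            ):
                productive = rng.random() >= config.frac_unproductive
                if not productive:
                    # plant an internal stop so rule-based evaluation agrees
                    # with the flag when the flag is withheld
                    seq = seq[:33] + "TAA" + seq[36:]
                flag: object = productive
                if rng.random() < config.frac_flag_unknown:
                    flag = None
                umis = int(rng.integers(2, 30))
                contig_rows.append(
                    dict(
                        barcode=bc,
                        is_cell="True",
                        contig_id=f"{bc}_contig_{k + 1}",
                        high_confidence="True",
                        length=len(seq),
                        chain=chain,
                        v_gene=v,
                        d_gene=d,
                        j_gene=j,
                        c_gene=c,
                        full_length="True",
                        productive={True: "True", False: "False", None: "None"}[flag],
                        cdr3=cdr3_aa,
                        cdr3_nt=cdr3_nt,
                        reads=umis * int(rng.integers(10, 60)),
                        umis=umis,
                        raw_clonotype_id=f"clonotype{clone['clone_id'] + 1}",
                        sequence=seq,
                    )
                )
                productivity[chain] = productive

            truth_rows.append(
                dict(
                    sample_id=config.sample_id,
                    barcode=bc,
                    clone_id=clone["clone_id"],
                    clone_size=clone["size"],
                    expanded=clone["size"] > 1,
                    vd_gene=clone["vd_gene"],
                    gamma_v=clone["gamma_v"],
                    delta_cdr3_aa=clone["d_cdr3_aa"],
                    has_gamma=has_gamma,
                    has_delta=has_delta,
                    gamma_productive=productivity.get("TRG", False),
                    delta_productive=productivity.get("TRD", productivity.get("TRA", False)),
                )
            )
            cell_idx += 1

    contigs = pd.DataFrame(contig_rows, columns=TENX_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    return contigs, truth


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    config: ExpressionSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cell × gene count matrix with planted structure.

    Returns ``(counts, meta)`` where ``counts`` is a dense cell × gene
    integer DataFrame (cells in rows) and ``meta`` records per-cell cluster
    membership, batch and whether the cell belongs to the
    signature-bearing subpopulation.

    Counts are negative binomial with mean ``nb_mean`` scaled per gene and
    shape ``nb_dispersion`` (variance = μ + μ²/dispersion, so large
    dispersion approaches Poisson). Each cluster gets
    ``n_marker_genes_per_cluster`` marker genes elevated by
    ``marker_log_fc`` (natural-log fold change); ``vd_marker_genes`` are
    elevated only in their assigned cluster; ``planted_signature_genes``
    are shifted by ``signature_effect`` in cells of ``signature_cluster``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    special = list(config.vd_marker_genes) + [
        g for g in config.planted_signature_genes if g not in config.vd_marker_genes
    ]
    n_background = config.n_genes - len(special)
    gene_names = special + [f"GENE{i:04d}" for i in range(n_background)]
    assert len(gene_names) == config.n_genes

    clusters = rng.integers(config.n_clusters, size=config.n_cells)
    # per-gene baseline expression on a lognormal scale around nb_mean
    base = config.nb_mean * rng.lognormal(mean=0.0, sigma=0.5, size=config.n_genes)
    log_mu = np.tile(np.log(base), (config.n_cells, 1))

    gene_index = {g: i for i, g in enumerate(gene_names)}
    # generic cluster markers drawn from the background genes
    bg_idx = np.array([gene_index[g] for g in gene_names if g not in special])
    rng.shuffle(bg_idx)
    marker_assignment: dict[int, np.ndarray] = {}
    p = 0
    for cl in range(config.n_clusters):
        take = bg_idx[p : p + config.n_marker_genes_per_cluster]
        p += config.n_marker_genes_per_cluster
        marker_assignment[cl] = take
        log_mu[np.ix_(clusters == cl, take)] += config.marker_log_fc

    for gene, cl in config.vd_marker_genes.items():
        log_mu[np.ix_(clusters == cl, [gene_index[gene]])] += config.marker_log_fc

    sig_mask = clusters == config.signature_cluster
    sig_idx = [gene_index[g] for g in config.planted_signature_genes]
    if sig_idx:
        log_mu[np.ix_(sig_mask, sig_idx)] += config.signature_effect

    if config.batch_labels is not None:
        batches = pd.Series(config.batch_labels)
        for b in batches.unique():
            shift = rng.normal(0.0, config.batch_log_fc, size=config.n_genes)
            log_mu[(batches == b).to_numpy()] += shift
    else:
        batches = pd.Series(["batch0"] * config.n_cells)

    mu = np.exp(log_mu)
    r = config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    cell_ids = [f"CELL{i:05d}" for i in range(config.n_cells)]
    counts_df = pd.DataFrame(counts, index=cell_ids, columns=gene_names)
    meta = pd.DataFrame(
        dict(
            cell_id=cell_ids,
            cluster=clusters,
            batch=batches.to_numpy(),
            in_signature_population=sig_mask,
        )
    ).set_index("cell_id")
    return counts_df, meta


# ---------------------------------------------------------------------------
# cohort


def simulate_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Simulate a bulk cohort with survival and response driven by a
    planted signature fraction.

    Each sample's expression is a mixture of a background profile and a
    signature-bearing profile with mixing weight (the "signature
    fraction") drawn uniformly from ``signature_fraction_range``. Survival
    times are exponential with hazard ``λ0 · HR^z`` where z is the
    standardized fraction; responses are Bernoulli with logit linear in z.

    Returns a wide DataFrame indexed by sample_id with gene columns plus
    ``time`` (months), ``event`` (0/1), ``response`` (CR/PR vs SD/PD),
    ``arm`` and the planted ``signature_fraction``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    frac = rng.uniform(*config.signature_fraction_range, size=n)
    z = (frac - frac.mean()) / frac.std(ddof=0)

    genes = list(config.signature_genes) + [
        f"BG{i:04d}" for i in range(config.n_background_genes)
    ]
    base = rng.lognormal(mean=2.0, sigma=0.5, size=len(genes))
    log_expr = np.tile(np.log(base), (n, 1))
    sig_cols = np.arange(len(config.signature_genes))
    log_expr[:, sig_cols] += config.signature_log_fc * frac[:, None]
    log_expr += rng.normal(0.0, config.noise_sd, size=log_expr.shape)
    expr = np.exp(log_expr)

    lam0 = np.log(2.0) / config.baseline_median_survival
    lam = lam0 * config.hazard_ratio_per_sd ** z
    time = rng.exponential(1.0 / lam)
    event = np.ones(n, dtype=int)
    censored = rng.random(n) < config.censor_rate
    event[censored] = 0
    time[censored] *= rng.random(censored.sum())
    time = np.maximum(time, 1e-3)

    logit = np.log(config.response_base_rate / (1 - config.response_base_rate))
    p_resp = 1.0 / (1.0 + np.exp(-(logit + config.response_logit_slope * z)))
    response = np.where(rng.random(n) < p_resp, "CR/PR", "SD/PD")

    table = pd.DataFrame(expr, columns=genes)
    table.insert(0, "sample_id", [f"SAMPLE{i:04d}" for i in range(n)])
    table["time"] = time
    table["event"] = event
    table["response"] = response
    table["arm"] = config.arm
    table["signature_fraction"] = frac
    return table.set_index("sample_id")


# ---------------------------------------------------------------------------
# writers / readers (round-trip safe, plain-text formats)


def write_contigs_10x(contigs: pd.DataFrame, path: str | Path) -> None:
    contigs.to_csv(path, index=False)


def write_contigs_airr(contigs: pd.DataFrame, path: str | Path) -> None:
    """Write a 10x-dialect contig table as an AIRR rearrangement TSV."""
    airr = pd.DataFrame(
        dict(
            cell_id=contigs["barcode"],
            sequence_id=contigs["contig_id"],
            locus=contigs["chain"],
            v_call=contigs["v_gene"],
            d_call=contigs["d_gene"],
            j_call=contigs["j_gene"],
            c_call=contigs["c_gene"],
            complete_vdj=contigs["full_length"].map(
                {"True": "T", "False": "F"}
            ),
            productive=contigs["productive"].map(
                {"True": "T", "False": "F", "None": ""}
            ),
            junction=contigs["cdr3_nt"],
            junction_aa=contigs["cdr3"],
            sequence=contigs["sequence"],
            duplicate_count=contigs["umis"],
            consensus_count=contigs["reads"],
        )
    )
    airr.to_csv(path, sep="\t", index=False)


def write_counts_mtx(counts: pd.DataFrame, outdir: str | Path) -> None:
    """Write a cell × gene count table as MTX + barcodes/features TSVs
    (genes × cells in the matrix file, as 10x does)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sparse.csr_matrix(counts.to_numpy().T)
    spio.mmwrite(outdir / "matrix.mtx", mat)
    pd.Series(counts.index).to_csv(
        outdir / "barcodes.tsv", index=False, header=False, sep="\t"
    )
    pd.Series(counts.columns).to_csv(
        outdir / "features.tsv", index=False, header=False, sep="\t"
    )


def read_counts_mtx(indir: str | Path) -> pd.DataFrame:
    indir = Path(indir)
    mat = spio.mmread(indir / "matrix.mtx").tocsr().T
    barcodes = pd.read_csv(indir / "barcodes.tsv", header=None, sep="\t")[0]
    features = pd.read_csv(indir / "features.tsv", header=None, sep="\t")[0]
    return pd.DataFrame(
        np.asarray(mat.todense()), index=list(barcodes), columns=list(features)
    )


def write_cohort_tsv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t")


def read_cohort_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")
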