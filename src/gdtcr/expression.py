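"""Single-cell expression processing.

QC filtering, library-size normalization with log1p transform, batch
location adjustment, Leiden clustering, expression-based Vδ2 labelling,
control-matched gene-set scoring, Wilcoxon rank-sum differential
expression with Benjamini–Hochberg adjustment, and derivation of the
top-k upregulated gene signature.

All operations work on an :class:`anndata.AnnData`; heavy lifting for QC,
normalization, neighbors/PCA/Leiden and gene-set scoring is delegated to
scanpy, while the rank-sum DE is implemented here so that its statistic,
tie-corrected normal p-value and natural-log fold change follow one
pinned convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scanpy as sc
from anndata import AnnData
from scipy import sparse, stats

from gdtcr._errors import ConfigurationError, PipelineError, UndefinedInputError
from gdtcr._stats import bh_adjust

DEFAULT_VD_GENES = [
    "TRDV1",
    "TRDV2",
    "TRDV3",
    "TRAV14DV4",
    "TRAV23DV6",
    "TRAV29DV5",
    "TRAV36DV7",
    "TRAV38-2DV8",
]


@dataclass
class QCThresholds:
    """Cell/gene quality-control thresholds.

    Upper bounds are strict: a cell with exactly ``max_genes`` detected
    genes is removed. ``max_pct_mito`` is a percentage in [0, 100];
    mitochondrial genes are identified by ``mito_prefix``.
    """

    min_genes: int = 200
    min_cells_per_gene: int = 3
    max_genes: int = 4000
    max_counts: int = 20000
    max_pct_mito: float = 10.0
    mito_prefix: str = "MT-"


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sparse.issparse(x) else np.asarray(x)


def qc_filter(
    adata: AnnData, thresholds: QCThresholds | None = None
) -> tuple[AnnData, dict]:
    """Apply QC filtering in a fixed order.

    (1) drop cells with fewer than ``min_genes`` genes, (2) drop genes
    detected in fewer than ``min_cells_per_gene`` cells, (3) drop cells at
    or above any strict upper bound (genes, counts, percent
    mitochondrial). Returns the filtered copy and an audit dict of
    cell/gene counts after each stage.
    """
    th = thresholds or QCThresholds()
    adata = adata.copy()
    audit = {"input": (adata.n_obs, adata.n_vars)}

    sc.pp.filter_cells(adata, min_genes=th.min_genes)
    audit["after_min_genes"] = (adata.n_obs, adata.n_vars)
    sc.pp.filter_genes(adata, min_cells=th.min_cells_per_gene)
    audit["after_min_cells_per_gene"] = (adata.n_obs, adata.n_vars)

    x = _dense(adata.X)
    n_genes = (x > 0).sum(axis=1)
    total = x.sum(axis=1)
    mito = np.array(
        [g.upper().startswith(th.mito_prefix.upper()) for g in adata.var_names]
    )
    pct_mito = 100.0 * x[:, mito].sum(axis=1) / np.maximum(total, 1)
    keep = (n_genes < th.max_genes) & (total < th.max_counts) & (
        pct_mito < th.max_pct_mito
    )
    adata.obs["n_genes"] = n_genes
    adata.obs["total_counts"] = total
    adata.obs["pct_mito"] = pct_mito
    adata = adata[keep].copy()
    audit["after_upper_bounds"] = (adata.n_obs, adata.n_vars)
    if adata.n_obs == 0:
        stage = next(k for k in list(audit)[1:] if audit[k][0] == 0)
        raise PipelineError(f"QC removed all cells at stage {stage}")
    return adata, audit


def normalize_log(adata: AnnData, target_sum: float = 1e4) -> AnnData:
    """Normalize each cell to ``target_sum`` counts, then log1p (base e).

    Raw counts are preserved in ``layers["counts"]``; the log-normalized
    values become ``X``.
    """
    adata = adata.copy()
    totals = _dense(adata.X).sum(axis=1)
    if np.any(totals == 0):
        raise PipelineError("zero-count cell encountered during normalization")
    adata.layers["counts"] = adata.X.copy()
    sc.pp.normalize_total(adata, target_sum=target_sum)
    sc.pp.log1p(adata)
    return adata


def batch_adjust(
    adata: AnnData, batch_key: str = "batch", adjust_scale: bool = False
) -> AnnData:
    """Equalize per-gene batch means on the log layer (location adjustment).

    Each gene's per-batch mean is shifted to the global mean; with
    ``adjust_scale`` the per-batch standard deviations are also equalized.
    A single batch is returned unchanged with a warning.
    """
    adata = adata.copy()
    batches = adata.obs[batch_key].astype(str)
    levels = batches.unique()
    if len(levels) < 2:
        warnings.warn("single batch: batch adjustment is the identity")
        return adata
    x = _dense(adata.X).astype(float)
    grand_mean = x.mean(axis=0)
    for b in levels:
        m = (batches == b).to_numpy()
        mu_b = x[m].mean(axis=0)
        if adjust_scale:
            sd_b = x[m].std(axis=0)
            sd_b[sd_b == 0] = 1.0
            x[m] = (x[m] - mu_b) / sd_b + grand_mean
        else:
            x[m] = x[m] - mu_b + grand_mean
    adata.X = x
    return adata


def cluster_cells(
    adata: AnnData,
    resolution: float = 0.6,
    n_neighbors: int = 15,
    n_pcs: int = 30,
    seed: int = 0,
    n_top_genes: int = 2000,
) -> pd.Series:
    """Leiden clustering: HVG selection → PCA → kNN graph → Leiden.

    Returns integer labels (also stored in ``obs["leiden_cluster"]``);
    deterministic under a fixed seed.
    """
    if adata.n_obs <= n_neighbors:
        raise ConfigurationError(
            f"n_neighbors={n_neighbors} requires more than {n_neighbors} cells"
        )
    work = adata.copy()
    n_pcs = min(n_pcs, work.n_obs - 1, work.n_vars - 1)
    sc.pp.highly_variable_genes(
        work, n_top_genes=min(n_top_genes, work.n_vars), flavor="seurat"
    )
    work = work[:, work.var["highly_variable"]].copy()
    sc.pp.scale(work, max_value=10)
    sc.tl.pca(work, n_comps=n_pcs, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(work, n_neighbors=n_neighbors, n_pcs=n_pcs, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        sc.tl.leiden(
            work,
            resolution=resolution,
            random_state=seed,
            flavor="leidenalg",
            key_added="leiden_cluster",
        )
    labels = work.obs["leiden_cluster"].astype(int)
    adata.obs["leiden_cluster"] = labels.values
    return pd.Series(labels.values, index=adata.obs_names, name="leiden_cluster")


def assign_vd2_labels(
    adata: AnnData, vd_gene_list: list[str] | None = None, layer: str | None = None
) -> pd.Series:
    """Expression-based Vδ2 labels from the most strongly expressed Vδ gene.

    Argmax over the listed Vδ genes: TRDV2 → ``Vd2pos``, any other winner
    → ``Vd2neg``; cells with all-zero Vδ expression, or a tie for the
    maximum, are ``unassigned``.
    """
    genes = vd_gene_list or DEFAULT_VD_GENES
    present = [g for g in genes if g in adata.var_names]
    if not present:
        raise ConfigurationError("none of the Vδ genes are present in the matrix")
    x = _dense(adata[:, present].layers[layer] if layer else adata[:, present].X)
    top = x.max(axis=1)
    n_at_max = (x == top[:, None]).sum(axis=1)
    argmax = x.argmax(axis=1)
    winner = np.array(present, dtype=object)[argmax]
    labels = np.where(winner == "TRDV2", "Vd2pos", "Vd2neg")
    labels = np.where((top <= 0) | (n_at_max > 1), "unassigned", labels)
    out = pd.Series(labels, index=adata.obs_names, name="vd2_status")
    adata.obs["vd2_status"] = out
    return out


def gene_set_score(
    adata: AnnData,
    gene_set: list[str],
    n_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
) -> pd.Series:
    """Control-matched gene-set score per cell.

    Mean expression of the set minus the mean of a control set sampled
    from expression-magnitude bins matched to the set genes (scanpy's
    ``score_genes``). The overlap of the set with the matrix is reported;
    an empty overlap is an error. Fixed seed → reproducible scores.
    """
    overlap = [g for g in gene_set if g in adata.var_names]
    if not overlap:
        raise UndefinedInputError("gene set has empty overlap with the matrix")
    if len(overlap) < len(gene_set):
        warnings.warn(
            f"gene set overlap {len(overlap)}/{len(gene_set)} genes"
        )
    work = adata.copy()
    sc.tl.score_genes(
        work,
        overlap,
        ctrl_size=ctrl_size,
        n_bins=n_bins,
        score_name="_score",
        random_state=seed,
    )
    score = pd.Series(
        work.obs["_score"].to_numpy(), index=adata.obs_names, name="gene_set_score"
    )
    return score


def wilcoxon_de(
    adata: AnnData,
    target_mask,
    reference_mask,
    layer: str | None = None,
    logfc_clip: float = 7.0,
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum DE, target vs reference.

    The p-value uses the normal approximation with tie correction; BH
    adjustment is applied across genes. The log fold change is
    ``log(mean(expm1 target) + ε) − log(mean(expm1 reference) + ε)``
    (natural log, on the log1p-normalized layer). ``logfc_display`` clips
    to ±``logfc_clip`` for plotting; ranking always uses the unclipped
    value.
    """
    target_mask = np.asarray(target_mask, dtype=bool)
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if target_mask.sum() == 0 or reference_mask.sum() == 0:
        raise UndefinedInputError("DE groups must be non-empty")
    if np.any(target_mask & reference_mask):
        raise UndefinedInputError("DE groups must be disjoint")

    x = _dense(adata.layers[layer] if layer else adata.X).astype(float)
    xt, xr = x[target_mask], x[reference_mask]
    n1, n2 = len(xt), len(xr)

    ranks = np.apply_along_axis(stats.rankdata, 0, np.vstack([xt, xr]))
    r1 = ranks[:n1].sum(axis=0)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    # tie correction per gene
    tie_term = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        _, counts = np.unique(np.concatenate([xt[:, j], xr[:, j]]), return_counts=True)
        tie_term[j] = np.sum(counts**3 - counts)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u1 - mu) / np.sqrt(sigma2)
    z = np.nan_to_num(z, nan=0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    padj = bh_adjust(pvals)

    logfc = np.log(np.expm1(xt).mean(axis=0) + eps) - np.log(
        np.expm1(xr).mean(axis=0) + eps
    )
    de = pd.DataFrame(
        dict(
            gene=list(adata.var_names),
            statistic=u1,
            z=z,
            pval=pvals,
            padj=padj,
            logfc=logfc,
            logfc_display=np.clip(logfc, -logfc_clip, logfc_clip),
            direction=np.where(z > 0, "up", np.where(z < 0, "down", "flat")),
        )
    )
    return de


@dataclass
class GeneSignature:
    """An ordered gene list with the DE statistics that produced it."""

    genes: list[str]
    contrast: str = ""
    table: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {"genes": self.genes, "contrast": self.contrast}
        if self.table is not None:
            d["stats"] = self.table.to_dict(orient="records")
        return d


def derive_signature(
    de: pd.DataFrame, k: int = 20, contrast: str = ""
) -> GeneSignature:
    """Top-k upregulated genes by ascending raw p-value.

    Ties in p break by larger log fold change, then gene name, so the
    result is deterministic under input permutation. Fewer than k
    upregulated genes returns all of them with a warning.
    """
    up = de[de["direction"] == "up"].copy()
    up = up.sort_values(
        ["pval", "logfc", "gene"], ascending=[True, False, True], kind="mergesort"
    )
    if len(up) < k:
        warnings.warn(
            f"only {len(up)} upregulated genes available (requested {k})"
        )
    top = up.head(k)
    return GeneSignature(
        genes=top["gene"].tolist(), contrast=contrast, table=top.reset_index(drop=True)
    )
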