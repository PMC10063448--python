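"""Clonotype calling, expansion labelling, chain usage and diversity.

A clonotype is the set of cells within one sample sharing the identical
concatenated γ+δ full nucleotide sequence. A cell is "expanded" when at
least one other cell in the same sample shares its clonotype key, else a
"singleton". Repertoire diversity is quantified by the Gini coefficient
of the clone-size distribution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from gdtcr._errors import UndefinedInputError
from gdtcr._stats import signed_rank_test

VD2_GENE = "TRDV2"


def _vd2_status(vd_gene: str) -> str:
    return "Vd2pos" if vd_gene.upper().replace("/", "") == VD2_GENE else "Vd2neg"


def call_clonotypes(paired: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign per-sample clonotype keys to paired cells.

    The key is the γ full nucleotide sequence concatenated with the δ full
    nucleotide sequence; keys are scoped per sample (identical keys in
    different samples are distinct clonotypes). Cells with an empty γ or δ
    sequence are dropped with an audit reason.

    Returns ``(cells, audit)`` where ``cells`` has one row per cell with
    sample_id, barcode, vd_gene, vd2_status, cdr3_aa (δ chain),
    clonotype_key and clone_size.
    """
    g_seq = paired["gamma_sequence_nt"].astype(str)
    d_seq = paired["delta_sequence_nt"].astype(str)
    empty = (g_seq == "") | (d_seq == "")
    audit = pd.DataFrame(
        dict(
            sample_id=paired.loc[empty, "sample_id"],
            barcode=paired.loc[empty, "barcode"],
            reasons="empty_sequence",
        )
    ).reset_index(drop=True)

    kept = paired.loc[~empty]
    cells = pd.DataFrame(
        dict(
            sample_id=kept["sample_id"],
            barcode=kept["barcode"],
            vd_gene=kept["delta_v_gene"],
            vd2_status=kept["delta_v_gene"].map(_vd2_status),
            cdr3_aa=kept["delta_cdr3_aa"],
            clonotype_key=g_seq[~empty] + d_seq[~empty],
        )
    ).reset_index(drop=True)
    sizes = cells.groupby(["sample_id", "clonotype_key"])["barcode"].transform("size")
    cells["clone_size"] = sizes.astype(int)
    return cells, audit


def label_expansion(cells: pd.DataFrame) -> pd.DataFrame:
    """Label each cell expanded/singleton by the ≥2-cells-per-sample rule."""
    out = cells.copy()
    if "clone_size" not in out.columns:
        out["clone_size"] = out.groupby(["sample_id", "clonotype_key"])[
            "barcode"
        ].transform("size")
    out["expansion"] = np.where(out["clone_size"] >= 2, "expanded", "singleton")
    return out


def expansion_summary(cells: pd.DataFrame, group_by: str) -> pd.DataFrame:
    """Expanded/singleton percentages per group.

    ``group_by`` is typically ``vd2_status``, ``vd_gene`` or
    ``phenotype_cluster``. Empty groups are omitted. Percentages are of
    cells, not clones; a clone-level summary is available via
    :func:`clone_summary`.
    """
    if "expansion" not in cells.columns:
        cells = label_expansion(cells)
    rows = []
    for group, sub in cells.groupby(group_by, observed=True):
        n = len(sub)
        n_exp = int((sub["expansion"] == "expanded").sum())
        rows.append(
            dict(
                group=group,
                n_cells=n,
                n_expanded=n_exp,
                expanded_pct=100.0 * n_exp / n,
                singleton_pct=100.0 * (n - n_exp) / n,
            )
        )
    return pd.DataFrame(rows)


def clone_summary(cells: pd.DataFrame) -> pd.DataFrame:
    """One row per clonotype: sample, key, size, δ V gene."""
    if "expansion" not in cells.columns:
        cells = label_expansion(cells)
    return (
        cells.groupby(["sample_id", "clonotype_key"], sort=True)
        .agg(
            clone_size=("barcode", "size"),
            vd_gene=("vd_gene", "first"),
            expansion=("expansion", "first"),
        )
        .reset_index()
    )


def chain_usage_table(
    cells: pd.DataFrame | None = None,
    counts: dict[str, int] | None = None,
    decimals: int = 1,
) -> pd.DataFrame:
    """Per-δ-chain usage: overall % and % within the Vδ2⁻ subset.

    Accepts either a labelled cell table (uses ``vd_gene``) or an explicit
    ``counts`` mapping of δ V gene → cell count. The within-Vδ2⁻ share is
    computed from counts, which is arithmetically identical to dividing
    the overall share by the Vδ2⁻ overall fraction. Reported percentages
    are rounded to ``decimals``; unrounded columns are also included.
    """
    if counts is None:
        if cells is None:
            raise UndefinedInputError("provide either cells or counts")
        counts = cells["vd_gene"].value_counts().to_dict()
    total = sum(counts.values())
    if total == 0:
        raise UndefinedInputError("empty repertoire")
    vd2neg_total = sum(
        c for g, c in counts.items() if _vd2_status(g) == "Vd2neg"
    )
    rows = []
    for gene in sorted(counts, key=lambda g: -counts[g]):
        c = counts[gene]
        is_neg = _vd2_status(gene) == "Vd2neg"
        within = 100.0 * c / vd2neg_total if (is_neg and vd2neg_total) else np.nan
        rows.append(
            dict(
                vd_gene=gene,
                count=c,
                overall_pct_exact=100.0 * c / total,
                overall_pct=round(100.0 * c / total, decimals),
                vd2neg_count=c if is_neg else 0,
                within_vd2neg_pct_exact=within,
                within_vd2neg_pct=round(within, decimals) if is_neg and vd2neg_total
                else np.nan,
            )
        )
    return pd.DataFrame(rows)


def gini_coefficient(clone_sizes) -> float:
    """Gini coefficient of a clone-size distribution.

    Uses the pairwise mean-absolute-difference definition
    ``G = Σ_i Σ_j |x_i − x_j| / (2 n² μ)`` with no small-sample
    correction: 0 for a perfectly even repertoire, < 1 always.
    """
    x = np.asarray(list(clone_sizes), dtype=float)
    if x.size == 0:
        raise UndefinedInputError("Gini coefficient of an empty repertoire")
    if np.any(x <= 0):
        raise UndefinedInputError("clone sizes must be positive")
    n = x.size
    xs = np.sort(x)
    # Σ_i Σ_j |x_i - x_j| = 2 Σ_i (2i - n + 1) x_(i)  for 0-based sorted x
    i = np.arange(n)
    total_abs_diff = 2.0 * np.sum((2 * i - n + 1) * xs)
    return float(total_abs_diff / (2.0 * n * n * xs.mean()))


def compare_gini(group_a, group_b) -> dict:
    """Wilcoxon signed-rank comparison of paired Gini coefficients.

    Exact two-sided p for n ≤ 25 tie-free pairs, normal approximation with
    continuity correction otherwise; identical vectors give p = 1.
    """
    stat, p = signed_rank_test(group_a, group_b)
    return dict(statistic=stat, pvalue=p, n=len(list(group_a)))
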