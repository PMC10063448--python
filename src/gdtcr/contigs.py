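"""V(D)J contig table ingestion, productive filtering and γ/δ pairing.

The normalized contig table is a pandas DataFrame with columns

    sample_id, barcode, contig_id, chain, v_gene, d_gene, j_gene, c_gene,
    full_length, productive, cdr3_aa, cdr3_nt, sequence_nt, umis, reads

where ``chain`` is one of TRG/TRD/TRA/TRB/other and ``productive`` is
True/False/None (None = unknown, to be re-evaluated by rules).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from gdtcr._errors import FormatError

NORMALIZED_COLUMNS = [
    "sample_id",
    "barcode",
    "contig_id",
    "chain",
    "v_gene",
    "d_gene",
    "j_gene",
    "c_gene",
    "full_length",
    "productive",
    "cdr3_aa",
    "cdr3_nt",
    "sequence_nt",
    "umis",
    "reads",
]

_TENX_REQUIRED = [
    "barcode", "contig_id", "chain", "v_gene", "d_gene", "j_gene", "c_gene",
    "full_length", "productive", "cdr3", "cdr3_nt", "umis", "reads",
]
_AIRR_REQUIRED = [
    "cell_id", "sequence_id", "locus", "v_call", "j_call",
    "productive", "junction", "junction_aa", "duplicate_count",
]

_TRUE_STRINGS = {"true", "t", "yes", "1"}
_FALSE_STRINGS = {"false", "f", "no", "0"}

#: Hybrid Vα/Vδ gene segments usable in both α and δ rearrangements.
DEFAULT_HYBRID_GENES = frozenset(
    {"TRAV14DV4", "TRAV23DV6", "TRAV29DV5", "TRAV36DV7", "TRAV38-2DV8"}
)


def _parse_flag(value) -> bool | None:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    return None


def _flag_column(series: pd.Series) -> pd.Series:
    # object dtype keeps python True/False/None (identity-comparable)
    return pd.Series(
        [_parse_flag(v) for v in series], index=series.index, dtype=object
    )


def _clean_str(series: pd.Series) -> pd.Series:
    out = series.astype("string").fillna("")
    return out.replace({"None": "", "none": "", "nan": "", "NA": ""}).astype(str)


def _chain_enum(series: pd.Series) -> pd.Series:
    known = {"TRG", "TRD", "TRA", "TRB"}
    s = series.astype(str).str.upper().str.strip()
    return s.where(s.isin(known), "other")


def read_contigs(path, dialect: str, sample_id: str | None = None) -> pd.DataFrame:
    """Read a contig annotation file into the normalized table.

    Parameters
    ----------
    path
        CSV (``dialect="tenx_csv"``, 10x ``all_contig_annotations.csv``
    layout) or TSV (``dialect="airr_tsv"``, AIRR rearrangement schema).
    dialect
        ``"tenx_csv"`` or ``"airr_tsv"``.
    sample_id
        Sample identifier attached to every record; defaults to an existing
        ``sample_id`` column, else the file stem.

    Truth-valued columns accept dialect spellings ("True"/"true"/"T"/"F"/…);
    anything unrecognized (e.g. "None") becomes unknown (None). Missing
    gene calls map to the empty string.
    """
    from pathlib import Path

    path = Path(path)
    if dialect == "tenx_csv":
        sep, required = ",", _TENX_REQUIRED
    elif dialect == "airr_tsv":
        sep, required = "\t", _AIRR_REQUIRED
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty contig file")
        return pd.DataFrame(columns=NORMALIZED_COLUMNS)

    if raw.empty and len(raw.columns) <= 1:
        warnings.warn(f"{path}: empty contig file")
        return pd.DataFrame(columns=NORMALIZED_COLUMNS)

    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s) {', '.join(missing)} "
            f"for dialect {dialect}"
        )

    if sample_id is None:
        sample_id = (
            raw["sample_id"].iloc[0] if "sample_id" in raw.columns and len(raw)
            else path.stem
        )

    if dialect == "tenx_csv":
        table = pd.DataFrame(
            dict(
                sample_id=sample_id,
                barcode=raw["barcode"],
                contig_id=raw["contig_id"],
                chain=_chain_enum(raw["chain"]),
                v_gene=_clean_str(raw["v_gene"]),
                d_gene=_clean_str(raw["d_gene"]),
                j_gene=_clean_str(raw["j_gene"]),
                c_gene=_clean_str(raw["c_gene"]),
                full_length=_flag_column(raw["full_length"]),
                productive=_flag_column(raw["productive"]),
                cdr3_aa=_clean_str(raw["cdr3"]),
                cdr3_nt=_clean_str(raw["cdr3_nt"]),
                sequence_nt=_clean_str(raw["sequence"]) if "sequence" in raw.columns
                else "",
                umis=pd.to_numeric(raw["umis"]).astype(int),
                reads=pd.to_numeric(raw["reads"]).astype(int),
            )
        )
    else:
        table = pd.DataFrame(
            dict(
                sample_id=sample_id,
                barcode=raw["cell_id"],
                contig_id=raw["sequence_id"],
                chain=_chain_enum(raw["locus"]),
                v_gene=_clean_str(raw["v_call"]),
                d_gene=_clean_str(raw["d_call"]) if "d_call" in raw.columns else "",
                j_gene=_clean_str(raw["j_call"]),
                c_gene=_clean_str(raw["c_call"]) if "c_call" in raw.columns else "",
                full_length=_flag_column(raw["complete_vdj"])
                if "complete_vdj" in raw.columns
                else None,
                productive=_flag_column(raw["productive"]),
                cdr3_aa=_clean_str(raw["junction_aa"]),
                cdr3_nt=_clean_str(raw["junction"]),
                sequence_nt=_clean_str(raw["sequence"]) if "sequence" in raw.columns
                else "",
                umis=pd.to_numeric(raw["duplicate_count"]).astype(int),
                reads=pd.to_numeric(raw["consensus_count"]).astype(int)
                if "consensus_count" in raw.columns
                else pd.to_numeric(raw["duplicate_count"]).astype(int),
            )
        )
    if (table["umis"] < 0).any() or (table["reads"] < 0).any():
        raise FormatError(f"{path}: negative UMI or read counts")
    return table[NORMALIZED_COLUMNS]


# ---------------------------------------------------------------------------
# productive filtering


@dataclass
class ProductiveRules:
    """Six independent conditions a contig must satisfy to be productive:
    full-length span, initiator codon at the expected position, CDR3
    detected, in-frame V–J junction, no internal stop codon, and V/J calls
    from a consistent locus.

    When ``trust_flag`` is true (default) a record whose productive flag is
    already True/False short-circuits rule evaluation; records with unknown
    flags are always evaluated against the rules.
    """

    require_full_length: bool = True
    require_start_codon: bool = True
    require_cdr3: bool = True
    require_in_frame: bool = True
    forbid_internal_stop: bool = True
    require_consistent_locus: bool = True
    trust_flag: bool = True


def _gene_locus(gene: str) -> str:
    """Locus prefix of a gene call; hybrid Vα/Vδ segments are ambiguous."""
    g = gene.upper().replace("/", "")
    if not g:
        return ""
    if g.startswith("TRAV") and "DV" in g:
        return "TRA/TRD"
    return g[:3]


def _loci_consistent(v_gene: str, j_gene: str) -> bool:
    lv, lj = _gene_locus(v_gene), _gene_locus(j_gene)
    if not lv or not lj:
        return False
    return lj in lv.split("/") or lv in lj.split("/") or lv == lj


def _has_internal_stop(row) -> bool:
    if row.cdr3_aa and "*" in row.cdr3_aa:
        return True
    seq = row.sequence_nt
    if seq and len(seq) >= 3:
        trimmed = seq[: len(seq) - len(seq) % 3]
        aa = str(Seq(trimmed).translate())
        if "*" in aa.rstrip("*"):
            return True
    nt = row.cdr3_nt
    if nt and len(nt) % 3 == 0 and "*" in str(Seq(nt).translate()):
        return True
    return False


def _rule_failures(row, rules: ProductiveRules) -> list[str]:
    reasons = []
    if rules.require_full_length and row.full_length is not True:
        reasons.append("not_full_length")
    if rules.require_start_codon and not str(row.sequence_nt).startswith("ATG"):
        reasons.append("no_start_codon")
    if rules.require_cdr3 and not (row.cdr3_aa or row.cdr3_nt):
        reasons.append("no_cdr3")
    if rules.require_in_frame and row.cdr3_nt and len(row.cdr3_nt) % 3 != 0:
        reasons.append("out_of_frame")
    if rules.forbid_internal_stop and _has_internal_stop(row):
        reasons.append("internal_stop")
    if rules.require_consistent_locus and not _loci_consistent(row.v_gene, row.j_gene):
        reasons.append("inconsistent_locus")
    return reasons


def filter_productive(
    table: pd.DataFrame, rules: ProductiveRules | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep only productive contigs.

    Returns ``(kept, audit)``; ``audit`` has one row per excluded contig
    with a semicolon-joined reason code list.
    """
    rules = rules or ProductiveRules()
    keep_idx = []
    audit_rows = []
    for row in table.itertuples():
        if rules.trust_flag and row.productive is True:
            keep_idx.append(row.Index)
            continue
        if rules.trust_flag and row.productive is False:
            audit_rows.append(
                dict(sample_id=row.sample_id, contig_id=row.contig_id,
                     reasons="flagged_unproductive")
            )
            continue
        reasons = _rule_failures(row, rules)
        if reasons:
            audit_rows.append(
                dict(sample_id=row.sample_id, contig_id=row.contig_id,
                     reasons=";".join(reasons))
            )
        else:
            keep_idx.append(row.Index)
    kept = table.loc[keep_idx].copy()
    audit = pd.DataFrame(audit_rows, columns=["sample_id", "contig_id", "reasons"])
    return kept, audit


# ---------------------------------------------------------------------------
# hybrid delta reassignment


def _canon_gene(gene: str) -> str:
    return gene.upper().replace("/", "")


def reassign_hybrid_delta(
    table: pd.DataFrame, hybrid_genes: frozenset | set | None = None
) -> pd.DataFrame:
    """Relabel hybrid Vα/Vδ contigs as delta-chain contigs.

    A contig whose V gene is a hybrid segment (e.g. TRAV29DV5, matched
    case-insensitively and tolerant of "TRAV29/DV5" spellings) has its
    chain set to TRD when its D, J and C gene calls are all TRD-locus
    genes. Only the ``chain`` column ever changes.
    """
    hybrids = {_canon_gene(g) for g in (hybrid_genes or DEFAULT_HYBRID_GENES)}
    out = table.copy()
    v = out["v_gene"].map(_canon_gene)
    is_hybrid = v.isin(hybrids)
    all_delta = (
        out["d_gene"].str.upper().str.startswith("TRD")
        & out["j_gene"].str.upper().str.startswith("TRD")
        & out["c_gene"].str.upper().str.startswith("TRD")
    )
    out.loc[is_hybrid & all_delta, "chain"] = "TRD"
    return out


# ---------------------------------------------------------------------------
# per-cell chain selection and pairing


def select_cell_chains(table: pd.DataFrame, policy: str = "umi") -> pd.DataFrame:
    """Keep at most one TRG and one TRD contig per (sample, barcode).

    The default policy keeps the highest-UMI contig; ties break by read
    count, then lexicographically smallest contig_id, so the result does
    not depend on input row order.
    """
    if policy != "umi":
        raise ValueError(f"unknown chain-selection policy {policy!r}")
    gd = table[table["chain"].isin(["TRG", "TRD"])]
    ordered = gd.sort_values(
        ["sample_id", "barcode", "chain", "umis", "reads", "contig_id"],
        ascending=[True, True, True, False, False, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates(
        subset=["sample_id", "barcode", "chain"], keep="first"
    )


def pair_cells(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair γ with δ contigs by shared (sample_id, barcode).

    Returns ``(paired, orphans)``. ``paired`` carries ``gamma_*`` and
    ``delta_*`` column blocks; ``orphans`` lists cells with only one chain.
    """
    gam = table[table["chain"] == "TRG"].add_prefix("gamma_").rename(
        columns={"gamma_sample_id": "sample_id", "gamma_barcode": "barcode"}
    )
    dlt = table[table["chain"] == "TRD"].add_prefix("delta_").rename(
        columns={"delta_sample_id": "sample_id", "delta_barcode": "barcode"}
    )
    paired = gam.merge(dlt, on=["sample_id", "barcode"], how="inner")
    paired = paired.sort_values(["sample_id", "barcode"]).reset_index(drop=True)

    outer = gam.merge(
        dlt, on=["sample_id", "barcode"], how="outer", indicator=True
    )
    orphan_mask = outer["_merge"] != "both"
    orphans = pd.DataFrame(
        dict(
            sample_id=outer.loc[orphan_mask, "sample_id"],
            barcode=outer.loc[orphan_mask, "barcode"],
            missing_chain=outer.loc[orphan_mask, "_merge"].map(
                {"left_only": "TRD", "right_only": "TRG"}
            ),
        )
    ).sort_values(["sample_id", "barcode"]).reset_index(drop=True)
    return paired, orphans
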