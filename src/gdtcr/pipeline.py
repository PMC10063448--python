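"""End-to-end pipeline orchestration.

Runs the stages (contig processing → clonotypes → networks → expression →
signature → cohort) from a single YAML-style config with one global seed,
writing per-stage TSV/JSON artifacts plus a deterministic manifest of
input hashes and parameters. ``demo=True`` generates all inputs with the
synthetic-data module: a multi-patient γδ repertoire whose cells also get
a simulated expression profile (with the true Vδ transcript planted per
cell), pooled with simulated αβ CD4/CD8 reference cells for the signature
contrast, and a bulk cohort driven by the derived signature.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from gdtcr import __version__
from gdtcr._errors import ConfigurationError, PipelineError
from gdtcr.clonotypes import (
    call_clonotypes,
    chain_usage_table,
    clone_summary,
    expansion_summary,
    gini_coefficient,
    label_expansion,
)
from gdtcr.cohort import response_association, sample_signature_score, survival_analysis
from gdtcr.contigs import (
    filter_productive,
    pair_cells,
    read_contigs,
    reassign_hybrid_delta,
    select_cell_chains,
)
from gdtcr.expression import (
    DEFAULT_VD_GENES,
    QCThresholds,
    assign_vd2_labels,
    cluster_cells,
    derive_signature,
    gene_set_score,
    normalize_log,
    qc_filter,
    wilcoxon_de,
)
from gdtcr.network import build_networks, network_stats_table
from gdtcr.simulate import (
    CohortSimConfig,
    ExpressionSimConfig,
    RepertoireSimConfig,
    simulate_cohort,
    simulate_expression,
    simulate_repertoire,
    write_contigs_10x,
)

# per-stage seed offsets fanned out from the single global seed
_SEED_REPERTOIRE = 101
_SEED_EXPRESSION = 202
_SEED_COHORT = 303
_SEED_SCORE = 404

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "repertoire": {
        "n_patients": 3,
        "n_cells_per_patient": 150,
        "frac_unproductive": 0.05,
        "frac_orphan_gamma": 0.03,
        "frac_orphan_delta": 0.03,
        "power_law_exponent": 2.0,
    },
    "expression": {
        "n_ab_cells": 1550,
        "n_genes": 600,
        "n_clusters": 4,
        "resolution": 0.6,
        "n_neighbors": 15,
        "n_pcs": 30,
        "signature_effect": 1.5,
        "n_signature_genes": 25,
    },
    "network": {"threshold": 0},
    "signature": {"k": 20},
    "cohort": {
        "n_samples": 150,
        "hazard_ratio_per_sd": 2.5,
        "response_logit_slope": 1.0,
        "censor_rate": 0.2,
    },
    "inputs": {},
}

_KNOWN_KEYS = set(DEFAULT_CONFIG)


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return merge_config(cfg)


def merge_config(overrides: dict) -> dict:
    """Overlay user config on the defaults, rejecting unknown keys."""
    unknown = set(overrides) - _KNOWN_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in overrides.items():
        if isinstance(v, dict):
            bad = set(v) - set(DEFAULT_CONFIG[k]) if isinstance(DEFAULT_CONFIG[k], dict) else set()
            if bad and k != "inputs":
                raise ConfigurationError(
                    f"unknown config key(s) under {k}: {', '.join(sorted(bad))}"
                )
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _plant_vd_expression(
    counts: pd.DataFrame, vd_by_cell: pd.Series, rng: np.random.Generator
) -> pd.DataFrame:
    """Overwrite Vδ transcript counts so each cell expresses its true Vδ
    gene (and only it); cells absent from ``vd_by_cell`` (αβ cells) get
    zero Vδ expression."""
    counts = counts.copy()
    for g in DEFAULT_VD_GENES:
        if g in counts.columns:
            counts[g] = 0
    gd = [c for c in vd_by_cell.index if c in counts.index]
    for cell in gd:
        counts.loc[cell, vd_by_cell[cell]] = int(rng.integers(5, 20))
    return counts


def _demo_repertoire(cfg: dict, seed: int, outdir: Path):
    rep_cfg = cfg["repertoire"]
    tables, truths = [], []
    for i in range(rep_cfg["n_patients"]):
        c = RepertoireSimConfig(
            n_cells=rep_cfg["n_cells_per_patient"],
            power_law_exponent=rep_cfg["power_law_exponent"],
            frac_unproductive=rep_cfg["frac_unproductive"],
            frac_orphan_gamma=rep_cfg["frac_orphan_gamma"],
            frac_orphan_delta=rep_cfg["frac_orphan_delta"],
            sample_id=f"patient{i + 1}",
            seed=seed + _SEED_REPERTOIRE + i,
        )
        contigs, truth = simulate_repertoire(c)
        path = outdir / f"contigs_{c.sample_id}.csv"
        write_contigs_10x(contigs, path)
        tables.append(read_contigs(path, "tenx_csv", sample_id=c.sample_id))
        truths.append(truth)
    return pd.concat(tables, ignore_index=True), pd.concat(truths, ignore_index=True)


def run_pipeline(
    config: dict | None = None, outdir: str | Path = "gdtcr_out", demo: bool = False
) -> dict:
    """Run all stages and write artifacts plus a manifest.

    Without ``demo``, ``config["inputs"]`` must name the contig files
    (``contigs``: list of {path, dialect, sample_id}) and optionally a
    cohort TSV; with ``demo`` every input is generated synthetically at
    the configured scale. Returns the manifest dict (also written to
    ``manifest.json``).
    """
    cfg = merge_config(config or {})
    seed = int(cfg["seed"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"

    try:
        # ---- stage: contigs ------------------------------------------------
        stage = "contigs"
        if demo:
            contigs, truth = _demo_repertoire(cfg, seed, outdir)
        else:
            specs = cfg["inputs"].get("contigs")
            if not specs:
                raise ConfigurationError(
                    "inputs.contigs is required when not running with --demo"
                )
            contigs = pd.concat(
                [
                    read_contigs(s["path"], s.get("dialect", "tenx_csv"),
                                 sample_id=s.get("sample_id"))
                    for s in specs
                ],
                ignore_index=True,
            )
            truth = None

        productive, audit = filter_productive(contigs)
        audit.to_csv(outdir / "contig_exclusions.tsv", sep="\t", index=False)
        reassigned = reassign_hybrid_delta(productive)
        selected = select_cell_chains(reassigned)
        paired, orphans = pair_cells(selected)
        paired.to_csv(outdir / "paired_cells.tsv", sep="\t", index=False)
        orphans.to_csv(outdir / "orphan_cells.tsv", sep="\t", index=False)

        # ---- stage: clonotypes --------------------------------------------
        stage = "clonotypes"
        cells, clono_audit = call_clonotypes(paired)
        cells = label_expansion(cells)
        usage = chain_usage_table(cells)
        usage.to_csv(outdir / "chain_usage.tsv", sep="\t", index=False)
        gini_rows = [
            dict(
                sample_id=s,
                gini=gini_coefficient(
                    clone_summary(sub)["clone_size"].tolist()
                ),
            )
            for s, sub in cells.groupby("sample_id")
        ]
        pd.DataFrame(gini_rows).to_csv(outdir / "gini.tsv", sep="\t", index=False)

        # ---- stage: expression --------------------------------------------
        stage = "expression"
        expr_cfg = cfg["expression"]
        sig_genes_planted = [f"SIG{i:03d}" for i in range(expr_cfg["n_signature_genes"])]
        if demo:
            n_gd = len(cells)
            n_ab = expr_cfg["n_ab_cells"]
            e_cfg = ExpressionSimConfig(
                n_cells=n_gd + n_ab,
                n_genes=expr_cfg["n_genes"],
                n_clusters=expr_cfg["n_clusters"],
                planted_signature_genes=sig_genes_planted,
                signature_effect=0.0,  # planted below, keyed on lineage
                vd_marker_genes={g: 0 for g in DEFAULT_VD_GENES},
                seed=seed + _SEED_EXPRESSION,
            )
            counts, meta = simulate_expression(e_cfg)
            rng = np.random.default_rng(seed + _SEED_EXPRESSION + 1)
            # γδ cells take the repertoire barcodes; the rest are αβ cells
            new_index = list(cells["barcode"]) + [
                f"AB{i:05d}" for i in range(n_ab)
            ]
            counts.index = new_index
            meta.index = new_index
            meta["lineage"] = ["gd"] * n_gd + [
                "CD4" if i % 2 == 0 else "CD8" for i in range(n_ab)
            ]
            counts = _plant_vd_expression(
                counts, cells.set_index("barcode")["vd_gene"], rng
            )
            # plant the signature shift in Vδ2− γδ cells
            vd2neg = cells.loc[cells["vd2_status"] == "Vd2neg", "barcode"]
            boost = np.exp(expr_cfg["signature_effect"])
            block = counts.loc[vd2neg, sig_genes_planted].to_numpy()
            counts.loc[vd2neg, sig_genes_planted] = rng.poisson(
                np.maximum(block, 0.5) * boost
            )
            adata = ad.AnnData(
                counts.to_numpy(dtype=float),
                obs=meta.loc[counts.index].copy(),
                var=pd.DataFrame(index=counts.columns),
            )
            adata.obs_names = counts.index
        else:
            counts_dir = cfg["inputs"].get("counts_dir")
            meta_path = cfg["inputs"].get("meta")
            if not counts_dir or not meta_path:
                raise ConfigurationError(
                    "inputs.counts_dir and inputs.meta are required when not "
                    "running with --demo"
                )
            from gdtcr.simulate import read_counts_mtx

            counts = read_counts_mtx(counts_dir)
            meta = pd.read_csv(meta_path, sep="\t", index_col=0)
            adata = ad.AnnData(
                counts.to_numpy(dtype=float),
                obs=meta.loc[counts.index].copy(),
                var=pd.DataFrame(index=counts.columns),
            )
            adata.obs_names = counts.index

        adata, qc_audit = qc_filter(adata, QCThresholds())
        adata = normalize_log(adata)
        leiden = cluster_cells(
            adata,
            resolution=expr_cfg["resolution"],
            n_neighbors=expr_cfg["n_neighbors"],
            n_pcs=expr_cfg["n_pcs"],
            seed=seed,
        )
        vd2 = assign_vd2_labels(adata, layer="counts")

        # ---- stage: signature ---------------------------------------------
        stage = "signature"
        lineage = adata.obs.get("lineage", pd.Series("gd", index=adata.obs_names))
        is_gd = (lineage == "gd").to_numpy()
        target = is_gd & (vd2 == "Vd2neg").to_numpy()
        reference = ~target & (
            (~is_gd) | (vd2 == "Vd2pos").to_numpy()
        )
        de = wilcoxon_de(adata, target, reference)
        de.to_csv(outdir / "de_table.tsv", sep="\t", index=False)
        signature = derive_signature(
            de, k=cfg["signature"]["k"],
            contrast="Vd2neg gd vs pooled Vd2pos gd + CD4 + CD8",
        )
        with open(outdir / "signature.json", "w") as fh:
            json.dump(signature.to_dict(), fh, indent=2, sort_keys=True)
        score = gene_set_score(adata, signature.genes, seed=seed + _SEED_SCORE)
        cell_table = adata.obs.copy()
        cell_table["vd2_status"] = vd2
        cell_table["signature_score"] = score
        cell_table.to_csv(outdir / "cell_table.tsv", sep="\t")

        # ---- stage: network -----------------------------------------------
        stage = "network"
        net_cells = cells.merge(
            leiden.rename("phenotype_cluster"),
            left_on="barcode",
            right_index=True,
            how="left",
        )
        nets = build_networks(net_cells, threshold=cfg["network"]["threshold"])
        stats_table = network_stats_table(nets)
        stats_table.to_csv(outdir / "network_stats.tsv", sep="\t", index=False)
        for pid, net in nets.items():
            net.edge_list().to_csv(
                outdir / f"network_edges_{pid}.tsv", sep="\t", index=False
            )

        # ---- stage: cohort -------------------------------------------------
        stage = "cohort"
        co_cfg = cfg["cohort"]
        if demo:
            cohort = simulate_cohort(
                CohortSimConfig(
                    n_samples=co_cfg["n_samples"],
                    signature_genes=signature.genes,
                    hazard_ratio_per_sd=co_cfg["hazard_ratio_per_sd"],
                    response_logit_slope=co_cfg["response_logit_slope"],
                    censor_rate=co_cfg["censor_rate"],
                    seed=seed + _SEED_COHORT,
                )
            )
        else:
            cohort_path = cfg["inputs"].get("cohort")
            if not cohort_path:
                raise ConfigurationError(
                    "inputs.cohort is required when not running with --demo"
                )
            from gdtcr.simulate import read_cohort_tsv

            cohort = read_cohort_tsv(cohort_path)
        sample_scores = sample_signature_score(cohort, signature.genes)
        sample_scores.to_frame().to_csv(outdir / "cohort_scores.tsv", sep="\t")
        surv = survival_analysis(cohort, sample_scores)
        resp = response_association(sample_scores, cohort["response"])
        results = dict(
            logrank=surv["logrank"],
            response=resp,
            n_samples=int(len(cohort)),
        )
        with open(outdir / "cohort_results.json", "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True)
    except ConfigurationError:
        raise
    except Exception as exc:  # noqa: BLE001 - attribute failures to a stage
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ---- manifest ----------------------------------------------------------
    artifacts = sorted(
        p.name for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = dict(
        version=__version__,
        seed=seed,
        demo=demo,
        parameters={k: v for k, v in cfg.items() if k != "inputs"},
        qc_audit={k: list(v) for k, v in qc_audit.items()},
        files={name: _sha256(outdir / name) for name in artifacts},
    )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
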