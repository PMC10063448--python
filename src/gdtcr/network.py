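"""Per-patient CDR3 similarity networks over cells.

Cells (nodes) are connected when the Levenshtein distance between their
delta-chain CDR3 amino-acid sequences is at most a threshold; the default
threshold 0 connects only identical sequences. Cells lacking a phenotype
cluster label are excluded before network construction. Network summary
statistics (number of clusters, maximum cluster size) are normalized by
the number of cells and log10 transformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib
import networkx as nx
import numpy as np
import pandas as pd

from gdtcr._errors import UndefinedInputError


def levenshtein(a: str, b: str) -> int:
    """Levenshtein edit distance (unit-cost insert/delete/substitute)."""
    return int(edlib.align(a, b, task="distance")["editDistance"])


@dataclass
class RepertoireNetwork:
    """Similarity network over one patient's cells."""

    patient_id: str
    graph: nx.Graph
    threshold: int = 0
    components: list[frozenset] = field(init=False)

    def __post_init__(self):
        self.components = [
            frozenset(c) for c in nx.connected_components(self.graph)
        ]

    @property
    def n_cells(self) -> int:
        return self.graph.number_of_nodes()

    def edge_list(self) -> pd.DataFrame:
        rows = [
            dict(cell_a=a, cell_b=b, distance=d)
            for a, b, d in self.graph.edges(data="distance")
        ]
        return pd.DataFrame(rows, columns=["cell_a", "cell_b", "distance"])


def build_networks(
    cells: pd.DataFrame,
    threshold: int = 0,
    patient_col: str = "sample_id",
    cdr3_col: str = "cdr3_aa",
    cell_col: str = "barcode",
    cluster_col: str = "phenotype_cluster",
) -> dict[str, RepertoireNetwork]:
    """Build one CDR3 similarity network per patient.

    Cells without a phenotype cluster label (missing ``cluster_col``
    values, when the column exists) are excluded first. Distances are
    computed only within patient; cross-patient edges are never formed.
    """
    eligible = cells
    if cluster_col in cells.columns:
        eligible = cells[cells[cluster_col].notna()]

    nets: dict[str, RepertoireNetwork] = {}
    for patient in sorted(cells[patient_col].unique()):
        sub = eligible[eligible[patient_col] == patient]
        g = nx.Graph()
        ids = sub[cell_col].tolist()
        seqs = sub[cdr3_col].astype(str).tolist()
        g.add_nodes_from(ids)
        if threshold == 0:
            # exact-match grouping avoids the all-pairs distance matrix;
            # edges still cover every within-group pair
            by_seq: dict[str, list] = {}
            for cid, s in zip(ids, seqs):
                by_seq.setdefault(s, []).append(cid)
            for members in by_seq.values():
                for i in range(len(members)):
                    for j in range(i + 1, len(members)):
                        g.add_edge(members[i], members[j], distance=0)
        else:
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    d = levenshtein(seqs[i], seqs[j])
                    if d <= threshold:
                        g.add_edge(ids[i], ids[j], distance=d)
        if g.number_of_nodes() == 0:
            warnings.warn(f"patient {patient}: no eligible cells, empty network")
        nets[str(patient)] = RepertoireNetwork(str(patient), g, threshold)
    return nets


def network_stats(net: RepertoireNetwork) -> dict:
    """Cluster count and maximum cluster size, raw and normalized.

    Normalized values are log10(raw / n_cells); they are ≤ 0 because a
    network cannot have more clusters (or a larger cluster) than cells.
    """
    if net.n_cells == 0:
        raise UndefinedInputError(f"patient {net.patient_id}: empty network")
    n_clusters = len(net.components)
    max_size = max(len(c) for c in net.components)
    return dict(
        patient_id=net.patient_id,
        n_cells=net.n_cells,
        n_clusters_raw=n_clusters,
        max_cluster_size_raw=max_size,
        n_clusters_norm_log10=float(np.log10(n_clusters / net.n_cells)),
        max_cluster_size_norm_log10=float(np.log10(max_size / net.n_cells)),
    )


def network_stats_table(nets: dict[str, RepertoireNetwork]) -> pd.DataFrame:
    return pd.DataFrame(
        [network_stats(n) for n in nets.values() if n.n_cells > 0]
    )
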