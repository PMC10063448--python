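import numpy as np
import pandas as pd
import pytest

from gdtcr.contigs import (
    filter_productive,
    pair_cells,
    reassign_hybrid_delta,
    select_cell_chains,
)
from gdtcr.clonotypes import call_clonotypes, label_expansion
from gdtcr.simulate import RepertoireSimConfig, simulate_repertoire


def contig_row(**overrides):
    """One normalized contig record with sensible productive defaults."""
    row = dict(
        sample_id="s1",
        barcode="BC1",
        contig_id="BC1_contig_1",
        chain="TRD",
        v_gene="TRDV1",
        d_gene="TRDD3",
        j_gene="TRDJ1",
        c_gene="TRDC",
        full_length=True,
        productive=None,
        cdr3_aa="CALGELGDTR",
        cdr3_nt="TGTGCACTCGGGGAACTCGGGGACACTCGG",
        sequence_nt="ATG" + "GCA" * 10 + "TGTGCACTCGGGGAACTCGGGGACACTCGG" + "GGA" * 5,
        umis=5,
        reads=50,
    )
    row.update(overrides)
    return row


@pytest.fixture
def contig_table_factory():
    def make(rows):
        return pd.DataFrame([contig_row(**r) for r in rows])

    return make


def contigs_to_cells(contigs_df, sample_id):
    """Run the standard contig-processing chain down to labelled cells."""
    from gdtcr.contigs import read_contigs

    kept, _ = filter_productive(contigs_df)
    paired, orphans = pair_cells(select_cell_chains(reassign_hybrid_delta(kept)))
    cells, _ = call_clonotypes(paired)
    return label_expansion(cells), orphans


@pytest.fixture
def zero_noise_repertoire():
    """Simulated repertoire without noise plus its normalized contig table."""
    import tempfile
    from pathlib import Path

    from gdtcr.contigs import read_contigs
    from gdtcr.simulate import write_contigs_10x

    cfg = RepertoireSimConfig(
        n_cells=50,
        clone_size_law=[10, 8, 5, 5, 3, 3, 2, 2] + [1] * 12,
        seed=11,
        sample_id="p1",
    )
    contigs, truth = simulate_repertoire(cfg)
    with tempfile.TemporaryDirectory() as d:
        path = Path(d) / "contigs.csv"
        write_contigs_10x(contigs, path)
        table = read_contigs(path, "tenx_csv", sample_id="p1")
    return cfg, table, truth
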