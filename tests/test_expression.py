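"""QC, normalization, batch adjustment, clustering, Vδ2 labels, scoring, DE."""

import itertools

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from gdtcr._errors import ConfigurationError, PipelineError, UndefinedInputError
from gdtcr.expression import (
    QCThresholds,
    assign_vd2_labels,
    batch_adjust,
    cluster_cells,
    derive_signature,
    gene_set_score,
    normalize_log,
    qc_filter,
    wilcoxon_de,
)
from gdtcr.simulate import ExpressionSimConfig, simulate_expression


def make_adata(counts, obs=None):
    a = ad.AnnData(np.asarray(counts, dtype=float))
    a.obs_names = [f"c{i}" for i in range(a.n_obs)]
    a.var_names = [f"g{i}" for i in range(a.n_vars)]
    if obs:
        for k, v in obs.items():
            a.obs[k] = v
    return a


def sim_adata(cfg: ExpressionSimConfig):
    counts, meta = simulate_expression(cfg)
    a = ad.AnnData(counts.to_numpy(dtype=float), obs=meta.copy())
    a.obs_names = counts.index
    a.var_names = counts.columns
    return a


class TestQC:
    def _adata(self, n_cells=10, n_genes=250):
        rng = np.random.default_rng(0)
        return make_adata(rng.poisson(3, size=(n_cells, n_genes)))

    def test_cell_at_gene_cap_removed(self):
        # a cell with exactly max_genes detected genes fails the strict bound
        a = self._adata(n_cells=30, n_genes=4200)
        x = np.zeros((30, 4200))
        x[:, :300] = 1  # everyone expresses 300 genes
        x[0, :4000] = 1  # cell 0 expresses exactly 4000
        a.X = x
        out, _ = qc_filter(a, QCThresholds(min_cells_per_gene=1))
        assert "c0" not in out.obs_names
        assert out.n_obs == 29

    def test_gene_in_two_cells_removed(self):
        a = self._adata(n_cells=10, n_genes=250)
        a.X[:, 0] = 0
        a.X[[0, 1], 0] = 1
        out, _ = qc_filter(a)
        assert "g0" not in out.var_names

    def test_constructed_violations_give_known_survivors(self):
        rng = np.random.default_rng(1)
        n_genes = 300
        x = rng.poisson(5, size=(10, n_genes)).astype(float)
        x[0] = 0
        x[0, :100] = 1          # cell 0: 100 genes < 200 → dropped at stage 1
        x[1, :] = 100           # cell 1: 30,000 counts → dropped at upper bound
        a = make_adata(x)
        a.var_names = ["MT-1"] + [f"g{i}" for i in range(1, n_genes)]
        x2 = a.X.copy()
        x2[2, 0] = x2[2].sum()  # cell 2: ~50% mito → dropped at upper bound
        a.X = x2
        out, audit = qc_filter(a)
        assert set(out.obs_names) == {f"c{i}" for i in range(3, 10)}
        assert audit["after_min_genes"][0] == 9
        assert audit["after_upper_bounds"][0] == 7

    def test_all_cells_removed_names_stage(self):
        a = make_adata(np.ones((5, 300)) * 100)  # 30,000 counts per cell
        with pytest.raises(PipelineError, match="after_upper_bounds"):
            qc_filter(a)


class TestNormalize:
    def test_cell_arithmetic(self):
        a = make_adata([[10, 90], [50, 50]])
        out = normalize_log(a)
        np.testing.assert_allclose(
            out.X[0], np.log1p([1000.0, 9000.0]), atol=1e-9
        )

    def test_identical_cells_map_identically(self):
        a = make_adata([[3, 7, 1], [3, 7, 1]])
        out = normalize_log(a)
        np.testing.assert_array_equal(out.X[0], out.X[1])

    def test_round_trip_row_sums(self):
        rng = np.random.default_rng(2)
        a = make_adata(rng.poisson(4, size=(20, 50)) + 1)
        out = normalize_log(a)
        sums = np.expm1(out.X).sum(axis=1)
        np.testing.assert_allclose(sums, 1e4, atol=1e-6)

    def test_zero_count_cell_rejected(self):
        a = make_adata([[0, 0], [1, 2]])
        with pytest.raises(PipelineError):
            normalize_log(a)


class TestBatchAdjust:
    def test_constant_shift_removed(self):
        rng = np.random.default_rng(3)
        base = rng.normal(5, 1, size=(40, 20))
        x = base.copy()
        x[20:] += 2.5  # batch shift
        a = make_adata(x, obs={"batch": ["a"] * 20 + ["b"] * 20})
        out = batch_adjust(a)
        mean_a = out.X[:20].mean(axis=0)
        mean_b = out.X[20:].mean(axis=0)
        np.testing.assert_allclose(mean_a, mean_b, atol=1e-9)

    def test_single_batch_is_identity(self):
        a = make_adata(np.random.default_rng(4).normal(size=(10, 5)),
                       obs={"batch": ["a"] * 10})
        with pytest.warns(UserWarning):
            out = batch_adjust(a)
        np.testing.assert_array_equal(out.X, a.X)

    def test_planted_contrast_survives_adjustment(self):
        # batch shift removed, biological group difference preserved
        rng = np.random.default_rng(5)
        x = rng.normal(5, 0.3, size=(80, 10))
        group = np.array([0, 1] * 40)
        batch = np.array(["a"] * 40 + ["b"] * 40)
        x[group == 1, 0] += 2.0  # biology on gene 0, balanced across batches
        x[batch == "b"] += 1.5  # technical shift
        a = make_adata(x, obs={"batch": batch})
        out = batch_adjust(a)
        contrast = out.X[group == 1, 0].mean() - out.X[group == 0, 0].mean()
        batch_gap = np.abs(
            out.X[batch == "b"].mean(axis=0) - out.X[batch == "a"].mean(axis=0)
        ).max()
        assert contrast == pytest.approx(2.0, abs=0.3)
        assert batch_gap < 1e-9


@pytest.fixture(scope="module")
def planted_two_clusters():
    cfg = ExpressionSimConfig(
        n_cells=400, n_genes=200, n_clusters=2,
        n_marker_genes_per_cluster=30, marker_log_fc=2.5, seed=7,
    )
    a = sim_adata(cfg)
    truth = a.obs["cluster"].to_numpy()
    a = normalize_log(a)
    return a, truth


class TestClustering:
    def test_recovers_planted_clusters(self, planted_two_clusters):
        from sklearn.metrics import adjusted_rand_score

        a, truth = planted_two_clusters
        labels = cluster_cells(a.copy(), seed=0)
        assert adjusted_rand_score(truth, labels) > 0.9

    def test_same_seed_identical_labels(self, planted_two_clusters):
        a, _ = planted_two_clusters
        l1 = cluster_cells(a.copy(), seed=3)
        l2 = cluster_cells(a.copy(), seed=3)
        assert (l1 == l2).all()

    def test_too_few_cells_rejected(self):
        a = make_adata(np.random.default_rng(0).poisson(3, size=(10, 30)))
        with pytest.raises(ConfigurationError):
            cluster_cells(a, n_neighbors=15)


class TestVd2Labels:
    def _adata(self, rows):
        a = make_adata(rows)
        a.var_names = ["TRDV1", "TRDV2", "TRDV3"]
        return a

    def test_argmax_rules(self):
        a = self._adata([[0, 5, 0], [6, 2, 0], [0, 0, 0], [3, 3, 0]])
        labels = assign_vd2_labels(a, ["TRDV1", "TRDV2", "TRDV3"])
        assert list(labels) == ["Vd2pos", "Vd2neg", "unassigned", "unassigned"]

    def test_missing_genes_rejected(self):
        a = make_adata([[1, 2]])
        with pytest.raises(ConfigurationError):
            assign_vd2_labels(a, ["TRDV1", "TRDV2"])

    def test_concordance_with_contig_labels_on_zero_noise_sim(
        self, zero_noise_repertoire
    ):
        from conftest import contigs_to_cells

        _, table, truth = zero_noise_repertoire
        cells, _ = contigs_to_cells(table, "p1")
        # plant each cell's true Vδ transcript as its top expressed gene
        genes = sorted(cells["vd_gene"].unique())
        rng = np.random.default_rng(8)
        x = rng.poisson(0.05, size=(len(cells), len(genes))).astype(float)
        for i, g in enumerate(cells["vd_gene"]):
            x[i, genes.index(g)] += 10
        a = make_adata(x)
        a.var_names = genes
        a.obs_names = cells["barcode"]
        expr_labels = assign_vd2_labels(a, genes).to_numpy()
        contig_labels = cells["vd2_status"].to_numpy()
        assert (expr_labels != "unassigned").all()
        assert (expr_labels == contig_labels).all()


class TestGeneSetScore:
    def test_constant_matrix_scores_zero(self):
        a = make_adata(np.full((30, 60), 4.0))
        scores = gene_set_score(a, ["g1", "g2", "g3"], n_bins=5, ctrl_size=10)
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)

    def test_planted_shift_separates_subpopulation(self):
        cfg = ExpressionSimConfig(
            n_cells=500, n_genes=300, n_clusters=2,
            n_marker_genes_per_cluster=0,
            planted_signature_genes=[f"SIG{i:03d}" for i in range(20)],
            signature_effect=1.0, signature_cluster=0, seed=9,
        )
        a = sim_adata(cfg)
        in_pop = a.obs["in_signature_population"].to_numpy()
        a = normalize_log(a)
        scores = gene_set_score(a, [f"SIG{i:03d}" for i in range(20)], seed=0)
        from gdtcr._stats import rank_sum_test

        _, p = rank_sum_test(scores[in_pop], scores[~in_pop])
        assert p < 0.01
        assert scores[in_pop].mean() > scores[~in_pop].mean()

    def test_same_seed_bitwise_identical(self):
        rng = np.random.default_rng(10)
        a = make_adata(rng.poisson(3, size=(50, 80)))
        s1 = gene_set_score(a, ["g1", "g5", "g9"], seed=4)
        s2 = gene_set_score(a, ["g1", "g5", "g9"], seed=4)
        assert (s1 == s2).all()

    def test_empty_overlap_rejected(self):
        a = make_adata(np.ones((5, 5)))
        with pytest.raises(UndefinedInputError):
            gene_set_score(a, ["absent1", "absent2"])

    def test_random_sets_center_on_zero(self):
        rng = np.random.default_rng(11)
        a = make_adata(rng.poisson(3, size=(100, 200)).astype(float))
        means = []
        for i in range(30):
            genes = [f"g{j}" for j in rng.choice(200, size=15, replace=False)]
            means.append(gene_set_score(a, genes, seed=i).mean())
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) < 3 * se + 1e-3


def ranksum_enumeration_oracle(x, y):
    """Exact two-sided rank-sum p by enumerating group assignments."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(idx)].sum()
        count += abs(w - mu) >= abs(w_obs - mu) - 1e-12
        total += 1
    return count / total


class TestWilcoxonDE:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(12)
        x = rng.normal(2, 0.5, size=(40, 30))
        a = make_adata(np.vstack([x, x]))
        de = wilcoxon_de(a, [True] * 40 + [False] * 40, [False] * 40 + [True] * 40)
        assert (de["padj"] > 0.9).all()
        np.testing.assert_allclose(de["logfc"], 0.0, atol=1e-9)

    def test_normal_approximation_close_to_exact_small_n(self):
        a = make_adata([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        de = wilcoxon_de(a, [True] * 3 + [False] * 3, [False] * 3 + [True] * 3)
        exact = ranksum_enumeration_oracle(
            np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
        )
        assert de.loc[0, "pval"] == pytest.approx(exact, abs=0.06)

    def test_planted_de_gene_ranks_first(self):
        rng = np.random.default_rng(13)
        x = rng.normal(1, 0.3, size=(100, 50))
        x[:50, 7] += 3.0
        a = make_adata(x)
        de = wilcoxon_de(a, [True] * 50 + [False] * 50, [False] * 50 + [True] * 50)
        assert de.sort_values("padj").iloc[0]["gene"] == "g7"

    def test_group_errors(self):
        a = make_adata(np.ones((4, 3)))
        with pytest.raises(UndefinedInputError):
            wilcoxon_de(a, [False] * 4, [True] * 4)
        with pytest.raises(UndefinedInputError):
            wilcoxon_de(a, [True, True, False, False], [True, False, True, False])


class TestDeriveSignature:
    def _de_frame(self, n_up, n_down=5):
        rng = np.random.default_rng(14)
        rows = []
        for i in range(n_up):
            rows.append(dict(gene=f"UP{i:02d}", pval=1e-6 * (i + 1),
                             logfc=1.0, z=3.0, direction="up"))
        for i in range(n_down):
            rows.append(dict(gene=f"DN{i:02d}", pval=1e-6, logfc=-1.0,
                             z=-3.0, direction="down"))
        return pd.DataFrame(rows).sample(frac=1, random_state=15).reset_index(drop=True)

    def test_top_20_of_25_upregulated(self):
        sig = derive_signature(self._de_frame(25), k=20)
        assert len(sig.genes) == 20
        assert all(g.startswith("UP") for g in sig.genes)
        assert sig.genes == [f"UP{i:02d}" for i in range(20)]

    def test_fewer_than_k_warns_and_returns_all(self):
        with pytest.warns(UserWarning, match="upregulated"):
            sig = derive_signature(self._de_frame(6), k=20)
        assert len(sig.genes) == 6

    def test_deterministic_under_permutation(self):
        de = self._de_frame(25)
        sig1 = derive_signature(de, k=20)
        sig2 = derive_signature(
            de.sample(frac=1, random_state=16).reset_index(drop=True), k=20
        )
        assert sig1.genes == sig2.genes
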