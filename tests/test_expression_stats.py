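import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from snrppfs import expression_stats as es


def auc_oracle(pos, neg):
    """Pair-enumeration AUC: P(pos > neg) + 0.5 P(tie)."""
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def bh_oracle(p):
    """Step-up BH by direct definition."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestDifferentialExpression:
    @pytest.fixture
    def mat(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(40)]
        m = pd.DataFrame(rng.normal(6, 1, size=(40, 60)), index=genes)
        m.iloc[:4, :30] += 2.0
        m.columns = [f"s{i}" for i in range(60)]
        return m, ["tumor"] * 30 + ["normal"] * 30

    def test_logfc_is_mean_difference(self, mat):
        m, labels = mat
        de = es.differential_expression(m, labels)
        np.testing.assert_allclose(
            de["logFC"], de["ave_expr_tumor"] - de["ave_expr_normal"], rtol=0, atol=1e-12
        )

    def test_direction_follows_sign(self, mat):
        m, labels = mat
        de = es.differential_expression(m, labels)
        assert ((de["direction"] == "up") == (de["logFC"] > 0)).all()
        assert (de["adj_p"] >= de["p_value"] - 1e-15).all()

    def test_label_swap_negates_logfc(self, mat):
        m, labels = mat
        swapped = ["normal" if l == "tumor" else "tumor" for l in labels]
        a = es.differential_expression(m, labels)
        b = es.differential_expression(m, swapped)
        np.testing.assert_allclose(a["logFC"], -b["logFC"], atol=1e-12)

    def test_null_gene_large_p(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.normal(5, 1, size=(50, 80)), index=[f"g{i}" for i in range(50)])
        m.columns = [f"s{i}" for i in range(80)]
        de = es.differential_expression(m, ["tumor"] * 40 + ["normal"] * 40)
        # null p-values roughly uniform
        assert de["p_value"].mean() > 0.3
        assert (de["p_value"] < 0.01).sum() <= 3

    def test_moderated_t_close_to_welch_for_strong_effects(self, mat):
        m, labels = mat
        mod = es.differential_expression(m, labels, method="moderated")
        wel = es.differential_expression(m, labels, method="welch")
        strong = mod["logFC"].abs() > 1.5
        assert (np.sign(mod.loc[strong, "t_statistic"]) == np.sign(wel.loc[strong, "t_statistic"])).all()
        assert (mod.loc[strong, "p_value"] < 1e-6).all() and (wel.loc[strong, "p_value"] < 1e-6).all()

    def test_single_group_rejected(self, mat):
        m, _ = mat
        with pytest.raises(ValueError):
            es.differential_expression(m, ["tumor"] * m.shape[1])


class TestBhAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(es.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        assert es.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            es.bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_oracle_and_is_monotone(self, p):
        adj = es.bh_adjust(p)
        np.testing.assert_allclose(adj, bh_oracle(p), atol=1e-12)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj <= 1.0).all()


class TestRoc:
    def test_perfect_separation(self):
        r = es.roc([5, 6, 7, 1, 2, 3], ["tumor"] * 3 + ["normal"] * 3)
        assert r.auc == 1.0
        assert r.sensitivity == 100.0 and r.specificity == 100.0

    def test_tied_example_by_enumeration(self):
        scores = [1, 2, 3, 2, 3, 4]
        labels = ["tumor"] * 3 + ["normal"] * 3
        r = es.roc(scores, labels)
        raw = auc_oracle([1, 2, 3], [2, 3, 4])
        assert r.orientation == "down-positive"
        assert r.auc == pytest.approx(1 - raw)

    def test_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n1, n2 = rng.integers(3, 40, size=2)
            pos = rng.integers(0, 8, size=n1).astype(float)
            neg = rng.integers(0, 8, size=n2).astype(float)
            scores = np.concatenate([pos, neg])
            labels = ["tumor"] * n1 + ["normal"] * n2
            r = es.roc(scores, labels)
            expected = auc_oracle(pos, neg)
            assert r.auc == pytest.approx(max(expected, 1 - expected), abs=1e-12)

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=30)
        labels = ["tumor"] * 15 + ["normal"] * 15
        flipped = ["normal"] * 15 + ["tumor"] * 15
        a = es.roc(scores, labels)
        b = es.roc(scores, flipped)
        assert a.auc == pytest.approx(b.auc)  # orientation correction makes both >= .5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            es.roc([1, 2, 3], ["tumor", "tumor", "tumor"])


class TestEmbeddings:
    def test_rank_one_data_explained_by_pc1(self):
        t = np.linspace(0, 1, 20)
        m = pd.DataFrame(np.outer([1.0, 2.0, -1.0], t) + 5, columns=[f"s{i}" for i in range(20)])
        m.index = ["g1", "g2", "g3"]
        _, evr = es.pca_embed(m)
        assert evr[0] == pytest.approx(1.0)

    def test_pca_gene_order_invariance(self, small_cohort):
        X = small_cohort.expression.iloc[:30]
        a, _ = es.pca_embed(X)
        b, _ = es.pca_embed(X.iloc[::-1])
        pd.testing.assert_frame_equal(a, b, atol=1e-8)

    def test_planted_cohort_separates_on_pcs(self, small_cohort, small_labels):
        from sklearn.metrics import silhouette_score

        X = small_cohort.expression.loc[list(small_cohort.truth.mb_genes)]
        scores, _ = es.pca_embed(X)
        sil = silhouette_score(scores.to_numpy(), (np.asarray(small_labels) == "tumor").astype(int))
        assert sil > 0.5

    def test_plsda_separates_planted_classes(self, small_cohort, small_labels):
        X = small_cohort.expression.loc[list(small_cohort.truth.mb_genes)]
        scores = es.plsda_embed(X, small_labels)
        tum = scores.loc[np.asarray(small_labels) == "tumor", "comp1"]
        nrm = scores.loc[np.asarray(small_labels) == "normal", "comp1"]
        assert min(tum.min(), tum.max()) > nrm.max() or max(tum.min(), tum.max()) < nrm.min()

    def test_plsda_null_does_not_separate(self):
        rng = np.random.default_rng(17)
        m = pd.DataFrame(rng.normal(size=(20, 60)), columns=[f"s{i}" for i in range(60)])
        m.index = [f"g{i}" for i in range(20)]
        labels = ["tumor"] * 30 + ["normal"] * 30
        scores = es.plsda_embed(m, labels)
        tum = scores.iloc[:30, 0].to_numpy()
        nrm = scores.iloc[30:, 0].to_numpy()
        # under the null the class score ranges still overlap: PLS can tilt
        # toward chance covariance but complete separation must fail
        assert min(tum.max(), nrm.max()) > max(tum.min(), nrm.min())
        # and the standardized class separation stays small vs the planted case
        pooled = np.sqrt((tum.var(ddof=1) + nrm.var(ddof=1)) / 2)
        assert abs(tum.mean() - nrm.mean()) / pooled < 2.0

    def test_constant_matrix_raises(self):
        m = pd.DataFrame(np.full((5, 10), 3.0), columns=[f"s{i}" for i in range(10)])
        m.index = [f"g{i}" for i in range(5)]
        with pytest.raises(FloatingPointError):
            es.plsda_embed(m, ["tumor"] * 5 + ["normal"] * 5)


class TestBiclusterOrder:
    def test_identical_genes_adjacent(self):
        rng = np.random.default_rng(19)
        m = pd.DataFrame(rng.normal(size=(5, 12)), index=list("abcde"))
        m.loc["b"] = m.loc["d"]  # identical pair
        m.columns = [f"s{i}" for i in range(12)]
        gene_order, _ = es.bicluster_order(m, zscore=False)
        assert abs(gene_order.index("b") - gene_order.index("d")) == 1

    def test_block_structure_contiguous(self):
        up = np.tile([3.0, 3, 3, 0, 0, 0], (4, 1))
        down = np.tile([0.0, 0, 0, 3, 3, 3], (4, 1))
        rng = np.random.default_rng(23)
        m = pd.DataFrame(
            np.vstack([up, down]) + rng.normal(0, 0.1, size=(8, 6)),
            index=[f"u{i}" for i in range(4)] + [f"d{i}" for i in range(4)],
            columns=[f"s{i}" for i in range(6)],
        )
        gene_order, sample_order = es.bicluster_order(m)
        block = ["u" if g.startswith("u") else "d" for g in gene_order]
        assert block == sorted(block) or block == sorted(block, reverse=True)

    def test_single_gene(self):
        m = pd.DataFrame([[1.0, 2.0]], index=["solo"], columns=["s1", "s2"])
        gene_order, sample_order = es.bicluster_order(m)
        assert gene_order == ["solo"] and set(sample_order) == {"s1", "s2"}
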