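"""Single-cell stage: QC rules against a per-cell oracle, normalization
formula, resolution selection, markers, co-expression AUROC against
exhaustive pair counting, and module scoring."""

import numpy as np
import pandas as pd
import pytest
from anndata import AnnData
from hypothesis import given, settings
from hypothesis import strategies as st

from limbgrn.intervals import ValidationError
from limbgrn.singlecell import (
    QcThresholds,
    auc_from_values,
    coexpression_auc,
    coexpression_screen,
    double_positive_cells,
    find_markers,
    log_normalize,
    module_score,
    qc_filter,
    qc_metrics,
    select_resolution,
    snn_leiden_clusterer,
)


def make_adata(counts, mito=None, gene_names=None):
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    var = pd.DataFrame(index=gene_names or [f"g{i}" for i in range(n_genes)])
    var["mito"] = mito if mito is not None else np.zeros(n_genes, dtype=bool)
    obs = pd.DataFrame(index=[f"c{i}" for i in range(n_cells)])
    return AnnData(X=counts, obs=obs, var=var)


SMALL_T = QcThresholds(min_total=10, max_total=100, min_genes=3, max_mito_frac=0.2)


class TestQcFilter:
    def test_boundaries(self):
        mito = np.array([True] + [False] * 4)
        cells = np.array(
            [
                [0, 3, 3, 3, 1],   # total 10, 5 genes expressed, mito 0 -> keep
                [0, 9, 0, 0, 0],   # total 9 < min_total -> drop
                [0, 3, 3, 3, 0],   # 4 genes, mito 0, total 9 -> drop (total)
                [0, 50, 50, 1, 0], # total 101 > max -> drop
                [3, 4, 4, 4, 0],   # mito 3/15 = 0.2, not < 0.2 -> drop
                [0, 0, 0, 0, 0],   # all-zero -> drop
            ]
        )
        kept = qc_filter(make_adata(cells, mito), SMALL_T)
        assert list(kept.obs_names) == ["c0"]

    def test_matches_per_cell_oracle(self, rng):
        counts = rng.poisson(3.0, size=(500, 30))
        mito = np.zeros(30, dtype=bool)
        mito[:3] = True
        adata = make_adata(counts, mito)
        t = QcThresholds(min_total=80, max_total=110, min_genes=25, max_mito_frac=0.12)
        kept = set(qc_filter(adata, t).obs_names)
        for i in range(500):
            row = counts[i]
            total = row.sum()
            ok = (
                t.min_total <= total <= t.max_total
                and (row > 0).sum() >= t.min_genes
                and row[:3].sum() / max(total, 1) < t.max_mito_frac
            )
            assert (f"c{i}" in kept) == ok

    def test_idempotent(self, rng):
        adata = make_adata(rng.poisson(5.0, size=(100, 20)))
        once = qc_filter(adata, SMALL_T)
        twice = qc_filter(once, SMALL_T)
        assert list(once.obs_names) == list(twice.obs_names)

    def test_requires_mito_flags(self, rng):
        adata = AnnData(X=np.ones((3, 3)))
        with pytest.raises(ValidationError):
            qc_metrics(adata)


class TestLogNormalize:
    def test_matches_formula_oracle(self, rng):
        counts = rng.poisson(4.0, size=(40, 25))
        counts[0] = 0  # an all-zero cell
        norm = log_normalize(make_adata(counts), scale=1e4)
        totals = counts.sum(axis=1)
        for i in range(40):
            if totals[i] == 0:
                assert np.all(norm.X[i] == 0)
                continue
            expected = np.log1p(1e4 * counts[i] / totals[i])
            np.testing.assert_allclose(norm.X[i], expected, rtol=1e-12)

    def test_single_gene_cell(self):
        counts = np.zeros((1, 5))
        counts[0, 2] = 7
        norm = log_normalize(make_adata(counts), scale=100.0)
        assert norm.X[0, 2] == pytest.approx(np.log1p(100.0))
        assert norm.X[0, 0] == 0.0

    def test_counts_preserved_in_layer(self, rng):
        counts = rng.poisson(4.0, size=(10, 5))
        norm = log_normalize(make_adata(counts))
        np.testing.assert_array_equal(norm.layers["counts"], counts)


def blob_adata(rng, centers, n_per, n_genes=40, sd=0.4):
    rows, labels = [], []
    for ci, c in enumerate(centers):
        mu = np.zeros(n_genes)
        mu[ci * 10 : ci * 10 + 10] = c
        for _ in range(n_per):
            rows.append(np.exp(rng.normal(mu, sd)))
            labels.append(ci)
    X = np.array(rows)
    return make_adata(X), np.array(labels)


class TestSelectResolution:
    def test_two_separated_blobs(self, rng):
        adata, _ = blob_adata(rng, [3.0, -3.0], 60)
        res, labels = select_resolution(adata, seed=0)
        assert len(np.unique(labels)) == 2

    def test_three_planted_nb_clusters(self, rng):
        # negative-binomial counts with cluster-specific expression blocks
        means = np.ones((3, 60))
        for c in range(3):
            means[c, c * 20 : (c + 1) * 20] = 20.0
        counts = np.vstack(
            [rng.negative_binomial(2, 2 / (2 + means[c] * 5), size=(70, 60)) for c in range(3)]
        )
        norm = log_normalize(make_adata(counts))
        res, labels = select_resolution(norm, seed=0)
        assert len(np.unique(labels)) == 3

    def test_tie_breaks_toward_lowest_resolution(self):
        fixed = np.array([0] * 10 + [1] * 10)
        X = np.vstack([np.zeros((10, 4)), np.ones((10, 4))]) + np.linspace(0, 0.01, 20)[:, None]

        def clusterer(mat, resolution, seed):
            return fixed if resolution in (0.4, 0.6) else np.zeros(20, dtype=int)

        res, labels = select_resolution(make_adata(X), clusterer=clusterer, seed=0)
        assert res == 0.4

    def test_degenerate_clustering_raises(self):
        def clusterer(mat, resolution, seed):
            return np.zeros(mat.shape[0], dtype=int)

        with pytest.raises(ValidationError, match="degenerate"):
            select_resolution(make_adata(np.eye(10)), clusterer=clusterer, seed=0)


class TestFindMarkers:
    def test_exclusive_gene_is_marker(self, rng):
        X = rng.uniform(0.5, 1.0, size=(40, 5))
        labels = np.array([0] * 20 + [1] * 20)
        X[labels == 1, 0] = 0.0  # gene 0 expressed only in cluster 0
        X[:, 1] = 0.7            # uniform gene: filtered by logfc threshold
        markers = find_markers(make_adata(X), labels)
        g0 = markers[(markers.gene_id == "g0") & (markers.cluster == 0)]
        assert len(g0) == 1 and g0.iloc[0]["pct_out"] == 0.0
        assert "g1" not in set(markers.gene_id)

    def test_planted_cluster_markers_recovered(self, rng):
        adata, labels = blob_adata(rng, [2.0, 2.0, 2.0], 50)
        markers = find_markers(log_normalize(adata), labels)
        for c in range(3):
            found = set(markers[markers.cluster == c].gene_id)
            planted = {f"g{i}" for i in range(c * 10, c * 10 + 10)}
            assert planted <= found


def auc_pair_counting_oracle(pos, neg):
    """Concordant-pair count (+ half ties) over all n1*n2 pairs."""
    wins = sum(1.0 for p in pos for n in neg if p > n)
    ties = sum(0.5 for p in pos for n in neg if p == n)
    return (wins + ties) / (len(pos) * len(neg))


class TestCoexpressionAuc:
    def test_complete_tie_is_half(self):
        assert auc_from_values(np.ones(8), np.ones(5)) == 0.5

    def test_perfect_separation_is_one(self):
        assert auc_from_values(np.full(6, 2.0), np.zeros(4)) == 1.0

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(50):
            pos = rng.integers(0, 6, size=6).astype(float)
            neg = rng.integers(0, 6, size=5).astype(float)
            assert auc_from_values(pos, neg) == pytest.approx(
                auc_pair_counting_oracle(pos, neg), abs=1e-12
            )

    def test_cell_set_interface(self, rng):
        X = rng.uniform(0, 1, size=(10, 3))
        adata = make_adata(X)
        score = coexpression_auc(adata, "g1", ["c0", "c1", "c2"], ["c5", "c6"])
        expected = auc_pair_counting_oracle(list(X[:3, 1]), list(X[5:7, 1]))
        assert score.auc == pytest.approx(expected)
        with pytest.raises(ValidationError, match="absent|not in"):
            coexpression_auc(adata, "nope", ["c0"], ["c5"])
        with pytest.raises(ValidationError, match="disjoint"):
            coexpression_auc(adata, "g1", ["c0"], ["c0"])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(-50, 50), min_size=2, max_size=15),
        st.lists(st.integers(-50, 50), min_size=2, max_size=15),
    )
    def test_invariant_under_monotone_transform(self, pos, neg):
        pos, neg = np.array(pos) / 10.0, np.array(neg) / 10.0
        base = auc_from_values(pos, neg)
        assert auc_from_values(np.exp(pos), np.exp(neg)) == pytest.approx(base)
        assert auc_from_values(3 * pos + 7, 3 * neg + 7) == pytest.approx(base)

    def test_screen_matches_single_gene_scores(self, rng):
        X = rng.uniform(0, 1, size=(30, 8))
        adata = make_adata(X)
        pos = np.zeros(30, dtype=bool)
        pos[:12] = True
        screen = coexpression_screen(adata, pos, ~pos)
        for gi in range(8):
            expected = auc_pair_counting_oracle(list(X[:12, gi]), list(X[12:, gi]))
            assert screen.iloc[gi]["auc"] == pytest.approx(expected)


class TestDoublePositive:
    def test_definition(self):
        counts = np.array(
            [
                [1, 1, 0],  # Hand2+, Pbx1+ -> dp
                [1, 0, 1],  # Hand2+, Pbx2+ -> dp
                [1, 0, 0],  # Hand2 only -> no
                [0, 1, 1],  # Pbx only -> no
            ]
        )
        adata = make_adata(counts, gene_names=["Hand2", "Pbx1", "Pbx2"])
        np.testing.assert_array_equal(
            double_positive_cells(adata), [True, True, False, False]
        )


class TestModuleScore:
    def test_whole_matrix_set_scores_zero(self, rng):
        # when the set spans every gene the sampled controls are the set
        # itself and the score cancels exactly
        X = rng.uniform(0, 2, size=(15, 30))
        adata = make_adata(X)
        scores = module_score(adata, list(adata.var_names), n_bins=5, seed=3)
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)

    def test_deterministic_for_fixed_seed(self, rng):
        X = rng.uniform(0, 2, size=(20, 60))
        adata = make_adata(X)
        s1 = module_score(adata, ["g0", "g5", "g9"], seed=11)
        s2 = module_score(adata, ["g0", "g5", "g9"], seed=11)
        np.testing.assert_array_equal(s1, s2)

    def test_planted_program_ranks_highest(self, rng):
        X = rng.uniform(0.5, 1.5, size=(90, 50))
        labels = np.repeat([0, 1, 2], 30)
        program = [f"g{i}" for i in range(5)]
        X[labels == 1, :5] *= 4.0  # program over-expressed in cluster 1
        # coarse bins so the sampled controls include non-program genes
        scores = module_score(make_adata(X), program, n_bins=5, seed=0)
        means = [scores[labels == c].mean() for c in range(3)]
        assert np.argmax(means) == 1

    def test_empty_set_rejected(self, rng):
        with pytest.raises(ValidationError):
            module_score(make_adata(np.ones((3, 4))), [])
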