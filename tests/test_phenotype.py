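"""DTW against an exhaustive-path oracle, Manhattan distances, graph clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from actiga.io import MetadataTable
from actiga.phenotype import (
    cluster_enrichment,
    cluster_graph,
    compare_predictability,
    dtw_distance,
    embedding_distances,
)


def dtw_path_oracle(x, y):
    """Minimum cost over every monotone warping path (exhaustive recursion)."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i, j):
        cost = (x[i] - y[j]) ** 2
        if i == 0 and j == 0:
            return cost
        candidates = []
        if i > 0:
            candidates.append(best(i - 1, j))
        if j > 0:
            candidates.append(best(i, j - 1))
        if i > 0 and j > 0:
            candidates.append(best(i - 1, j - 1))
        return cost + min(candidates)

    return best(len(x) - 1, len(y) - 1)


class TestDTW:
    def test_identical_series_zero(self):
        assert dtw_distance([1, 2, 3], [1, 2, 3]) == 0.0

    def test_symmetry(self):
        assert dtw_distance([0, 0, 1], [0, 1]) == dtw_distance([0, 1], [0, 0, 1])

    def test_small_example_matches_oracle(self):
        assert dtw_distance([0, 0, 1], [0, 1]) == pytest.approx(
            dtw_path_oracle((0, 0, 1), (0, 1))
        )

    def test_exhaustive_oracle_all_short_series(self):
        """Every pair of series of length <= 4 over the alphabet {0,1,2}."""
        alphabet = (0.0, 1.0, 2.0)
        series = [
            s
            for L in (1, 2, 3, 4)
            for s in itertools.product(alphabet, repeat=L)
        ]
        rng = np.random.default_rng(0)
        # all pairs is 120^2; sampling-free subset: all pairs with both lengths <= 3,
        # plus random length-4 pairs, keeps the check exact and fast
        short = [s for s in series if len(s) <= 3]
        for x in short:
            for y in short:
                assert dtw_distance(x, y) == pytest.approx(dtw_path_oracle(x, y))
        long = [s for s in series if len(s) == 4]
        idx = rng.choice(len(long), size=40)
        for i in idx:
            for j in rng.choice(len(long), size=5):
                x, y = long[i], long[int(j)]
                assert dtw_distance(x, y) == pytest.approx(dtw_path_oracle(x, y))

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance([], [1.0])


class TestEmbeddingDistances:
    def test_identical_rows_zero(self):
        E = np.ones((3, 4))
        assert embedding_distances(E).max() == 0.0

    def test_simple_pair(self):
        D = embedding_distances(np.array([[0.0, 0.0], [1.0, 1.0]]))
        assert D[0, 1] == pytest.approx(2.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        E = rng.normal(size=(5, 3))
        D = embedding_distances(E)
        for i in range(5):
            for j in range(5):
                assert D[i, j] == pytest.approx(np.abs(E[i] - E[j]).sum())

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            embedding_distances(np.array([[np.nan, 0.0]]))


class TestClusterGraph:
    def test_planted_two_block_partition_recovered(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.05, size=(50, 8))
        b = rng.normal(10, 0.05, size=(50, 8))
        D = embedding_distances(np.vstack([a, b]))
        out = cluster_graph(D, k_neighbors=10, seed=0)
        labels = out["labels"]
        truth = np.repeat([0, 1], 50)
        # perfect agreement up to relabeling
        agreement = max(
            np.mean(labels == truth),
            np.mean(labels == 1 - truth),
        )
        assert len(np.unique(labels)) == 2 and agreement == 1.0

    def test_identical_embeddings_single_cluster(self):
        D = np.zeros((30, 30))
        out = cluster_graph(D, k_neighbors=5, seed=0)
        assert len(np.unique(out["labels"])) == 1

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(3)
        D = embedding_distances(rng.normal(size=(40, 6)))
        l1 = cluster_graph(D, seed=7)["labels"]
        l2 = cluster_graph(D, seed=7)["labels"]
        np.testing.assert_array_equal(l1, l2)


class TestClusterEnrichment:
    def test_pure_cluster_strongly_enriched(self):
        labels = np.repeat([0, 1], 100)
        md = MetadataTable(
            pd.DataFrame({"flag": np.repeat(["A", "B"], 100)}), {"flag": "categorical"}
        )
        out = cluster_enrichment(labels, md, n_iter=2000, seed=0)
        row = out[(out.cluster == 0) & (out.level == "A")].iloc[0]
        assert row.oe_ratio == pytest.approx(2.0)
        assert row.p < 0.005

    def test_uniform_label_no_effect(self):
        rng = np.random.default_rng(4)
        labels = np.repeat([0, 1], 100)
        md = MetadataTable(
            pd.DataFrame({"flag": rng.choice(["A", "B"], 200)}), {"flag": "categorical"}
        )
        out = cluster_enrichment(labels, md, n_iter=1000, seed=1)
        assert np.all(np.abs(out.effect_pct) < 40)

    def test_expected_counts_conserved(self):
        labels = np.repeat([0, 1, 2], 30)
        md = MetadataTable(
            pd.DataFrame({"flag": np.tile(["A", "B", "C"], 30)}), {"flag": "categorical"}
        )
        out = cluster_enrichment(labels, md, n_iter=1000, seed=2)
        for level in ("A", "B", "C"):
            sub = out[out.level == level]
            assert sub.expected.sum() == pytest.approx(sub.observed.sum())


class TestComparePredictability:
    def test_shape_contract(self):
        rng = np.random.default_rng(5)
        raw = rng.normal(size=(80, 6))
        emb = rng.normal(size=(80, 4))
        md = MetadataTable(
            pd.DataFrame({"t1": rng.normal(size=80), "t2": rng.choice([0, 1], 80)}),
            {"t1": "continuous", "t2": "categorical"},
        )
        groups = np.arange(80) // 2
        out = compare_predictability(raw, emb, md, ["t1", "t2"], groups)
        assert list(out.columns) == ["target", "kind", "raw", "embedding", "delta"]
        assert len(out) == 2

    def test_identical_feature_sets_zero_delta(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 5))
        md = MetadataTable(pd.DataFrame({"t": rng.normal(size=60)}), {"t": "continuous"})
        out = compare_predictability(X, X.copy(), md, ["t"], np.arange(60) // 2)
        assert out.delta.iloc[0] == pytest.approx(0.0)

    def test_embedding_readout_target_favors_embeddings(self):
        rng = np.random.default_rng(7)
        emb = rng.normal(size=(100, 4))
        raw = rng.normal(size=(100, 4))  # unrelated
        target = emb @ np.array([1.0, -2.0, 0.5, 1.5])
        md = MetadataTable(pd.DataFrame({"t": target}), {"t": "continuous"})
        out = compare_predictability(raw, emb, md, ["t"], np.arange(100) // 2)
        assert out.delta.iloc[0] > 0
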