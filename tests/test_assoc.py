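"""Mixed-type association scores and evaluation metrics against oracles."""

import numpy as np
import pandas as pd
import pytest

from actiga.assoc import (
    adjusted_auprc,
    adjusted_balanced_accuracy,
    cramers_v,
    goodman_kruskal_gamma,
    mixed_association,
    predictability,
    smote_oversample,
)


def gamma_pair_oracle(table):
    """Count concordant/discordant pairs by expanding the table to items."""
    rows, cols = [], []
    t = np.asarray(table, dtype=int)
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            rows += [i] * t[i, j]
            cols += [j] * t[i, j]
    C = D = 0
    n = len(rows)
    for a in range(n):
        for b in range(a + 1, n):
            dr = rows[a] - rows[b]
            dc = cols[a] - cols[b]
            if dr * dc > 0:
                C += 1
            elif dr * dc < 0:
                D += 1
    return (C - D) / (C + D)


class TestGamma:
    def test_textbook_table(self):
        assert goodman_kruskal_gamma([[10, 2], [3, 9]]) == pytest.approx(0.875)

    def test_all_concordant_is_one(self):
        assert goodman_kruskal_gamma([[5, 0], [0, 7]]) == pytest.approx(1.0)

    def test_matches_pair_counting_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            shape = (rng.integers(2, 4), rng.integers(2, 4))
            table = rng.integers(0, 6, size=shape)
            if table.sum() < 2:
                continue
            try:
                ours = goodman_kruskal_gamma(table)
            except ValueError:
                continue
            assert ours == pytest.approx(gamma_pair_oracle(table))


class TestMixedAssociation:
    def test_identical_continuous_is_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        score = mixed_association(x, x, "continuous", "continuous")
        assert score.score == pytest.approx(1.0)
        assert score.method == "spearman"

    def test_ordinal_concordant_is_one(self):
        a = pd.Series([0] * 10 + [1] * 10)
        score = mixed_association(a, a, "ordinal", "ordinal")
        assert score.score == pytest.approx(1.0)
        assert score.method == "gamma"

    def test_nominal_uses_cramers_v(self):
        rng = np.random.default_rng(2)
        a = pd.Series(rng.choice(["x", "y", "z"], 200))
        score = mixed_association(a, a, "categorical", "categorical")
        assert score.method == "fisher_chi2"
        assert score.score == pytest.approx(1.0)

    def test_categorical_continuous_separated_near_one(self):
        rng = np.random.default_rng(3)
        labels = np.repeat([0, 1], 100)
        values = np.where(labels == 1, 10.0, -10.0) + rng.normal(0, 0.1, 200)
        score = mixed_association(values, labels, "continuous", "categorical", rng=rng)
        assert score.method == "logistic_auroc"
        assert score.score > 0.95

    def test_independent_pair_scores_low(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=500)
        b = rng.choice(["p", "q"], 500)
        score = mixed_association(a, b, "continuous", "categorical", rng=rng)
        assert score.score < 0.15

    def test_constant_variable_reported_undefined(self):
        a = np.ones(20)
        b = np.arange(20.0)
        score = mixed_association(a, b, "continuous", "continuous")
        assert not score.defined and np.isnan(score.score)

    def test_symmetry_for_same_kind_pairs(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=80)
        b = a + rng.normal(0, 0.5, 80)
        s1 = mixed_association(a, b, "continuous", "continuous")
        s2 = mixed_association(b, a, "continuous", "continuous")
        assert s1.score == pytest.approx(s2.score)

    def test_monotone_in_planted_dependence(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=400)
        scores = []
        for beta in (0.2, 1.0, 5.0):
            y = beta * x + rng.normal(size=400)
            scores.append(mixed_association(x, y, "continuous", "continuous").score)
        assert scores == sorted(scores)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            mixed_association([1, 2], [3, 4], "continuous", "continuous")


class TestBalancedAccuracy:
    def test_perfect_classifier(self):
        assert adjusted_balanced_accuracy(np.eye(3) * 10) == pytest.approx(1.0)

    def test_always_predict_one_class_on_balanced_binary(self):
        assert adjusted_balanced_accuracy([[0, 10], [0, 10]]) == pytest.approx(0.5)

    def test_symmetric_confusion(self):
        assert adjusted_balanced_accuracy([[8, 2], [2, 8]]) == pytest.approx(0.8)

    def test_empty_class_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            out = adjusted_balanced_accuracy([[10, 0], [0, 0]])
        assert out == pytest.approx(1.0)


class TestAdjustedAUPRC:
    def test_perfect_ranking_is_one(self):
        labels = np.array([0] * 50 + [1] * 10)
        scores = labels.astype(float)
        adj, raw, prev = adjusted_auprc(scores, labels)
        assert adj == pytest.approx(1.0)

    def test_random_scores_near_zero(self):
        rng = np.random.default_rng(7)
        labels = (rng.random(2000) < 0.2).astype(int)
        adj, raw, prev = adjusted_auprc(rng.random(2000), labels)
        assert abs(adj) < 0.05
        assert prev == pytest.approx(0.2, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            adjusted_auprc([0.1, 0.2], [1, 1])


class TestPredictability:
    def _groups(self, n):
        return np.arange(n) // 2  # 2 samples per patient

    def test_target_equal_to_feature_regression(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(100, 3))
        score = predictability(x, x[:, 0], "regression", self._groups(100))
        assert score > 0.9

    def test_independent_features_classification_near_half(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(1000, 2))
        y = rng.integers(0, 2, 1000)
        score = predictability(x, y, "classification", self._groups(1000))
        assert score == pytest.approx(0.5, abs=0.05)

    def test_fewer_groups_than_folds_rejected(self):
        x = np.zeros((10, 2))
        with pytest.raises(ValueError):
            predictability(x, np.zeros(10), "regression", np.zeros(10), cv_folds=5)


def test_smote_balances_classes():
    rng = np.random.default_rng(10)
    X = rng.normal(size=(60, 2))
    y = np.array([0] * 50 + [1] * 10)
    Xb, yb = smote_oversample(X, y, rng=rng)
    _, counts = np.unique(yb, return_counts=True)
    assert counts[0] == counts[1] == 50
    # synthetic points lie within the minority convex hull bounding box
    mins, maxs = X[y == 1].min(0), X[y == 1].max(0)
    synth = Xb[60:]
    assert np.all(synth >= mins - 1e-9) and np.all(synth <= maxs + 1e-9)
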