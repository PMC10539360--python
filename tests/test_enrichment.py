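"""Error groups, observed/expected effects, permutation tests, network rules."""

import numpy as np
import pandas as pd
import pytest

from actiga.enrichment import (
    assign_error_groups,
    correlation_network,
    group_difference_tests,
    oe_effect,
    oe_ratio_example,
    permutation_test,
)
from actiga.io import MetadataTable


def _records(errors):
    return pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(len(errors))],
         "predicted_ga": np.asarray(errors) + 20.0,
         "actual_ga": np.full(len(errors), 20.0),
         "signed_error": np.asarray(errors, dtype=float)}
    )


class TestErrorGroups:
    def test_zero_error_is_low(self):
        g = assign_error_groups(_records([0.0]), tau=10.0)
        assert g.assignments.group.tolist() == ["low"]

    def test_above_threshold_is_higher(self):
        g = assign_error_groups(_records([12.0]), tau=10.0)
        assert g.assignments.group.tolist() == ["higher"]

    def test_mixed_counts(self):
        g = assign_error_groups(_records([-11, -12, 13, 14, 0]), tau=10.0)
        assert g.sizes() == {"higher": 2, "lower": 2, "low": 1}

    def test_balance_rule_minimizes_imbalance(self):
        errors = [-1, -2, -3, 4, 5, 6, 7, 0.2]
        g = assign_error_groups(_records(errors), tau="balance")
        err = np.array(errors)
        for t in np.arange(0.5, 8, 0.5):
            imb = abs((err > t).sum() - (err < -t).sum())
            best = abs((err > g.threshold).sum() - (err < -g.threshold).sum())
            assert best <= imb

    def test_balance_ties_take_smaller_tau(self):
        g = assign_error_groups(_records([5.0, -5.0]), tau="balance")
        assert g.threshold == 0.5

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        g = assign_error_groups(_records(rng.normal(0, 10, 100)), tau=5.0)
        assert g.assignments.group.isin(["higher", "lower", "low"]).all()
        assert sum(g.sizes().values()) == 100


class TestOEEffect:
    def test_cohort_table_prior_ptb(self):
        eff = oe_effect({"neg": 2028, "pos": 277}, {"neg": 200, "pos": 96})
        assert round(eff["pos"].effect_pct, 2) == 169.88
        assert round(eff["neg"].effect_pct, 2) == -23.20

    def test_cohort_table_corticosteroids(self):
        eff = oe_effect({"neg": 2028, "pos": 277}, {"neg": 72, "pos": 198})
        assert round(eff["pos"].effect_pct, 2) == 510.23

    def test_uniform_spread_gives_zero_effect(self):
        eff = oe_effect({"a": 50, "b": 50}, {"a": 10, "b": 10})
        assert eff["a"].effect_pct == pytest.approx(0.0)
        assert eff["b"].effect_pct == pytest.approx(0.0)

    def test_expected_counts_conserve_total(self):
        eff = oe_effect({"a": 30, "b": 50, "c": 20}, {"a": 5, "b": 10, "c": 5})
        assert sum(e.expected for e in eff.values()) == pytest.approx(20.0)


class TestOERatioExample:
    def test_worked_example_all_ratios_one(self):
        out = oe_ratio_example(100, [0.8, 0.1, 0.1])
        np.testing.assert_allclose(out.expected, [80, 10, 10])
        np.testing.assert_allclose(out.oe_ratio, 1.0)

    def test_zero_total_flagged_degenerate(self):
        out = oe_ratio_example(0, [0.5, 0.5])
        assert out.degenerate.all()

    def test_uneven_observed(self):
        out = oe_ratio_example(60, [0.5, 0.5], observed=[45, 15])
        np.testing.assert_allclose(out.oe_ratio, [1.5, 0.5])

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            oe_ratio_example(10, [0.5, 0.6])


class TestPermutationTest:
    def test_null_distribution_length_honored(self):
        rng = np.random.default_rng(0)
        labels = np.repeat(["a", "b"], 50)
        flags = rng.random(100) < 0.3
        res = permutation_test(labels, flags, n_iter=1500, rng=rng, method="tail")
        assert res.null_distribution.size == 1500
        assert res.n_iterations == 1500

    def test_concentrated_variable_is_significant(self):
        labels = np.repeat(["a", "b"], 100)
        flags = np.zeros(200)
        flags[:40] = 1  # all in group a
        res = permutation_test(labels, flags, group_of_interest="a",
                               n_iter=2000, rng=np.random.default_rng(1), method="tail")
        assert res.p_value < 0.001

    def test_small_n_iter_requires_force(self):
        labels = np.repeat(["a", "b"], 20)
        flags = np.zeros(40)
        flags[:5] = 1
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                permutation_test(labels, flags, n_iter=100, rng=np.random.default_rng(2))

    def test_mannwhitney_method_returns_valid_p(self):
        rng = np.random.default_rng(3)
        labels = np.repeat(["a", "b"], 60)
        flags = (rng.random(120) < 0.4).astype(float)
        res = permutation_test(labels, flags, n_iter=1000, rng=rng, method="mannwhitney")
        assert 0 < res.p_value <= 1


class TestGroupDifferenceTests:
    def _metadata(self, df, kinds):
        return MetadataTable(df, kinds)

    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(4)
        md = self._metadata(pd.DataFrame({"v": rng.normal(size=300)}), {"v": "continuous"})
        groups = np.tile(["a", "b", "c"], 100)
        out = group_difference_tests(md, groups)
        assert out.p_corrected.iloc[0] > 0.05

    def test_bonferroni_with_87_comparisons(self):
        rng = np.random.default_rng(5)
        md = self._metadata(pd.DataFrame({"v": rng.normal(size=60)}), {"v": "continuous"})
        out = group_difference_tests(md, np.repeat(["a", "b"], 30), n_comparisons=87)
        assert out.p_corrected.iloc[0] == pytest.approx(min(out.p.iloc[0] * 87, 1.0))

    def test_planted_shift_detected_after_correction(self):
        rng = np.random.default_rng(6)
        v = np.concatenate([rng.normal(0, 1, 100), rng.normal(2, 1, 100)])
        md = self._metadata(pd.DataFrame({"v": v}), {"v": "continuous"})
        out = group_difference_tests(md, np.repeat(["a", "b"], 100), n_comparisons=10)
        assert out.p_corrected.iloc[0] < 0.01

    def test_categorical_fisher_and_degenerate_reporting(self):
        df = pd.DataFrame({
            "c2": np.repeat(["x", "y"], 20),
            "const": ["z"] * 40,
        })
        md = self._metadata(df, {"c2": "categorical", "const": "categorical"})
        out = group_difference_tests(md, np.tile(["a", "b"], 20)).set_index("variable")
        assert out.loc["c2", "test"] == "fisher"
        assert out.loc["const", "test"] == "untestable"
        assert np.isnan(out.loc["const", "p"])

    def test_kruskal_mode_for_cohort_tables(self):
        rng = np.random.default_rng(7)
        md = self._metadata(pd.DataFrame({"v": rng.normal(size=80)}), {"v": "continuous"})
        out = group_difference_tests(md, np.repeat(["pos", "neg"], 40),
                                     continuous_test="kruskal")
        assert out.test.iloc[0] == "kruskal"


class TestCorrelationNetwork:
    def test_duplicated_variable_gets_unit_edge(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=100)
        md = MetadataTable(pd.DataFrame({"a": v, "b": v.copy()}),
                           {"a": "continuous", "b": "continuous"})
        g = correlation_network(md, {"a": 0.01, "b": 0.01})
        assert g.has_edge("a", "b")
        assert g.edges["a", "b"]["weight"] == pytest.approx(1.0)

    def test_cutoff_at_point_six(self):
        rng = np.random.default_rng(9)
        n = 4000
        x = rng.normal(size=n)

        def corr_pair(target_rho):
            y = target_rho * x + np.sqrt(1 - target_rho**2) * rng.normal(size=n)
            return y

        md = MetadataTable(
            pd.DataFrame({"x": x, "lo": corr_pair(0.55), "hi": corr_pair(0.75)}),
            {"x": "continuous", "lo": "continuous", "hi": "continuous"},
        )
        g = correlation_network(md, {})
        assert g.has_edge("x", "hi")
        assert not g.has_edge("x", "lo")

    def test_independent_variables_give_no_edges(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame({f"v{i}": rng.normal(size=500) for i in range(4)})
        md = MetadataTable(df, {c: "continuous" for c in df.columns})
        g = correlation_network(md, {})
        assert g.number_of_edges() == 0

    def test_node_size_from_corrected_p(self):
        rng = np.random.default_rng(11)
        md = MetadataTable(pd.DataFrame({"a": rng.normal(size=50)}), {"a": "continuous"})
        g = correlation_network(md, {"a": 1e-4})
        assert g.nodes["a"]["size"] == pytest.approx(4.0)
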