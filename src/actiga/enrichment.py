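"""Error groups, observed/expected enrichment, permutation tests and the
variable correlation network.

The clock's signed error (predicted minus actual GA, weeks) partitions
samples into higher-than-actual (> tau), lower-than-actual (< -tau) and
low-error groups. For a clinical variable, enrichment within a group is the
observed count against the count expected from group marginals; the
reported effect is (observed/expected - 1) * 100. Significance comes from
label permutations preserving group sizes; cross-group differences use
ANOVA / Kruskal-Wallis / Fisher / chi-squared with Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import MetadataTable

GROUPS = ("higher", "lower", "low")


@dataclass
class ErrorGrouping:
    threshold: float
    assignments: pd.DataFrame  # sample_id, signed_error, group

    def sizes(self) -> dict:
        counts = self.assignments["group"].value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUPS}


@dataclass
class ContingencyEffect:
    observed: float
    expected: float

    @property
    def oe_ratio(self) -> float:
        return self.observed / self.expected

    @property
    def effect_pct(self) -> float:
        return (self.oe_ratio - 1.0) * 100.0


@dataclass
class PermutationResult:
    observed: float
    null_distribution: np.ndarray
    p_value: float
    n_iterations: int
    method: str


def assign_error_groups(records: pd.DataFrame, tau="balance") -> ErrorGrouping:
    """Threshold signed errors into {higher, lower, low} groups.

    ``tau="balance"`` scans a 0.5-week grid and picks the threshold
    minimizing |#higher - #lower| (ties -> smaller tau).
    """
    if len(records) == 0:
        raise ValueError("records must be non-empty")
    err = records["signed_error"].to_numpy(dtype=float)
    if isinstance(tau, str):
        if tau != "balance":
            raise ValueError("tau must be a number or 'balance'")
        grid = np.arange(0.5, max(np.max(np.abs(err)), 0.5) + 0.5, 0.5)
        imbalance = [abs(int((err > t).sum()) - int((err < -t).sum())) for t in grid]
        tau = float(grid[int(np.argmin(imbalance))])
    tau = float(tau)
    group = np.where(err > tau, "higher", np.where(err < -tau, "lower", "low"))
    return ErrorGrouping(
        threshold=tau,
        assignments=pd.DataFrame(
            {
                "sample_id": records.get("sample_id", pd.RangeIndex(len(records))),
                "signed_error": err,
                "group": group,
            }
        ),
    )


def oe_effect(group_sizes: dict, variable_counts: dict) -> dict:
    """Observed/expected effect per group from marginal counts.

    expected_g = total_variable_count * group_size_g / total_n;
    effect = (observed_g / expected_g - 1) * 100.
    """
    total_n = sum(group_sizes.values())
    total_var = sum(variable_counts.values())
    if total_n <= 0 or total_var <= 0:
        raise ValueError("totals must be positive")
    out = {}
    for g, size in group_sizes.items():
        expected = total_var * size / total_n
        if expected == 0:
            raise ValueError(f"zero expected count in group {g!r}")
        out[g] = ContingencyEffect(observed=float(variable_counts.get(g, 0)), expected=expected)
    return out


def oe_ratio_example(total: float, proportions: Sequence[float], observed=None) -> pd.DataFrame:
    """Worked observed/expected example: expected_g = total * proportion_g."""
    proportions = np.asarray(proportions, dtype=float)
    if not np.isclose(proportions.sum(), 1.0):
        raise ValueError("proportions must sum to 1")
    expected = total * proportions
    obs = np.asarray(observed, dtype=float) if observed is not None else expected.copy()
    degenerate = total == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(expected > 0, obs / np.where(expected > 0, expected, 1.0), np.nan)
    return pd.DataFrame(
        {"expected": expected, "observed": obs, "oe_ratio": ratio, "degenerate": degenerate}
    )


def _group_oe_ratios(labels: np.ndarray, flags: np.ndarray, groups: Sequence) -> np.ndarray:
    """oe_ratio of a binary variable per group, given group labels."""
    total = flags.sum()
    n = len(labels)
    out = np.empty(len(groups))
    for i, g in enumerate(groups):
        in_g = labels == g
        expected = total * in_g.sum() / n
        out[i] = flags[in_g].sum() / expected if expected > 0 else np.nan
    return out


def permutation_test(
    sample_groups: Sequence,
    variable: Sequence,
    group_of_interest=None,
    n_iter: int = 1000,
    rng=None,
    method: str = "mannwhitney",
    n_observed_draws: int = 100,
    force: bool = False,
) -> PermutationResult:
    """Permutation test of a variable's enrichment (OE ratio) in one group.

    The null distribution permutes group labels over samples, preserving
    group sizes, and recomputes the OE ratio in `group_of_interest` (default:
    the first group). Two p-value constructions are available:

    - ``"mannwhitney"`` (default): bootstrap draws of the observed statistic
      are compared against the permutation null by a Mann-Whitney U test.
    - ``"tail"``: the exact permutation p-value ``(r + 1) / (n_iter + 1)``
      where r counts null values at least as extreme (two-sided) as observed.
    """
    labels = np.asarray(sample_groups)
    flags = np.asarray(variable).astype(float)
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if n_iter < 1000 and not force:
        warnings.warn("n_iter < 1000; pass force=True to proceed", stacklevel=2)
        raise ValueError("n_iter < 1000 requires force=True")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    g = group_of_interest if group_of_interest is not None else groups[0]

    in_g = labels == g
    size_g = int(in_g.sum())
    total = flags.sum()
    n = len(labels)
    expected = total * size_g / n
    observed = flags[in_g].sum() / expected

    # permuting labels with fixed sizes == drawing size_g positions at random
    null = np.empty(n_iter)
    for i in range(n_iter):
        pos = rng.choice(n, size=size_g, replace=False)
        null[i] = flags[pos].sum() / expected

    if method == "tail":
        centre = np.median(null)
        r = int(np.sum(np.abs(null - centre) >= abs(observed - centre)))
        p = (r + 1) / (n_iter + 1)
    elif method == "mannwhitney":
        idx = rng.integers(0, n, size=(n_observed_draws, n))
        obs_draws = np.empty(n_observed_draws)
        for i in range(n_observed_draws):
            b_labels = labels[idx[i]]
            b_flags = flags[idx[i]]
            b_in = b_labels == g
            b_exp = b_flags.sum() * b_in.sum() / n
            obs_draws[i] = b_flags[b_in].sum() / b_exp if b_exp > 0 else np.nan
        obs_draws = obs_draws[np.isfinite(obs_draws)]
        p = float(stats.mannwhitneyu(obs_draws, null).pvalue)
    else:
        raise ValueError("method must be 'mannwhitney' or 'tail'")
    return PermutationResult(
        observed=float(observed),
        null_distribution=null,
        p_value=float(min(max(p, np.nextafter(0, 1)), 1.0)),
        n_iterations=n_iter,
        method=method,
    )


def group_difference_tests(
    metadata: MetadataTable,
    groups: Sequence,
    continuous_test: str = "anova",
    n_comparisons: Optional[int] = None,
) -> pd.DataFrame:
    """Per-variable cross-group tests with Bonferroni correction.

    Continuous variables: one-way ANOVA across groups (or Kruskal-Wallis when
    ``continuous_test="kruskal"``, the two-group cohort-table mode).
    Categorical: Fisher's exact test for a 2x2 layout, chi-squared otherwise.
    Degenerate variables are reported as untestable rather than dropped.
    """
    labels = np.asarray(groups)
    level_names = pd.unique(labels)
    rows = []
    for col in metadata.variables:
        kind = metadata.kinds[col]
        values = metadata.data[col]
        row = {"variable": col, "kind": kind, "category": metadata.categories.get(col, "")}
        try:
            if kind == "continuous":
                arms = [values[labels == g].dropna().to_numpy(dtype=float) for g in level_names]
                arms = [a for a in arms if a.size > 0]
                if len(arms) < 2 or np.ptp(np.concatenate(arms)) == 0:
                    raise ValueError("degenerate")
                if continuous_test == "kruskal":
                    stat, p = stats.kruskal(*arms)
                else:
                    stat, p = stats.f_oneway(*arms)
                row.update(statistic=float(stat), p=float(p), test=continuous_test)
            else:
                table = pd.crosstab(values, labels)
                if table.shape[0] < 2:
                    raise ValueError("degenerate")
                if table.shape == (2, 2):
                    stat, p = stats.fisher_exact(table.to_numpy())
                    row.update(statistic=float(stat), p=float(p), test="fisher")
                else:
                    chi2, p, _, _ = stats.chi2_contingency(table.to_numpy())
                    row.update(statistic=float(chi2), p=float(p), test="chi2")
        except ValueError:
            row.update(statistic=np.nan, p=np.nan, test="untestable")
        rows.append(row)
    out = pd.DataFrame(rows)
    m = n_comparisons if n_comparisons is not None else int(out["p"].notna().sum())
    out["p_corrected"] = np.minimum(out["p"] * m, 1.0)
    out["n_comparisons"] = m
    return out


def correlation_network(
    metadata: MetadataTable,
    node_pvalues: Optional[dict] = None,
    cutoff: float = 0.6,
    rng=None,
) -> nx.Graph:
    """Variable graph: nodes sized by -log10(corrected p), edges where the
    mixed association score reaches `cutoff` (default 0.6)."""
    from .assoc import mixed_association

    graph = nx.Graph()
    variables = metadata.variables
    pvals = node_pvalues or {}
    for v in variables:
        p = pvals.get(v, np.nan)
        size = float(-np.log10(max(p, 1e-300))) if np.isfinite(p) else 0.0
        graph.add_node(v, size=size, p_corrected=p, kind=metadata.kinds[v],
                       category=metadata.categories.get(v, ""))
    for i, a in enumerate(variables):
        for b in variables[i + 1 :]:
            score = mixed_association(
                metadata.data[a], metadata.data[b], metadata.kinds[a], metadata.kinds[b], rng=rng
            )
            if score.defined and score.score >= cutoff:
                graph.add_edge(a, b, weight=float(score.score))
    return graph
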