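"""Unsupervised phenotyping: DTW clustering of raw actigraphy versus
graph clustering of the clock's learned embeddings.

Raw weeks are compared by dynamic time warping (after bin-mean
downsampling; the full 10,080-point DTW is quadratic and is never needed at
default settings); embeddings by Manhattan distance. Either distance matrix
feeds a kNN graph with Gaussian-kernel affinities (local bandwidth = the
distance to the k-th neighbor) and Leiden modularity community detection;
clusters are then screened for metadata enrichment with observed/expected
ratios and permutation tests.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from numba import njit

from .enrichment import oe_effect, permutation_test


@njit
def _dtw_dp(x: np.ndarray, y: np.ndarray) -> float:
    n, m = x.size, y.size
    INF = 1e300
    prev = np.full(m + 1, INF)
    prev[0] = 0.0
    cur = np.empty(m + 1)
    for i in range(1, n + 1):
        cur[0] = INF
        for j in range(1, m + 1):
            c = (x[i - 1] - y[j - 1]) ** 2
            best = prev[j]
            if prev[j - 1] < best:
                best = prev[j - 1]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = c + best
        prev, cur = cur, prev
    return prev[m]


def dtw_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """Unconstrained DTW alignment cost with squared local cost and unit steps.

    Symmetric; zero for identical series.
    """
    xa = np.ascontiguousarray(x, dtype=np.float64)
    ya = np.ascontiguousarray(y, dtype=np.float64)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("series must be non-empty")
    return float(_dtw_dp(xa, ya))


def dtw_distance_matrix(series: Sequence[np.ndarray], bin_width: int = 30) -> np.ndarray:
    """Pairwise DTW over series downsampled by `bin_width`-point bin means."""
    binned = []
    for s in series:
        s = np.asarray(s, dtype=float).ravel()
        n = s.size - s.size % bin_width
        binned.append(s[:n].reshape(-1, bin_width).mean(axis=1))
    k = len(binned)
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            D[i, j] = D[j, i] = dtw_distance(binned[i], binned[j])
    return D


def embedding_distances(embeddings: np.ndarray) -> np.ndarray:
    """Pairwise Manhattan (L1) distances between embedding rows."""
    E = np.asarray(embeddings, dtype=float)
    if not np.all(np.isfinite(E)):
        raise ValueError("embeddings must be finite")
    from scipy.spatial.distance import squareform, pdist

    return squareform(pdist(E, metric="cityblock"))


def cluster_graph(
    D: np.ndarray,
    k_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    layout: bool = False,
) -> dict:
    """kNN graph with Gaussian affinities + Leiden community detection.

    Returns {"labels": cluster id per sample, "graph": igraph Graph,
    "layout": (n, 2) array or None}.
    """
    import igraph
    import leidenalg

    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.max() == 0:  # all samples coincide; the graph carries no structure
        return {"labels": np.zeros(n, dtype=int), "graph": None, "layout": None}
    if n < 2 * k_neighbors:
        k_neighbors = max(1, n // 2 - 1)
    order = np.argsort(D, axis=1)
    sigma = np.maximum(D[np.arange(n), order[:, min(k_neighbors, n - 1)]], 1e-12)
    edges, weights = [], []
    for i in range(n):
        for j in order[i, 1 : k_neighbors + 1]:
            j = int(j)
            w = float(np.exp(-(D[i, j] ** 2) / (sigma[i] * sigma[j])))
            if i < j:
                edges.append((i, j))
            else:
                edges.append((j, i))
            weights.append(w)
    # deduplicate symmetric edges keeping the max weight
    edge_w = {}
    for e, w in zip(edges, weights):
        edge_w[e] = max(edge_w.get(e, 0.0), w)
    g = igraph.Graph(n=n, edges=list(edge_w), edge_attrs={"weight": list(edge_w.values())})
    if len(g.connected_components()) > 1:
        warnings.warn("neighbor graph is disconnected; components become clusters", stacklevel=2)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
    )
    labels = np.asarray(part.membership)
    coords = None
    if layout:
        import umap

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords = umap.UMAP(
                metric="precomputed",
                random_state=seed,
                n_neighbors=min(k_neighbors, n - 1),
            ).fit_transform(D)
    return {"labels": labels, "graph": g, "layout": coords}


def cluster_enrichment(
    labels: Sequence[int],
    metadata,
    n_iter: int = 1000,
    seed: int = 0,
    variables: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per (cluster, variable level) observed/expected enrichment.

    Categorical/ordinal variables only; p-values are exact permutation tails,
    Bonferroni-corrected over all tested (cluster, level) pairs.
    """
    labels = np.asarray(labels)
    cluster_ids = np.unique(labels)
    sizes = {int(c): int((labels == c).sum()) for c in cluster_ids}
    rng = np.random.default_rng(seed)
    rows = []
    cols = variables if variables is not None else [
        v for v in metadata.variables if metadata.kinds[v] != "continuous"
    ]
    for var in cols:
        values = metadata.data[var].to_numpy()
        for level in pd.unique(values):
            flags = (values == level).astype(float)
            if flags.sum() == 0:
                continue
            counts = {int(c): float(flags[labels == c].sum()) for c in cluster_ids}
            effects = oe_effect(sizes, counts)
            for c in cluster_ids:
                perm = permutation_test(
                    labels, flags, group_of_interest=c, n_iter=n_iter,
                    rng=rng, method="tail",
                )
                eff = effects[int(c)]
                rows.append(
                    {
                        "cluster": int(c),
                        "variable": var,
                        "level": level,
                        "observed": eff.observed,
                        "expected": eff.expected,
                        "oe_ratio": eff.oe_ratio,
                        "effect_pct": eff.effect_pct,
                        "p": perm.p_value,
                    }
                )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_corrected"] = np.minimum(out["p"] * len(out), 1.0)
    return out


def compare_predictability(
    raw_features: np.ndarray,
    embeddings: np.ndarray,
    metadata,
    targets: Sequence[str],
    patient_groups: Sequence,
    k: int = 5,
    cv_folds: int = 5,
) -> pd.DataFrame:
    """Predictability of each metadata target from embeddings vs raw features.

    One row per target with both scores and their difference (embeddings
    minus raw); a Mann-Whitney U p-value compares the two score columns.
    """
    from scipy import stats as sps

    from .assoc import predictability

    rows = []
    for target in targets:
        kind = "regression" if metadata.kinds[target] == "continuous" else "classification"
        y = metadata.data[target]
        s_raw = predictability(raw_features, y, kind, patient_groups, k=k, cv_folds=cv_folds)
        s_emb = predictability(embeddings, y, kind, patient_groups, k=k, cv_folds=cv_folds)
        rows.append(
            {"target": target, "kind": kind, "raw": s_raw, "embedding": s_emb,
             "delta": s_emb - s_raw}
        )
    out = pd.DataFrame(rows)
    if len(out) >= 2:
        res = sps.mannwhitneyu(out["embedding"], out["raw"])
        out.attrs["mannwhitney_p"] = float(res.pvalue)
    return out
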