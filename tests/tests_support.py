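"""Independent brute-force oracles shared by the test modules."""

from functools import lru_cache

import numpy as np


def dtw_path_oracle(x, y):
    """Minimum alignment cost over every monotone warping path."""
    x = tuple(x)
    y = tuple(y)

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


def gamma_pair_oracle(table):
    """Goodman-Kruskal gamma by explicit concordant/discordant pair counting."""
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
            prod = (rows[a] - rows[b]) * (cols[a] - cols[b])
            if prod > 0:
                C += 1
            elif prod < 0:
                D += 1
    return (C - D) / (C + D)
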