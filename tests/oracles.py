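"""Independent oracles used by the tests.

These deliberately avoid the package's implementation paths: the clustering
oracle recomputes every inter-cluster average distance from the raw leaf
pairwise distances at every step (O(n^3) per merge), and the power oracle is
the closed-form noncentral-t expression.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def brute_force_average_linkage(X: np.ndarray) -> np.ndarray:
    """Average-linkage merge sequence by exhaustive recomputation.

    Inter-cluster distance is the arithmetic mean of Euclidean distances over
    all cross-cluster leaf pairs, recomputed from the original leaf distance
    matrix at every step. Ties break toward the pair whose combined sorted
    member tuple is lexicographically smallest. Returns an (n-1, 4) linkage
    matrix (node_a, node_b, height, size) with new node m numbered n + m.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    leaf_dist = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))

    clusters: dict[int, tuple[int, tuple[int, ...]]] = {
        i: (i, (i,)) for i in range(n)
    }  # slot -> (node id, leaf members)
    merges = np.zeros((n - 1, 4))
    for m in range(n - 1):
        slots = sorted(clusters)
        best = None
        for ai, a in enumerate(slots):
            for b in slots[ai + 1 :]:
                mem_a = clusters[a][1]
                mem_b = clusters[b][1]
                d = float(np.mean(leaf_dist[np.ix_(mem_a, mem_b)]))
                key = (d, tuple(sorted(mem_a + mem_b)))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _), a, b = best
        node_a, mem_a = clusters[a]
        node_b, mem_b = clusters[b]
        merges[m] = (node_a, node_b, d, len(mem_a) + len(mem_b))
        clusters[a] = (n + m, tuple(sorted(mem_a + mem_b)))
        del clusters[b]
    return merges


def two_sample_t_power(
    delta: float, sd: float, n1: int, n2: int, alpha: float = 0.05
) -> float:
    """Closed-form power of the two-tailed pooled two-sample t-test."""
    df = n1 + n2 - 2
    ncp = delta / (sd * np.sqrt(1 / n1 + 1 / n2))
    t_crit = sps.t.ppf(1 - alpha / 2, df)
    upper = sps.nct.sf(t_crit, df, ncp)
    lower = sps.nct.cdf(-t_crit, df, ncp)
    # scipy's nct far tail can underflow to nan; that mass is negligible
    return float(np.nan_to_num(upper) + np.nan_to_num(lower))
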