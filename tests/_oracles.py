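"""Independent reference implementations used to cross-check the package.

These deliberately use naive O(n^2) algorithms and direct enumeration so
they stay independent of the code paths they validate.
"""

from __future__ import annotations

import numpy as np


def brute_force_dbscan(xy: np.ndarray, eps: float, min_pts: int):
    """Textbook DBSCAN by exhaustive pairwise distances.

    Returns (labels, core_mask): labels -1 for noise, cluster ids 0..k-1 in
    order of discovery by input row order.  Border points reachable from
    several clusters go to the cluster discovered first.
    """
    n = len(xy)
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    neigh = [np.flatnonzero(d2[i] <= eps**2) for i in range(n)]  # includes self
    core = np.array([len(nb) >= min_pts for nb in neigh])
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        # expand a new cluster from this unclaimed core point
        labels[i] = cid
        stack = [i]
        while stack:
            j = stack.pop()
            for k in neigh[j]:
                if labels[k] == -1:
                    labels[k] = cid
                    if core[k]:
                        stack.append(k)
        cid += 1
    return labels, core


def poisson_min_points(mean: float, eps: float, m_max: int = 10_000) -> int:
    """Largest m with P(Poisson(mean) <= m-1) <= eps, by direct summation."""
    from math import exp, lgamma, log

    best = 1
    cdf = 0.0
    for k in range(0, m_max):
        log_pmf = -mean + k * log(mean) - lgamma(k + 1)
        cdf += exp(log_pmf)
        # cdf now holds P(X <= k); candidate m = k + 1
        if cdf <= eps:
            best = k + 1
        else:
            break
    return best


def partitions_equivalent(labels_a, labels_b) -> bool:
    """True when two labelings induce the same partition (noise = -1 fixed)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if not np.array_equal(a == -1, b == -1):
        return False
    mapping: dict[int, int] = {}
    seen: set[int] = set()
    for la, lb in zip(a, b):
        if la == -1:
            continue
        if la in mapping:
            if mapping[la] != lb:
                return False
        else:
            if lb in seen:
                return False
            mapping[la] = lb
            seen.add(lb)
    return True
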