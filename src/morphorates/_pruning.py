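"""Numba pruning kernel for the contrasts (REML) Brownian likelihood.

The kernel walks the tree in postorder, combining children by the
standard independent-contrasts recursion.  It returns the restricted
log-determinant (sum of log contrast variances, which equals
log|C| + log(1'C^-1 1)) and the per-dimension contrast sums of squares
Q_j (the phylogenetically mean-centered quadratic forms), from which
the REML log-likelihood under any per-dimension rates follows in O(d).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["tree_arrays", "contrasts_reml"]


def tree_arrays(tree):
    """Flattened child lists in postorder form for the kernel."""
    n = tree.n_nodes
    counts = np.zeros(n, dtype=np.int64)
    for i in range(n):
        p = tree.parent[i]
        if p >= 0:
            counts[p] += 1
    child_ptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=child_ptr[1:])
    child_list = np.empty(n - 1, dtype=np.int64)
    fill = child_ptr[:-1].copy()
    for i in range(n):
        p = tree.parent[i]
        if p >= 0:
            child_list[fill[p]] = i
            fill[p] += 1
    return (np.asarray(tree.postorder, dtype=np.int64), child_ptr,
            child_list, int(tree.n_tips))


@njit(cache=True)
def contrasts_reml(bl, Y, postorder, child_ptr, child_list, n_tips):
    """Restricted logdet and per-dimension contrast quadratics.

    bl holds the effective branch length above every node (the root
    entry is ignored); Y is (n_tips, d).  Returns (logdet, Q) where the
    REML log-likelihood for rates sigma2 is
    sum_j -0.5 ((N-1) log(2 pi sigma2_j) + logdet + Q_j / sigma2_j).
    """
    n_nodes = bl.shape[0]
    d = Y.shape[1]
    m = np.zeros((n_nodes, d))
    e = np.zeros(n_nodes)
    logdet = 0.0
    Q = np.zeros(d)
    for idx in range(postorder.shape[0]):
        k = postorder[idx]
        lo, hi = child_ptr[k], child_ptr[k + 1]
        if hi == lo:                      # tip
            for j in range(d):
                m[k, j] = Y[k, j]
            e[k] = 0.0
            continue
        c0 = child_list[lo]
        v = bl[c0] + e[c0]
        for j in range(d):
            m[k, j] = m[c0, j]
        for ci in range(lo + 1, hi):
            c = child_list[ci]
            vc = bl[c] + e[c]
            cv = v + vc
            if cv < 1e-300:
                cv = 1e-300
            logdet += np.log(cv)
            for j in range(d):
                diff = m[k, j] - m[c, j]
                Q[j] += diff * diff / cv
                m[k, j] = (m[k, j] * vc + m[c, j] * v) / cv
            v = v * vc / cv
        e[k] = v
    return logdet, Q
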