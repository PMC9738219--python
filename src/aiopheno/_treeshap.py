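"""Exact path-dependent Shapley values for sklearn decision-tree ensembles.

Implements the polynomial-time tree-traversal algorithm that maintains, for
each root-to-node path, the fraction of feature-subset permutations flowing
down ("one fraction"), the fraction that would flow down if the split feature
were marginalized over the tree's cover distribution ("zero fraction"), and
the Shapley permutation weights, extended as the traversal descends and
unwound when a feature repeats on a path. The conditional expectation used
when a feature is absent is the cover (weighted node sample count)
distribution, so the attributions satisfy local accuracy exactly:

    Σ_j φ_j(x) = f(x) − E[f],   E[f] = cover-weighted mean of leaf values.

The traversal is written iteratively (explicit DFS stack, preallocated path
buffers) so the same function body runs compiled under numba and as plain
Python (``python_fallback=True``, used by tests to cross-check the compiled
path).
"""

from __future__ import annotations

import numpy as np
from numba import njit


def _shap_one_py(cl, cr, feature, threshold, values, cover, x, phi, max_depth):
    """Accumulate Shapley values of one tree for one sample into ``phi``."""
    max_plen = max_depth + 2
    max_frames = 2 * max_plen + 2
    s_node = np.empty(max_frames, dtype=np.int64)
    s_plen = np.empty(max_frames, dtype=np.int64)
    s_pz = np.empty(max_frames, dtype=np.float64)
    s_po = np.empty(max_frames, dtype=np.float64)
    s_pi = np.empty(max_frames, dtype=np.int64)
    s_fp = np.empty((max_frames, max_plen), dtype=np.int64)
    s_zp = np.empty((max_frames, max_plen), dtype=np.float64)
    s_op = np.empty((max_frames, max_plen), dtype=np.float64)
    s_wp = np.empty((max_frames, max_plen), dtype=np.float64)
    fp = np.empty(max_plen, dtype=np.int64)
    zp = np.empty(max_plen, dtype=np.float64)
    op = np.empty(max_plen, dtype=np.float64)
    wp = np.empty(max_plen, dtype=np.float64)

    s_node[0] = 0
    s_plen[0] = 0
    s_pz[0] = 1.0
    s_po[0] = 1.0
    s_pi[0] = -1
    sp = 1
    while sp > 0:
        sp -= 1
        node = s_node[sp]
        l = s_plen[sp]
        pz = s_pz[sp]
        po = s_po[sp]
        pi = s_pi[sp]
        for i in range(l):
            fp[i] = s_fp[sp, i]
            zp[i] = s_zp[sp, i]
            op[i] = s_op[sp, i]
            wp[i] = s_wp[sp, i]

        # EXTEND the path with the incoming (zero, one) fractions
        fp[l] = pi
        zp[l] = pz
        op[l] = po
        wp[l] = 1.0 if l == 0 else 0.0
        for i in range(l - 1, -1, -1):
            wp[i + 1] += po * wp[i] * (i + 1.0) / (l + 1.0)
            wp[i] = pz * wp[i] * (l - i) / (l + 1.0)
        plen = l + 1

        if cl[node] < 0:  # leaf: credit every feature on the path
            leaf = values[node]
            l2 = plen - 1
            for i in range(1, plen):
                # sum of weights of the path UNWOUND at element i
                n_ = wp[l2]
                total = 0.0
                if op[i] != 0.0:
                    for j in range(l2 - 1, -1, -1):
                        tmp = n_ / ((j + 1.0) * op[i])
                        total += tmp
                        n_ = wp[j] - tmp * zp[i] * (l2 - j)
                else:
                    for j in range(l2 - 1, -1, -1):
                        total += wp[j] / (zp[i] * (l2 - j))
                w = total * (l2 + 1.0)
                phi[fp[i]] += w * (op[i] - zp[i]) * leaf
            continue

        split = feature[node]
        if x[split] <= threshold[node]:
            hot, cold = cl[node], cr[node]
        else:
            hot, cold = cr[node], cl[node]
        iz = 1.0
        io = 1.0
        k = -1
        for i in range(1, plen):
            if fp[i] == split:
                k = i
                break
        if k >= 0:  # feature already on the path: UNWIND it first
            iz = zp[k]
            io = op[k]
            l2 = plen - 1
            n_ = wp[l2]
            if io != 0.0:
                for j in range(l2 - 1, -1, -1):
                    tmp = n_ * (l2 + 1.0) / ((j + 1.0) * io)
                    n_ = wp[j] - tmp * iz * (l2 - j) / (l2 + 1.0)
                    wp[j] = tmp
            else:
                for j in range(l2 - 1, -1, -1):
                    wp[j] = wp[j] * (l2 + 1.0) / (iz * (l2 - j))
            # recomputed weights already sit at 0..l2−1; shift only the
            # (feature, zero, one) triples over the removed element
            for j in range(k, l2):
                fp[j] = fp[j + 1]
                zp[j] = zp[j + 1]
                op[j] = op[j + 1]
            plen = l2

        rj = cover[node]
        for child, child_pz, child_po in (
            (hot, iz * cover[hot] / rj, io),
            (cold, iz * cover[cold] / rj, 0.0),
        ):
            s_node[sp] = child
            s_plen[sp] = plen
            s_pz[sp] = child_pz
            s_po[sp] = child_po
            s_pi[sp] = split
            for i in range(plen):
                s_fp[sp, i] = fp[i]
                s_zp[sp, i] = zp[i]
                s_op[sp, i] = op[i]
                s_wp[sp, i] = wp[i]
            sp += 1
    return phi


_shap_one_nb = njit(cache=False)(_shap_one_py)


def _tree_arrays(tree):
    t = tree.tree_
    return (
        t.children_left.astype(np.int64),
        t.children_right.astype(np.int64),
        t.feature.astype(np.int64),
        t.threshold.astype(np.float64),
        t.value.reshape(-1).astype(np.float64),
        t.weighted_n_node_samples.astype(np.float64),
        int(t.max_depth),
    )


def tree_expected_value(tree) -> float:
    """Cover-weighted mean of leaf values — the tree's baseline E[f]."""
    cl, _, _, _, val, cover, _ = _tree_arrays(tree)
    leaves = cl < 0
    return float((val[leaves] * cover[leaves]).sum() / cover[0])


def tree_shap_values(tree, X, python_fallback: bool = False) -> np.ndarray:
    """Per-sample Shapley values (n_samples × n_features) for one regression
    tree fitted by sklearn."""
    cl, cr, feat, thr, val, cover, depth = _tree_arrays(tree)
    X = np.ascontiguousarray(X, dtype=np.float64)
    n, m = X.shape
    phi = np.zeros((n, m))
    if cl[0] < 0:  # single-leaf tree predicts a constant: all φ = 0
        return phi
    fn = _shap_one_py if python_fallback else _shap_one_nb
    for i in range(n):
        fn(cl, cr, feat, thr, val, cover, X[i], phi[i], depth)
    return phi


def forest_shap_values(forest, X, python_fallback: bool = False):
    """Shapley values for a sklearn RandomForestRegressor: mean of the
    per-tree attributions (the forest predicts the mean of its trees).

    Returns ``(phi, expected_value)``; ``phi.sum(1) + expected_value``
    reproduces the forest predictions exactly (local accuracy).
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    phi = np.zeros((X.shape[0], X.shape[1]))
    expected = 0.0
    for est in forest.estimators_:
        phi += tree_shap_values(est, X, python_fallback=python_fallback)
        expected += tree_expected_value(est)
    k = len(forest.estimators_)
    return phi / k, expected / k
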