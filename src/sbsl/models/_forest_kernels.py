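"""Numba kernels for the penalized-gain random forest.

The regularization follows the penalized-forest idea: when a node considers
splitting on a feature that no tree in the forest has used yet, the split's
Gini gain is multiplied by ``coef_reg`` (in (0, 1]); features already in the
forest's used-set compete unpenalized. With ``coef_reg = 1`` the model is a
plain random forest. Trees are grown sequentially on bootstrap samples so the
used-feature set accumulates across trees.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["grow_forest", "forest_predict"]


@njit(cache=True)
def grow_forest(X, y, n_trees, mtry, coef_reg, min_leaf, seed):
    n, p = X.shape
    max_nodes = 2 * n + 1
    feat = np.full((n_trees, max_nodes), -1, np.int64)
    thr = np.zeros((n_trees, max_nodes))
    left = np.full((n_trees, max_nodes), -1, np.int64)
    right = np.full((n_trees, max_nodes), -1, np.int64)
    value = np.zeros((n_trees, max_nodes))
    used = np.zeros(p, np.bool_)
    np.random.seed(seed)

    samples = np.empty(n, np.int64)
    stack = np.empty((max_nodes, 3), np.int64)
    cand = np.empty(p, np.int64)
    vals = np.empty(n)

    for t in range(n_trees):
        for i in range(n):
            samples[i] = np.random.randint(0, n)
        n_nodes = 1
        stack[0, 0] = 0
        stack[0, 1] = 0
        stack[0, 2] = n
        sp = 1
        while sp > 0:
            sp -= 1
            node = stack[sp, 0]
            start = stack[sp, 1]
            end = stack[sp, 2]
            m = end - start
            pos = 0
            for i in range(start, end):
                pos += y[samples[i]]
            val = pos / m
            value[t, node] = val
            if m < 2 * min_leaf or pos == 0 or pos == m:
                continue
            parent_gini = 2.0 * val * (1.0 - val)

            # sample mtry distinct candidate features (partial Fisher-Yates)
            for j in range(p):
                cand[j] = j
            k_take = mtry if mtry < p else p
            for j in range(k_take):
                r = j + np.random.randint(0, p - j)
                tmp = cand[j]
                cand[j] = cand[r]
                cand[r] = tmp

            best_pen_gain = 1e-12
            best_feat = -1
            best_thr = 0.0
            for jj in range(k_take):
                f = cand[jj]
                for i in range(m):
                    vals[i] = X[samples[start + i], f]
                order = np.argsort(vals[:m], kind="mergesort")
                cum_pos = 0
                for q in range(m - 1):
                    cum_pos += y[samples[start + order[q]]]
                    nl = q + 1
                    nr = m - nl
                    if nl < min_leaf or nr < min_leaf:
                        continue
                    v1 = vals[order[q]]
                    v2 = vals[order[q + 1]]
                    if v1 == v2:
                        continue
                    pl = cum_pos / nl
                    pr = (pos - cum_pos) / nr
                    child = (nl * 2.0 * pl * (1.0 - pl) + nr * 2.0 * pr * (1.0 - pr)) / m
                    gain = parent_gini - child
                    pen = gain if used[f] else gain * coef_reg
                    if pen > best_pen_gain:
                        best_pen_gain = pen
                        best_feat = f
                        best_thr = 0.5 * (v1 + v2)
            if best_feat < 0:
                continue
            used[best_feat] = True
            # in-place partition of samples[start:end]
            lo = start
            hi = end - 1
            while lo <= hi:
                if X[samples[lo], best_feat] <= best_thr:
                    lo += 1
                else:
                    tmp = samples[lo]
                    samples[lo] = samples[hi]
                    samples[hi] = tmp
                    hi -= 1
            mid = lo
            if mid == start or mid == end:
                continue  # numerically degenerate split; keep as leaf
            feat[t, node] = best_feat
            thr[t, node] = best_thr
            lid = n_nodes
            rid = n_nodes + 1
            n_nodes += 2
            left[t, node] = lid
            right[t, node] = rid
            stack[sp, 0] = lid
            stack[sp, 1] = start
            stack[sp, 2] = mid
            sp += 1
            stack[sp, 0] = rid
            stack[sp, 1] = mid
            stack[sp, 2] = end
            sp += 1
    return feat, thr, left, right, value, used


@njit(cache=True)
def forest_predict(X, feat, thr, left, right, value):
    n = X.shape[0]
    n_trees = feat.shape[0]
    out = np.zeros(n)
    for t in range(n_trees):
        for i in range(n):
            node = 0
            while feat[t, node] >= 0:
                if X[i, feat[t, node]] <= thr[t, node]:
                    node = left[t, node]
                else:
                    node = right[t, node]
            out[i] += value[t, node]
    return out / n_trees
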