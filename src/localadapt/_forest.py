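"""Compact random-forest regression with out-of-bag R-squared.

A genome scan fits one forest per locus: tens of thousands of forests on a
matrix of ~64 localities x 11 climate variables.  General-purpose forest
implementations carry per-model overhead that dominates at that size, so
this module implements the classical algorithm (CART regression trees on
bootstrap samples, `mtry` random candidate features per node, variance
reduction splits, node size >= `min_leaf`) directly in numba, returning the
out-of-bag R-squared per response column.  Behaviour is validated against
scikit-learn's RandomForestRegressor in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _forest_oob_r2(X, y, n_trees, mtry, min_leaf):  # pragma: no cover - jit
    n, p = X.shape
    max_nodes = 4 * n + 8
    feat = np.empty(max_nodes, np.int64)
    thresh = np.empty(max_nodes)
    left = np.empty(max_nodes, np.int64)
    right = np.empty(max_nodes, np.int64)
    value = np.empty(max_nodes)
    idx = np.empty(n, np.int64)
    st_node = np.empty(max_nodes, np.int64)
    st_lo = np.empty(max_nodes, np.int64)
    st_hi = np.empty(max_nodes, np.int64)
    vbuf = np.empty(n)
    featperm = np.empty(p, np.int64)
    inbag = np.empty(n, np.int64)
    pred_sum = np.zeros(n)
    pred_cnt = np.zeros(n, np.int64)

    for _t in range(n_trees):
        inbag[:] = 0
        for i in range(n):
            inbag[np.random.randint(0, n)] += 1
        m = 0
        for i in range(n):
            for _r in range(inbag[i]):
                idx[m] = i
                m += 1

        n_nodes = 1
        sp = 0
        st_node[0], st_lo[0], st_hi[0] = 0, 0, n
        sp = 1
        while sp > 0:
            sp -= 1
            node, lo, hi = st_node[sp], st_lo[sp], st_hi[sp]
            cnt = hi - lo
            s = 0.0
            for i in range(lo, hi):
                s += y[idx[i]]
            mean = s / cnt
            value[node] = mean
            feat[node] = -1
            if cnt < 2 * min_leaf:
                continue
            ss = 0.0
            for i in range(lo, hi):
                dv = y[idx[i]] - mean
                ss += dv * dv
            if ss <= 1e-12:
                continue
            for j in range(p):
                featperm[j] = j
            best_gain = -1.0
            best_f = -1
            best_t = 0.0
            base = s * s / cnt
            for k in range(mtry):
                r = k + np.random.randint(0, p - k)
                featperm[k], featperm[r] = featperm[r], featperm[k]
                f = featperm[k]
                for i in range(cnt):
                    vbuf[i] = X[idx[lo + i], f]
                order = np.argsort(vbuf[:cnt])
                sl = 0.0
                for split in range(1, cnt):
                    sl += y[idx[lo + order[split - 1]]]
                    if vbuf[order[split]] <= vbuf[order[split - 1]]:
                        continue
                    if split < min_leaf or cnt - split < min_leaf:
                        continue
                    sr = s - sl
                    gain = sl * sl / split + sr * sr / (cnt - split) - base
                    if gain > best_gain:
                        best_gain = gain
                        best_f = f
                        best_t = 0.5 * (vbuf[order[split]] + vbuf[order[split - 1]])
            if best_f < 0:
                continue
            i = lo
            j = hi - 1
            while i <= j:
                if X[idx[i], best_f] <= best_t:
                    i += 1
                else:
                    idx[i], idx[j] = idx[j], idx[i]
                    j -= 1
            if i == lo or i == hi:
                continue
            lchild = n_nodes
            rchild = n_nodes + 1
            n_nodes += 2
            feat[node] = best_f
            thresh[node] = best_t
            left[node] = lchild
            right[node] = rchild
            st_node[sp], st_lo[sp], st_hi[sp] = lchild, lo, i
            sp += 1
            st_node[sp], st_lo[sp], st_hi[sp] = rchild, i, hi
            sp += 1

        for i in range(n):
            if inbag[i] == 0:
                node = 0
                while feat[node] >= 0:
                    if X[i, feat[node]] <= thresh[node]:
                        node = left[node]
                    else:
                        node = right[node]
                pred_sum[i] += value[node]
                pred_cnt[i] += 1

    used = 0
    ysum = 0.0
    for i in range(n):
        if pred_cnt[i] > 0:
            used += 1
            ysum += y[i]
    if used < 2:
        return 0.0
    ybar = ysum / used
    sse = 0.0
    sst = 0.0
    for i in range(n):
        if pred_cnt[i] > 0:
            e = y[i] - pred_sum[i] / pred_cnt[i]
            sse += e * e
            d = y[i] - ybar
            sst += d * d
    if sst <= 0.0:
        return 0.0
    return 1.0 - sse / sst


@njit(cache=True)
def _scan_columns(X, Y, n_trees, mtry, min_leaf, seeds):  # pragma: no cover - jit
    n_loci = Y.shape[1]
    out = np.empty(n_loci)
    for l in range(n_loci):
        np.random.seed(seeds[l])
        out[l] = _forest_oob_r2(X, Y[:, l], n_trees, mtry, min_leaf)
    return out


def forest_oob_r2(X, Y, n_trees: int = 500, mtry: int | None = None,
                  min_leaf: int = 5, seed=None) -> np.ndarray:
    """Out-of-bag R-squared of one random-forest regression per column of Y.

    ``mtry`` defaults to ``max(p // 3, 1)``, the classical regression-forest
    choice.  Each column gets a child seed of ``seed``, so results are
    reproducible and independent of column order.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    Y = np.ascontiguousarray(Y, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    if mtry is None:
        mtry = max(X.shape[1] // 3, 1)
    mtry = min(mtry, X.shape[1])
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(Y.shape[1], dtype=np.uint32).astype(np.int64) % (2**31 - 1)
    return _scan_columns(X, Y, int(n_trees), int(mtry), int(min_leaf), seeds)
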