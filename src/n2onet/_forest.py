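"""Regression random forest core (numba-compiled).

CART-style trees with variance-reduction splits on bootstrap samples.
Importance for a predictor is the total decrease in node sum-of-squares over
its splits, averaged over trees ("increase in node purity"). Out-of-bag
predictions accumulate per sample for the OOB R^2.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _fit_forest(X, y, n_trees, mtry, min_node, seed):  # pragma: no cover - jit
    n, p = X.shape
    importance = np.zeros(p)
    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n)
    np.random.seed(seed)
    max_nodes = 2 * n + 1
    feat = np.empty(max_nodes, np.int64)
    thr = np.zeros(max_nodes)
    left = np.zeros(max_nodes, np.int64)
    right = np.zeros(max_nodes, np.int64)
    value = np.zeros(max_nodes)
    stack_node = np.empty(max_nodes, np.int64)
    stack_lo = np.empty(max_nodes, np.int64)
    stack_hi = np.empty(max_nodes, np.int64)
    fidx = np.empty(p, np.int64)

    for _t in range(n_trees):
        boot = np.random.randint(0, n, n)
        inbag = np.zeros(n, np.bool_)
        for i in boot:
            inbag[i] = True
        smp = boot.copy()
        n_nodes = 1
        stack_node[0] = 0
        stack_lo[0] = 0
        stack_hi[0] = n
        top = 1
        while top > 0:
            top -= 1
            node = stack_node[top]
            lo = stack_lo[top]
            hi = stack_hi[top]
            m = hi - lo
            s = 0.0
            s2 = 0.0
            for ii in range(lo, hi):
                yv = y[smp[ii]]
                s += yv
                s2 += yv * yv
            value[node] = s / m
            feat[node] = -1
            sse = s2 - s * s / m
            if m <= min_node or sse <= 1e-12:
                continue
            for q in range(p):
                fidx[q] = q
            best_gain = 1e-12
            best_f = -1
            best_thr = 0.0
            for q in range(mtry):
                r = q + np.random.randint(0, p - q)
                tmp = fidx[q]
                fidx[q] = fidx[r]
                fidx[r] = tmp
                f = fidx[q]
                xv = np.empty(m)
                for ii in range(m):
                    xv[ii] = X[smp[lo + ii], f]
                order = np.argsort(xv)
                cs = 0.0
                csq = 0.0
                for ii in range(m - 1):
                    yy = y[smp[lo + order[ii]]]
                    cs += yy
                    csq += yy * yy
                    xl = xv[order[ii]]
                    xr = xv[order[ii + 1]]
                    if xr <= xl + 1e-12:
                        continue
                    nl = ii + 1
                    nr = m - nl
                    sse_l = csq - cs * cs / nl
                    sse_r = (s2 - csq) - (s - cs) * (s - cs) / nr
                    gain = sse - sse_l - sse_r
                    if gain > best_gain:
                        best_gain = gain
                        best_f = f
                        best_thr = 0.5 * (xl + xr)
            if best_f < 0:
                continue
            i1 = lo
            for ii in range(lo, hi):
                if X[smp[ii], best_f] <= best_thr:
                    tmp = smp[i1]
                    smp[i1] = smp[ii]
                    smp[ii] = tmp
                    i1 += 1
            if i1 == lo or i1 == hi:
                continue
            feat[node] = best_f
            thr[node] = best_thr
            importance[best_f] += best_gain
            lchild = n_nodes
            rchild = n_nodes + 1
            n_nodes += 2
            left[node] = lchild
            right[node] = rchild
            stack_node[top] = lchild
            stack_lo[top] = lo
            stack_hi[top] = i1
            top += 1
            stack_node[top] = rchild
            stack_lo[top] = i1
            stack_hi[top] = hi
            top += 1
        for i in range(n):
            if inbag[i]:
                continue
            node = 0
            while feat[node] >= 0:
                if X[i, feat[node]] <= thr[node]:
                    node = left[node]
                else:
                    node = right[node]
            oob_sum[i] += value[node]
            oob_cnt[i] += 1
    return importance / n_trees, oob_sum, oob_cnt


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 500,
    mtry: int | None = None,
    min_node: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Fit a regression forest; returns (importance, oob_r2)."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    n, p = X.shape
    if mtry is None:
        mtry = max(1, p // 3)
    mtry = min(mtry, p)
    imp, oob_sum, oob_cnt = _fit_forest(
        X, y, int(n_trees), int(mtry), int(min_node), int(seed) % (2**31)
    )
    seen = oob_cnt > 0
    var_y = float(np.var(y))
    if var_y == 0 or not seen.any():
        return imp, float("nan")
    pred = oob_sum[seen] / oob_cnt[seen]
    mse = float(np.mean((y[seen] - pred) ** 2))
    return imp, 1.0 - mse / var_y
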