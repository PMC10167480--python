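"""Numba-compiled random-forest kernel for tiny balanced training sets.

The ensemble scheme trains hundreds of small forests (500 unlimited-depth
CART trees on ~2 x n_pos proteins each) per progulon, so per-model
overhead dominates the run time.  This kernel builds a full forest and
routes the test rows in a single compiled call: bootstrap resampling,
Gini splits on sqrt-subsampled features, growth to purity, majority leaf
vote.  Inputs must be dense (missing values imputed by the caller).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def forest_votes(X_tr, y_tr, X_te, n_trees, mtry, seed):  # pragma: no cover - jit
    """Fraction of trees voting class 1 for each test row.

    Each tree is fitted on a bootstrap sample of (X_tr, y_tr); at every
    node ``mtry`` candidate features are drawn without replacement (the
    search continues past constant features so a split is found whenever
    one exists); nodes grow until pure.  Leaf vote is the majority class
    (ties vote 0).
    """
    np.random.seed(seed)
    n, p = X_tr.shape
    n_te = X_te.shape[0]
    votes = np.zeros(n_te)
    max_nodes = 4 * n + 3
    feat = np.empty(max_nodes, np.int64)
    thr = np.empty(max_nodes, np.float64)
    left = np.empty(max_nodes, np.int64)
    right = np.empty(max_nodes, np.int64)
    leafv = np.empty(max_nodes, np.float64)
    idx = np.empty(n, np.int64)
    stack_node = np.empty(max_nodes, np.int64)
    stack_lo = np.empty(max_nodes, np.int64)
    stack_hi = np.empty(max_nodes, np.int64)
    featperm = np.empty(p, np.int64)
    vals = np.empty(n, np.float64)
    ys = np.empty(n, np.float64)
    for _t in range(n_trees):
        for i in range(n):
            idx[i] = np.random.randint(0, n)
        n_nodes = 1
        stack_node[0] = 0
        stack_lo[0] = 0
        stack_hi[0] = n
        sp = 1
        while sp > 0:
            sp -= 1
            node = stack_node[sp]
            lo = stack_lo[sp]
            hi = stack_hi[sp]
            m = hi - lo
            npos = 0.0
            for i in range(lo, hi):
                npos += y_tr[idx[i]]
            if npos == 0.0 or npos == m:
                feat[node] = -1
                leafv[node] = 1.0 if 2.0 * npos > m else 0.0
                continue
            for j in range(p):
                featperm[j] = j
            best_gain = -1.0
            best_f = -1
            best_t = 0.0
            n_checked = 0
            parent_imp = 1.0 - ((npos / m) ** 2 + ((m - npos) / m) ** 2)
            j = 0
            while j < p:
                r = j + np.random.randint(0, p - j)
                tmp = featperm[j]
                featperm[j] = featperm[r]
                featperm[r] = tmp
                f = featperm[j]
                j += 1
                for i in range(m):
                    vals[i] = X_tr[idx[lo + i], f]
                    ys[i] = y_tr[idx[lo + i]]
                # insertion sort (m is tiny)
                for a in range(1, m):
                    v = vals[a]
                    yy = ys[a]
                    b = a - 1
                    while b >= 0 and vals[b] > v:
                        vals[b + 1] = vals[b]
                        ys[b + 1] = ys[b]
                        b -= 1
                    vals[b + 1] = v
                    ys[b + 1] = yy
                if vals[0] < vals[m - 1]:
                    n_checked += 1
                    lpos = 0.0
                    for s in range(m - 1):
                        lpos += ys[s]
                        if vals[s + 1] > vals[s]:
                            nl = s + 1.0
                            nr = m - nl
                            rpos = npos - lpos
                            gl = 1.0 - ((lpos / nl) ** 2 + ((nl - lpos) / nl) ** 2)
                            gr = 1.0 - ((rpos / nr) ** 2 + ((nr - rpos) / nr) ** 2)
                            gain = parent_imp - (nl * gl + nr * gr) / m
                            if gain > best_gain:
                                best_gain = gain
                                best_f = f
                                best_t = 0.5 * (vals[s] + vals[s + 1])
                if n_checked >= mtry and best_f >= 0:
                    break
            if best_f < 0:
                feat[node] = -1
                leafv[node] = 1.0 if 2.0 * npos > m else 0.0
                continue
            a = lo
            b = hi - 1
            while a <= b:
                if X_tr[idx[a], best_f] <= best_t:
                    a += 1
                else:
                    tmp = idx[a]
                    idx[a] = idx[b]
                    idx[b] = tmp
                    b -= 1
            mid = a
            feat[node] = best_f
            thr[node] = best_t
            left[node] = n_nodes
            right[node] = n_nodes + 1
            n_nodes += 2
            stack_node[sp] = left[node]
            stack_lo[sp] = lo
            stack_hi[sp] = mid
            sp += 1
            stack_node[sp] = right[node]
            stack_lo[sp] = mid
            stack_hi[sp] = hi
            sp += 1
        for i in range(n_te):
            node = 0
            while feat[node] >= 0:
                if X_te[i, feat[node]] <= thr[node]:
                    node = left[node]
                else:
                    node = right[node]
            votes[i] += leafv[node]
    return votes / n_trees
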