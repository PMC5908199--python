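"""Compiled random-forest OOB-accuracy evaluator for permutation loops.

Label-permutation testing refits the forest tens of thousands of times
on a ~23-subject cohort; a per-fit Python overhead of even a few
milliseconds dominates that loop.  This module grows the same kind of
forest as the classifier used for the reported model — CART trees, Gini
split criterion, sqrt(n_features) candidate features per split, trees
grown to purity on bootstrap resamples, out-of-bag majority-vote
predictions — as a single numba-compiled kernel, so one 500-tree forest
costs ~2-3 ms.

Binary labels only (0/1).  OOB prediction ties are broken toward class 0,
matching the argmax-over-class-order convention of scikit-learn.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _forest_oob_votes(X, y, n_trees, mtry, seed):  # pragma: no cover - compiled
    n, d = X.shape
    votes = np.zeros((n, 2))
    np.random.seed(seed)
    inb = np.empty(n, np.int64)
    oob = np.empty(n, np.int64)
    cap = 4 * n + 8
    stack_lo_i = np.empty(cap, np.int64)
    stack_hi_i = np.empty(cap, np.int64)
    stack_lo_o = np.empty(cap, np.int64)
    stack_hi_o = np.empty(cap, np.int64)
    feat_order = np.empty(d, np.int64)
    for _t in range(n_trees):
        used = np.zeros(n, np.bool_)
        for i in range(n):
            j = np.random.randint(0, n)
            inb[i] = j
            used[j] = True
        n_oob = 0
        for i in range(n):
            if not used[i]:
                oob[n_oob] = i
                n_oob += 1
        stack_lo_i[0] = 0
        stack_hi_i[0] = n
        stack_lo_o[0] = 0
        stack_hi_o[0] = n_oob
        top = 1
        while top > 0:
            top -= 1
            li = stack_lo_i[top]
            hi = stack_hi_i[top]
            lo = stack_lo_o[top]
            ho = stack_hi_o[top]
            m = hi - li
            c1 = 0
            for i in range(li, hi):
                c1 += y[inb[i]]
            is_leaf = m < 2 or c1 == 0 or c1 == m
            best_feat = -1
            best_thr = 0.0
            best_imp = 1e18
            if not is_leaf:
                # draw mtry distinct candidate features (Fisher-Yates prefix)
                for k in range(d):
                    feat_order[k] = k
                for k in range(mtry):
                    r = k + np.random.randint(0, d - k)
                    tmp = feat_order[k]
                    feat_order[k] = feat_order[r]
                    feat_order[r] = tmp
                for k in range(mtry):
                    f = feat_order[k]
                    vals = np.empty(m)
                    labs = np.empty(m, np.int64)
                    for i in range(m):
                        vals[i] = X[inb[li + i], f]
                        labs[i] = y[inb[li + i]]
                    # insertion sort; node sizes are tiny
                    for i in range(1, m):
                        v = vals[i]
                        la = labs[i]
                        j = i - 1
                        while j >= 0 and vals[j] > v:
                            vals[j + 1] = vals[j]
                            labs[j + 1] = labs[j]
                            j -= 1
                        vals[j + 1] = v
                        labs[j + 1] = la
                    left1 = 0
                    for i in range(m - 1):
                        left1 += labs[i]
                        if vals[i + 1] <= vals[i]:
                            continue
                        nl = i + 1
                        nr = m - nl
                        r1 = c1 - left1
                        gl = 1.0 - (left1 / nl) ** 2 - ((nl - left1) / nl) ** 2
                        gr = 1.0 - (r1 / nr) ** 2 - ((nr - r1) / nr) ** 2
                        imp = nl * gl + nr * gr
                        if imp < best_imp:
                            best_imp = imp
                            best_feat = f
                            best_thr = 0.5 * (vals[i] + vals[i + 1])
                if best_feat < 0:
                    is_leaf = True
            if is_leaf:
                if 2 * c1 > m:
                    for i in range(lo, ho):
                        votes[oob[i], 1] += 1.0
                elif 2 * c1 < m:
                    for i in range(lo, ho):
                        votes[oob[i], 0] += 1.0
                else:
                    for i in range(lo, ho):
                        votes[oob[i], 0] += 0.5
                        votes[oob[i], 1] += 0.5
                continue
            # partition in-bag and OOB index ranges on the chosen split
            tmp_idx = np.empty(m, np.int64)
            nl = 0
            for i in range(li, hi):
                if X[inb[i], best_feat] <= best_thr:
                    tmp_idx[nl] = inb[i]
                    nl += 1
            nr = nl
            for i in range(li, hi):
                if X[inb[i], best_feat] > best_thr:
                    tmp_idx[nr] = inb[i]
                    nr += 1
            for i in range(m):
                inb[li + i] = tmp_idx[i]
            mo = ho - lo
            tmp_o = np.empty(mo, np.int64)
            ol = 0
            for i in range(lo, ho):
                if X[oob[i], best_feat] <= best_thr:
                    tmp_o[ol] = oob[i]
                    ol += 1
            orr = ol
            for i in range(lo, ho):
                if X[oob[i], best_feat] > best_thr:
                    tmp_o[orr] = oob[i]
                    orr += 1
            for i in range(mo):
                oob[lo + i] = tmp_o[i]
            stack_lo_i[top] = li
            stack_hi_i[top] = li + nl
            stack_lo_o[top] = lo
            stack_hi_o[top] = lo + ol
            top += 1
            stack_lo_i[top] = li + nl
            stack_hi_i[top] = hi
            stack_lo_o[top] = lo + ol
            stack_hi_o[top] = ho
            top += 1
    return votes


def oob_predictions(X, y, n_trees: int, seed: int) -> np.ndarray:
    """OOB majority-vote class predictions (ties toward class 0)."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.int64)
    mtry = max(1, int(np.sqrt(X.shape[1])))
    votes = _forest_oob_votes(X, y, int(n_trees), mtry, int(seed) % (2**31))
    return (votes[:, 1] > votes[:, 0]).astype(np.int64)


def oob_accuracy(X, y, n_trees: int, seed: int) -> float:
    """Fraction of subjects whose OOB majority vote matches their label."""
    pred = oob_predictions(X, y, n_trees, seed)
    return float((pred == np.asarray(y)).mean())
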