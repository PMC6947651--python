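"""Low-level CART kernels: weighted candidate sampling, split search, tree growth.

Everything here is numba-compiled and GIL-free so that sub-forests can be grown
on threads.  Randomness comes from an explicit splitmix64 state passed per
tree, never from global RNG state: this is what makes a forest bit-identical
for any worker count, given the same per-tree seeds.

Impurity-decrease conventions (pinned; the tests' brute-force oracles use the
same definitions):

* regression: raw sum-of-squared-deviations decrease,
  ``SS(parent) - SS(left) - SS(right)``;
* classification: child-fraction-weighted Gini decrease,
  ``G(parent) - (n_l/n) G(left) - (n_r/n) G(right)``.

Candidate thresholds are midpoints between consecutive distinct sorted values
of a candidate feature within the node; no minimum-child-size constraint is
applied to individual thresholds (a node is only *eligible* for splitting when
it holds at least ``2 * min_node_size`` samples).  Ties in impurity decrease
break toward the lowest feature index, then the lowest threshold.
"""

import numpy as np
from numba import njit

U64 = np.uint64

_GOLDEN = U64(0x9E3779B97F4A7C15)
_MIX1 = U64(0xBF58476D1CE4E5B9)
_MIX2 = U64(0x94D049BB133111EB)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53

REGRESSION = 0
CLASSIFICATION = 1


@njit(cache=True, nogil=True, inline="always")
def _next_u64(state):
    state[0] = state[0] + _GOLDEN
    z = state[0]
    z = (z ^ (z >> U64(30))) * _MIX1
    z = (z ^ (z >> U64(27))) * _MIX2
    return z ^ (z >> U64(31))


@njit(cache=True, nogil=True, inline="always")
def _rand_unit(state):
    """Uniform double in [0, 1) with 53 random bits."""
    return (_next_u64(state) >> U64(11)) * _INV53


@njit(cache=True, nogil=True)
def sample_candidates(weights, mtry, state):
    """Draw min(mtry, #positive-weight) distinct feature indices.

    Exponential-race keys (key_j = Exp(1) / w_j, keep the smallest) are
    distributionally identical to sequential weighted draws without
    replacement with renormalization.  Zero-weight features can never win.
    Returned indices are sorted ascending (the split search relies on this
    for deterministic tie-breaking).
    """
    p = weights.size
    keys = np.empty(p, np.float64)
    npos = 0
    for j in range(p):
        w = weights[j]
        if w > 0.0:
            keys[j] = -np.log(1.0 - _rand_unit(state)) / w
            npos += 1
        else:
            keys[j] = np.inf
    k = min(mtry, npos)
    order = np.argsort(keys)
    sel = np.empty(k, np.int64)
    for i in range(k):
        sel[i] = order[i]
    return np.sort(sel)


@njit(cache=True, nogil=True)
def best_split(X, y, samples, start, end, cand, task, n_classes):
    """Exhaustive best split over candidate features for one node.

    Returns (feature, threshold, decrease, n_left); feature == -1 signals
    that no candidate threshold yields a strictly positive decrease.
    """
    n = end - start
    best_dec = 0.0
    best_f = -1
    best_thr = 0.0
    best_nl = 0
    vals = np.empty(n, np.float64)

    if task == REGRESSION:
        s_tot = 0.0
        for i in range(n):
            s_tot += y[samples[start + i]]
        parent_term = s_tot * s_tot / n
        for ci in range(cand.size):
            f = cand[ci]
            for i in range(n):
                vals[i] = X[samples[start + i], f]
            order = np.argsort(vals)
            sl = 0.0
            for i in range(n - 1):
                sl += y[samples[start + order[i]]]
                v1 = vals[order[i]]
                v2 = vals[order[i + 1]]
                if v2 > v1:
                    nl = i + 1
                    nr = n - nl
                    sr = s_tot - sl
                    dec = sl * sl / nl + sr * sr / nr - parent_term
                    # relative tolerance: exact ties (equal partitions reached
                    # through different float summation orders) keep the
                    # earlier candidate = lowest feature, lowest threshold
                    if dec > best_dec + 1e-9 * (1.0 + best_dec):
                        best_dec = dec
                        best_f = f
                        best_thr = 0.5 * (v1 + v2)
                        best_nl = nl
    else:
        counts = np.zeros(n_classes, np.int64)
        counts_l = np.zeros(n_classes, np.int64)
        for i in range(n):
            counts[int(y[samples[start + i]])] += 1
        sq = 0.0
        for c in range(n_classes):
            sq += counts[c] * counts[c]
        gini_p = 1.0 - sq / (n * n)
        for ci in range(cand.size):
            f = cand[ci]
            for i in range(n):
                vals[i] = X[samples[start + i], f]
            order = np.argsort(vals)
            for c in range(n_classes):
                counts_l[c] = 0
            for i in range(n - 1):
                counts_l[int(y[samples[start + order[i]]])] += 1
                v1 = vals[order[i]]
                v2 = vals[order[i + 1]]
                if v2 > v1:
                    nl = i + 1
                    nr = n - nl
                    sq_l = 0.0
                    sq_r = 0.0
                    for c in range(n_classes):
                        cl = counts_l[c]
                        cr = counts[c] - cl
                        sq_l += cl * cl
                        sq_r += cr * cr
                    gini_l = 1.0 - sq_l / (nl * nl)
                    gini_r = 1.0 - sq_r / (nr * nr)
                    dec = gini_p - (nl / n) * gini_l - (nr / n) * gini_r
                    if dec > best_dec + 1e-9 * (1.0 + best_dec):
                        best_dec = dec
                        best_f = f
                        best_thr = 0.5 * (v1 + v2)
                        best_nl = nl
    return best_f, best_thr, best_dec, best_nl


@njit(cache=True, nogil=True)
def grow_tree(X, y, weights, mtry, min_node_size, task, n_classes, seed, bootstrap):
    """Grow one CART tree; returns a flat-array tree representation.

    Arrays: feature (-1 at leaves), threshold, value (leaf prediction: mean
    for regression, majority class code for classification), left, right,
    decrease (impurity decrease at internal nodes), n_node (samples reaching
    the node), node_count.
    """
    m = X.shape[0]
    state = np.empty(1, np.uint64)
    state[0] = U64(seed)
    _next_u64(state)  # decorrelate consecutive raw seeds

    samples = np.empty(m, np.int64)
    if bootstrap == 1:
        for i in range(m):
            samples[i] = int(_next_u64(state) % U64(m))
    else:
        for i in range(m):
            samples[i] = i

    cap = 2 * m + 1
    feature = np.full(cap, -1, np.int64)
    threshold = np.zeros(cap, np.float64)
    value = np.zeros(cap, np.float64)
    left = np.full(cap, -1, np.int64)
    right = np.full(cap, -1, np.int64)
    decrease = np.zeros(cap, np.float64)
    n_node = np.zeros(cap, np.int64)

    stack = np.empty((m + 2, 3), np.int64)  # (node_id, start, end)
    stack[0, 0] = 0
    stack[0, 1] = 0
    stack[0, 2] = m
    top = 1
    node_count = 1
    tmp = np.empty(m, np.int64)
    counts = np.zeros(n_classes, np.int64)
    min_split = 2 * min_node_size
    if min_split < 2:
        min_split = 2

    while top > 0:
        top -= 1
        node = stack[top, 0]
        start = stack[top, 1]
        end = stack[top, 2]
        n = end - start
        n_node[node] = n

        pure = False
        if task == REGRESSION:
            s = 0.0
            q = 0.0
            for i in range(start, end):
                yy = y[samples[i]]
                s += yy
                q += yy * yy
            value[node] = s / n
            ss_p = q - s * s / n
            if ss_p <= 1e-12 * max(1.0, q):
                pure = True
        else:
            for c in range(n_classes):
                counts[c] = 0
            for i in range(start, end):
                counts[int(y[samples[i]])] += 1
            best_c = 0
            nz = 0
            for c in range(n_classes):
                if counts[c] > counts[best_c]:
                    best_c = c
                if counts[c] > 0:
                    nz += 1
            value[node] = float(best_c)
            if nz <= 1:
                pure = True

        if pure or n < min_split:
            continue

        cand = sample_candidates(weights, mtry, state)
        f, thr, dec, nl = best_split(X, y, samples, start, end, cand, task, n_classes)
        if f < 0 or dec <= 0.0:
            continue

        # stable partition: left block keeps samples with X[., f] <= thr
        k = 0
        for i in range(start, end):
            if X[samples[i], f] > thr:
                tmp[k] = samples[i]
                k += 1
        j = start
        for i in range(start, end):
            if X[samples[i], f] <= thr:
                samples[j] = samples[i]
                j += 1
        for i in range(k):
            samples[j + i] = tmp[i]

        feature[node] = f
        threshold[node] = thr
        decrease[node] = dec
        left[node] = node_count
        right[node] = node_count + 1
        stack[top, 0] = node_count
        stack[top, 1] = start
        stack[top, 2] = start + nl
        stack[top + 1, 0] = node_count + 1
        stack[top + 1, 1] = start + nl
        stack[top + 1, 2] = end
        top += 2
        node_count += 2

    return (
        feature[:node_count].copy(),
        threshold[:node_count].copy(),
        value[:node_count].copy(),
        left[:node_count].copy(),
        right[:node_count].copy(),
        decrease[:node_count].copy(),
        n_node[:node_count].copy(),
    )


@njit(cache=True, nogil=True)
def predict_tree(feature, threshold, left, right, value, X, out):
    for i in range(X.shape[0]):
        node = 0
        while feature[node] >= 0:
            if X[i, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = value[node]
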