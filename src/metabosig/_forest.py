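"""Compact random-forest classifier compiled with numba.

The exhaustive subset screen fits tens of thousands of small forests
(tens of training samples, at most a handful of features); a
general-purpose implementation spends more time in per-fit bookkeeping
than in tree building at that scale. This module implements the standard
algorithm directly — bootstrap resampling per tree, Gini-impurity CART
splits on sqrt(p) randomly drawn features, full-depth growth, majority
vote per tree — and scores held-out samples by the fraction of trees
voting for the positive class.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _build_tree(X, y, boot_idx, max_features, seed):
    """Grow one CART tree on the bootstrap sample; returns node arrays.

    node_feature = -1 marks a leaf; node_value holds the leaf's majority
    class (ties resolved toward class 1, matching vote-fraction scoring).
    """
    np.random.seed(seed)
    n = boot_idx.shape[0]
    p = X.shape[1]
    max_nodes = 4 * n + 8
    node_feature = np.full(max_nodes, -1, dtype=np.int64)
    node_thresh = np.zeros(max_nodes)
    node_left = np.zeros(max_nodes, dtype=np.int64)
    node_right = np.zeros(max_nodes, dtype=np.int64)
    node_value = np.zeros(max_nodes)

    samples = boot_idx.copy()
    # stack of (node_id, start, end)
    stack = np.zeros((max_nodes, 3), dtype=np.int64)
    stack[0] = (0, 0, n)
    stack_size = 1
    n_nodes = 1

    while stack_size > 0:
        stack_size -= 1
        node_id, start, end = stack[stack_size]
        m = end - start
        ones = 0
        for i in range(start, end):
            ones += y[samples[i]]
        if ones == 0 or ones == m or m < 2:
            node_value[node_id] = 1.0 if 2 * ones >= m else 0.0
            continue

        best_feat = -1
        best_thresh = 0.0
        best_score = 1.0e18
        for _ in range(max_features):
            fi = np.random.randint(0, p)
            vals = np.empty(m)
            for i in range(m):
                vals[i] = X[samples[start + i], fi]
            order = np.argsort(vals)
            left1 = 0.0
            for i in range(m - 1):
                left1 += y[samples[start + order[i]]]
                if vals[order[i + 1]] <= vals[order[i]]:
                    continue
                nl = i + 1.0
                nr = m - nl
                r1 = ones - left1
                gini = nl * (1.0 - (left1 / nl) ** 2 - ((nl - left1) / nl) ** 2) + nr * (
                    1.0 - (r1 / nr) ** 2 - ((nr - r1) / nr) ** 2
                )
                if gini < best_score:
                    best_score = gini
                    best_feat = fi
                    best_thresh = 0.5 * (vals[order[i]] + vals[order[i + 1]])
        if best_feat < 0:
            node_value[node_id] = 1.0 if 2 * ones >= m else 0.0
            continue

        # partition samples[start:end] in place
        mid = start
        for i in range(start, end):
            if X[samples[i], best_feat] <= best_thresh:
                samples[mid], samples[i] = samples[i], samples[mid]
                mid += 1
        if mid == start or mid == end:  # degenerate split
            node_value[node_id] = 1.0 if 2 * ones >= m else 0.0
            continue

        left_id = n_nodes
        right_id = n_nodes + 1
        n_nodes += 2
        node_feature[node_id] = best_feat
        node_thresh[node_id] = best_thresh
        node_left[node_id] = left_id
        node_right[node_id] = right_id
        stack[stack_size] = (left_id, start, mid)
        stack[stack_size + 1] = (right_id, mid, end)
        stack_size += 2

    return node_feature[:n_nodes], node_thresh[:n_nodes], node_left[:n_nodes], node_right[:n_nodes], node_value[:n_nodes]


@njit(cache=True)
def _predict_tree(node_feature, node_thresh, node_left, node_right, node_value, X):
    n = X.shape[0]
    out = np.empty(n)
    for i in range(n):
        node = 0
        while node_feature[node] >= 0:
            if X[i, node_feature[node]] <= node_thresh[node]:
                node = node_left[node]
            else:
                node = node_right[node]
        out[i] = node_value[node]
    return out


@njit(cache=True)
def forest_vote_fractions(X_train, y_train, X_test, n_trees, seed):
    """Fraction of trees voting class 1 for each test sample."""
    n = X_train.shape[0]
    p = X_train.shape[1]
    max_features = max(1, int(np.sqrt(p)))
    votes = np.zeros(X_test.shape[0])
    np.random.seed(seed)
    tree_seeds = np.random.randint(0, 2**31 - 1, n_trees)
    for t in range(n_trees):
        np.random.seed(tree_seeds[t])
        boot = np.random.randint(0, n, n)
        nodes = _build_tree(X_train, y_train, boot, max_features, tree_seeds[t] + 1)
        votes += _predict_tree(nodes[0], nodes[1], nodes[2], nodes[3], nodes[4], X_test)
    return votes / n_trees
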