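"""Exact Shapley values for gradient-boosted tree ensembles.

For each tree, the value function v(S) of a feature coalition S is the
path-dependent conditional expectation: decision nodes whose feature is
in S route by the sample's value, others split flow proportionally to
training cover.  With at most a few candidate features the Shapley sum
is enumerated exactly over all coalitions of the features each tree
actually uses (features absent from a tree are null players), and tree
contributions add by linearity.  Local accuracy —
base + sum(phi) = prediction — holds to floating-point precision.
"""

from __future__ import annotations

from math import factorial

import numpy as np

_MAX_ENUM_FEATURES = 16


def _tree_subset_expectations(tree, X: np.ndarray, used: np.ndarray) -> np.ndarray:
    """v(S) for every subset S of ``used`` features; returns (2^m, n)."""
    left = tree.children_left
    right = tree.children_right
    feature = tree.feature
    threshold = tree.threshold
    value = tree.value[:, 0, 0]
    cover = tree.weighted_n_node_samples

    m = used.size
    n = X.shape[0]
    pos = {int(f): i for i, f in enumerate(used)}
    out = np.empty((1 << m, n))
    for s in range(1 << m):
        total = np.zeros(n)
        stack: list[tuple[int, np.ndarray | float]] = [(0, 1.0)]
        while stack:
            node, w = stack.pop()
            if left[node] == -1:  # leaf
                total += w * value[node]
                continue
            f = feature[node]
            if s >> pos[f] & 1:
                go_left = X[:, f] <= threshold[node]
                stack.append((left[node], w * go_left))
                stack.append((right[node], w * (~go_left)))
            else:
                frac = cover[left[node]] / cover[node]
                stack.append((left[node], w * frac))
                stack.append((right[node], w * (1.0 - frac)))
        out[s] = total
    return out


def _tree_phi(tree, X: np.ndarray, phi: np.ndarray, scale: float) -> None:
    """Accumulate scaled Shapley values of one tree into ``phi`` (n, p)."""
    used = np.unique(tree.feature[tree.feature >= 0])
    if used.size == 0:  # stump with a single leaf: no attribution
        return
    if used.size > _MAX_ENUM_FEATURES:
        raise ValueError(f"tree uses {used.size} features; exact enumeration capped at {_MAX_ENUM_FEATURES}")
    m = used.size
    v = _tree_subset_expectations(tree, X, used)
    fact = [factorial(k) for k in range(m + 1)]
    weights = [fact[k] * fact[m - k - 1] / fact[m] for k in range(m)]
    for i, f in enumerate(used):
        bit = 1 << i
        for s in range(1 << m):
            if s & bit:
                continue
            w = weights[bin(s).count("1")]
            phi[:, f] += scale * w * (v[s | bit] - v[s])


def ensemble_shapley(trees, X: np.ndarray, n_features: int, learning_rate: float, init_value: float):
    """Shapley values for a boosted ensemble of regression trees.

    ``trees`` is an iterable of fitted ``sklearn.tree._tree.Tree``
    objects whose (learning-rate scaled) outputs add to the raw
    prediction on top of ``init_value``.  Returns ``(phi, base)`` with
    ``phi`` of shape (n, n_features) and scalar ``base`` equal to the
    ensemble's expectation under the cover distribution.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    n = X.shape[0]
    phi = np.zeros((n, n_features))
    base = float(init_value)
    for tree in trees:
        _tree_phi(tree, X, phi, learning_rate)
        base += learning_rate * _root_expectation(tree)
    return phi, base


def _root_expectation(tree) -> float:
    """Cover-weighted mean leaf value (= v(empty set))."""
    left = tree.children_left
    leaf = left == -1
    cover = tree.weighted_n_node_samples[leaf]
    values = tree.value[leaf, 0, 0]
    return float((cover * values).sum() / cover.sum())


def brute_force_shapley(predict_expect, n_features: int, X: np.ndarray) -> np.ndarray:
    """Reference Shapley enumeration over ALL feature subsets.

    ``predict_expect(X, in_S)`` must return the coalition expectation
    for every row of X given a boolean feature-inclusion vector.  Meant
    for tests on small models; cost is O(2^p).
    """
    n, p = X.shape[0], n_features
    fact = [factorial(k) for k in range(p + 1)]
    v = {}
    for s in range(1 << p):
        in_s = np.array([(s >> i) & 1 == 1 for i in range(p)])
        v[s] = predict_expect(X, in_s)
    phi = np.zeros((n, p))
    for i in range(p):
        bit = 1 << i
        for s in range(1 << p):
            if s & bit:
                continue
            w = fact[bin(s).count("1")] * fact[p - bin(s).count("1") - 1] / fact[p]
            phi[:, i] += w * (v[s | bit] - v[s])
    return phi
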