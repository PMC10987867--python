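"""Path-dependent Shapley additive attributions for decision-tree ensembles.

Implements the polynomial-time tree traversal that yields, for each
sample and feature, the exact Shapley value of the set function

    v(S) = E[f(x) | x_S],

where the conditional expectation over "missing" features follows the
tree's own cover (training-sample) proportions at each split.  The
per-sample attributions plus the tree's expected value reconstruct the
model output exactly, which the test suite checks both against that
additivity identity and against brute-force coalition enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# A path element is [feature_index, zero_fraction, one_fraction, pweight].


def _extend(m: list[list[float]], pz: float, po: float, pi: int) -> list[list[float]]:
    m = [row[:] for row in m]
    m.append([pi, pz, po, 1.0 if len(m) == 0 else 0.0])
    l = len(m)
    for i in range(l - 2, -1, -1):
        m[i + 1][3] += po * m[i][3] * (i + 1) / l
        m[i][3] = pz * m[i][3] * (l - 1 - i) / l
    return m


def _unwind(m: list[list[float]], i: int) -> list[list[float]]:
    m = [row[:] for row in m]
    l = len(m)
    o, z = m[i][2], m[i][1]
    n = m[l - 1][3]
    for j in range(l - 2, -1, -1):
        if o != 0:
            t = m[j][3]
            m[j][3] = n * l / ((j + 1) * o)
            n = t - m[j][3] * z * (l - 1 - j) / l
        else:
            m[j][3] = m[j][3] * l / (z * (l - 1 - j))
    for j in range(i, l - 1):
        m[j][0], m[j][1], m[j][2] = m[j + 1][0], m[j + 1][1], m[j + 1][2]
    m.pop()
    return m


def _unwound_sum(m: list[list[float]], i: int) -> float:
    l = len(m)
    o, z = m[i][2], m[i][1]
    n = m[l - 1][3]
    total = 0.0
    for j in range(l - 2, -1, -1):
        if o != 0:
            tmp = n * l / ((j + 1) * o)
            total += tmp
            n = m[j][3] - tmp * z * (l - 1 - j) / l
        else:
            total += m[j][3] * l / (z * (l - 1 - j))
    return total


@dataclass(frozen=True)
class TreeArrays:
    """Flat arrays describing one decision tree with scalar leaf values."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    value: np.ndarray  # scalar per node (meaningful at leaves)
    node_weight: np.ndarray  # training cover per node

    def is_leaf(self, node: int) -> bool:
        return self.children_left[node] < 0


def sklearn_tree_arrays(estimator, class_index: int = 1) -> TreeArrays:
    """Extract :class:`TreeArrays` from a fitted sklearn decision tree.

    For classifiers the leaf value is the class-``class_index``
    probability, matching ``predict_proba``.
    """
    t = estimator.tree_
    value = t.value
    if value.ndim == 3 and value.shape[2] > 1:
        sums = value.sum(axis=2, keepdims=True)
        probs = np.divide(value, sums, out=np.zeros_like(value), where=sums > 0)
        leaf_value = probs[:, 0, class_index]
    else:
        leaf_value = value.reshape(len(t.threshold))
    return TreeArrays(
        children_left=t.children_left,
        children_right=t.children_right,
        feature=t.feature,
        threshold=t.threshold,
        value=np.asarray(leaf_value, dtype=float),
        node_weight=np.asarray(t.weighted_n_node_samples, dtype=float),
    )


def expected_value(tree: TreeArrays, node: int = 0) -> float:
    """Cover-weighted expectation of the tree output (v of the empty set)."""
    if tree.is_leaf(node):
        return float(tree.value[node])
    l, r = int(tree.children_left[node]), int(tree.children_right[node])
    wl, wr = tree.node_weight[l], tree.node_weight[r]
    return (wl * expected_value(tree, l) + wr * expected_value(tree, r)) / (wl + wr)


def tree_shap_values(tree: TreeArrays, x: np.ndarray) -> np.ndarray:
    """Shapley attributions of one sample for one tree."""
    x = np.asarray(x, dtype=float)
    phi = np.zeros(x.size)

    def recurse(node: int, m: list[list[float]], pz: float, po: float, pi: int) -> None:
        m = _extend(m, pz, po, pi)
        if tree.is_leaf(node):
            leaf = tree.value[node]
            for i in range(1, len(m)):
                w = _unwound_sum(m, i)
                phi[m[i][0]] += w * (m[i][2] - m[i][1]) * leaf
            return
        f = int(tree.feature[node])
        left, right = int(tree.children_left[node]), int(tree.children_right[node])
        hot, cold = (left, right) if x[f] <= tree.threshold[node] else (right, left)
        iz, io = 1.0, 1.0
        k = next((i for i in range(1, len(m)) if m[i][0] == f), None)
        if k is not None:
            iz, io = m[k][1], m[k][2]
            m = _unwind(m, k)
        w_node = tree.node_weight[node]
        recurse(hot, m, iz * tree.node_weight[hot] / w_node, io, f)
        recurse(cold, m, iz * tree.node_weight[cold] / w_node, 0.0, f)

    recurse(0, [], 1.0, 1.0, -1)
    return phi


def ensemble_shap_values(trees: list[TreeArrays], X: np.ndarray) -> tuple[np.ndarray, float]:
    """Mean per-tree attributions and base value for a tree ensemble whose
    prediction is the mean of its trees (random/extra forests)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    phi = np.zeros_like(X)
    for tree in trees:
        for i in range(X.shape[0]):
            phi[i] += tree_shap_values(tree, X[i])
    phi /= len(trees)
    base = float(np.mean([expected_value(t) for t in trees]))
    return phi, base
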