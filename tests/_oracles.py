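"""Independent brute-force oracles used to validate the implementations.

Everything here is deliberately naive — enumeration, repetition, direct
formulas — and shares no code with the package paths it checks.
"""

from __future__ import annotations

from itertools import combinations
from math import factorial

import numpy as np


def decile_means_by_repetition(x: np.ndarray) -> np.ndarray:
    """Mean voltage per 10% section via upsample-to-divisible repetition.

    Repeating every sample 10 times makes the length a multiple of 10, so
    the ten sections are plain windows whose means can be computed naively.
    """
    up = np.repeat(np.asarray(x, dtype=float), 10)
    w = up.size // 10
    return np.array([up[i * w : (i + 1) * w].mean() for i in range(10)])


def transition_scan(r: np.ndarray, s: np.ndarray, eps: float = 1e-6, cap: float = 1e6) -> int:
    """First-dominant-lead scan over explicit R/S amplitude tuples."""
    for k in range(6):
        if s[k] > eps:
            ratio = r[k] / s[k]
        elif r[k] <= eps:
            ratio = 0.0
        else:
            ratio = cap
        if ratio >= 1.0:
            return k + 1
    return 7


def tree_expvalue(tree, x: np.ndarray, S: set, node: int = 0) -> float:
    """Cover-weighted conditional expectation of a tree given features S."""
    if tree.is_leaf(node):
        return float(tree.value[node])
    f = int(tree.feature[node])
    left, right = int(tree.children_left[node]), int(tree.children_right[node])
    if f in S:
        child = left if x[f] <= tree.threshold[node] else right
        return tree_expvalue(tree, x, S, child)
    wl, wr = tree.node_weight[left], tree.node_weight[right]
    return (wl * tree_expvalue(tree, x, S, left) + wr * tree_expvalue(tree, x, S, right)) / (wl + wr)


def brute_force_shapley(tree, x: np.ndarray, n_features: int) -> np.ndarray:
    """Exact Shapley values by enumeration over all feature coalitions."""
    phi = np.zeros(n_features)
    features = list(range(n_features))
    for i in features:
        rest = [f for f in features if f != i]
        for size in range(n_features):
            for S in combinations(rest, size):
                weight = factorial(size) * factorial(n_features - size - 1) / factorial(n_features)
                S = set(S)
                phi[i] += weight * (tree_expvalue(tree, x, S | {i}) - tree_expvalue(tree, x, S))
    return phi


def greedy_ward_merges(X: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Greedy Ward agglomeration by exhaustive pair search.

    At each step every pair of current clusters is scored with the Ward
    merge height sqrt(2 * |A||B|/(|A|+|B|)) * ||centroid_A - centroid_B||
    and the minimum is merged.  Returns the merge sequence with heights.
    """
    X = np.asarray(X, dtype=float)
    clusters: list[frozenset] = [frozenset([i]) for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(clusters, 2):
            ca, cb = X[list(a)].mean(axis=0), X[list(b)].mean(axis=0)
            na, nb = len(a), len(b)
            h = np.sqrt(2.0 * na * nb / (na + nb)) * np.linalg.norm(ca - cb)
            if best is None or h < best[2]:
                best = (a, b, h)
        a, b, h = best
        merges.append(best)
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return merges
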