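"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the library's own code paths: shortest paths by
exhaustive simple-path enumeration, and the metric formulas transcribed
literally from their defining ratios.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_shortest_paths(weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by enumerating every simple path.

    ``weights``: dense symmetric matrix with np.inf for non-edges and 0 on
    the diagonal.  Exponential; only for N <= ~8.
    """
    n = weights.shape[0]
    best = np.full((n, n), np.inf)
    np.fill_diagonal(best, 0.0)

    def extend(path, cost, target_row):
        last = path[-1]
        if cost < best[target_row][last]:
            best[target_row][last] = cost
        for nxt in range(n):
            if nxt in path:
                continue
            w = weights[last, nxt]
            if np.isfinite(w):
                extend(path + [nxt], cost + w, target_row)

    for start in range(n):
        extend([start], 0.0, start)
    return best


def literal_metrics(TP: int, FP: int, TN: int, FN: int) -> dict:
    """Direct transcription of the six confusion-matrix metric formulas,
    with the same zero-denominator-to-zero convention as the library."""
    def div(a, b):
        return a / b if b != 0 else 0.0

    sen = div(TP, TP + FN)
    spe = div(TN, TN + FP)
    pre = div(TP, TP + FP)
    f1 = div(2 * sen * pre, sen + pre)
    acc = div(TP + TN, TP + TN + FP + FN)
    mcc = div(TP * TN - FP * FN,
              math.sqrt((TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)))
    return {"SEN": sen, "SPE": spe, "PRE": pre, "F1": f1, "ACC": acc, "MCC": mcc}


def pairwise_auc(y_true, scores) -> float:
    """AUC by exhaustive positive-negative pair counting, ties half."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def random_connected_graph(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random connected weighted graph as a dense weight matrix."""
    while True:
        adj = rng.random((n, n)) < 0.45
        adj = np.triu(adj, 1)
        adj = adj | adj.T
        # connectivity check by BFS
        seen = {0}
        frontier = [0]
        while frontier:
            v = frontier.pop()
            for u in np.nonzero(adj[v])[0]:
                if u not in seen:
                    seen.add(int(u))
                    frontier.append(int(u))
        if len(seen) == n:
            break
    weights = np.where(adj, rng.uniform(0.1, 5.0, (n, n)), np.inf)
    weights = np.minimum(weights, weights.T)
    np.fill_diagonal(weights, 0.0)
    return weights
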