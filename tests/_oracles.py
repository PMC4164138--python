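"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's scoring code paths: topologies are
enumerated as plain edge lists, parsimony scores come from a dense
dynamic program over the full cost matrix, Fitch lengths from the classic
set-intersection pass, and hypergeometric tails from explicit enumeration
of draws.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def all_unrooted_trees(n_tips: int) -> list[list[tuple[int, int]]]:
    """Every unrooted binary tree over tips 0..n-1, as edge lists.

    Internal nodes are labeled from n_tips upward.  Counts follow the
    double factorial (2n-5)!!: 1, 3, 15, 105, 945 for n = 4..8.
    """
    if n_tips < 3:
        raise ValueError("need >= 3 tips")
    first = [(0, n_tips), (1, n_tips), (2, n_tips)]
    trees = [(first, n_tips + 1)]
    for tip in range(3, n_tips):
        nxt = []
        for edges, next_id in trees:
            for i, (u, v) in enumerate(edges):
                new = edges[:i] + edges[i + 1:] + [
                    (u, next_id), (next_id, v), (next_id, tip)]
                nxt.append((new, next_id + 1))
        trees = nxt
    return [e for e, _ in trees]


def sankoff_score(edges: list[tuple[int, int]], states: np.ndarray,
                  cost: np.ndarray) -> int:
    """Minimum total cost of all characters on the tree, dense DP."""
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    n_tips, n_chars = states.shape
    k = cost.shape[0]
    big = 10**9
    root = next(n for n in adj if len(adj[n]) > 1)
    order: list[tuple[int, int | None]] = []
    stack = [(root, None)]
    while stack:
        node, par = stack.pop()
        order.append((node, par))
        for nb in adj[node]:
            if nb != par:
                stack.append((nb, node))
    vec: dict[int, np.ndarray] = {}
    for node, par in reversed(order):
        if len(adj[node]) == 1 and node < n_tips:
            v = np.full((n_chars, k), big, dtype=np.int64)
            v[np.arange(n_chars), states[node]] = 0
        else:
            v = np.zeros((n_chars, k), dtype=np.int64)
            for nb in adj[node]:
                if nb != par:
                    child = vec[nb]
                    v = v + np.min(child[:, None, :] + cost[None, :, :], axis=2)
        vec[node] = v
    return int(vec[root].min(axis=1).sum())


def fitch_length(edges: list[tuple[int, int]], column: np.ndarray) -> int:
    """Unordered parsimony steps of one character via Fitch's algorithm."""
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    n_tips = len(column)
    root = next(n for n in adj if len(adj[n]) > 1)
    order: list[tuple[int, int | None]] = []
    stack = [(root, None)]
    while stack:
        node, par = stack.pop()
        order.append((node, par))
        for nb in adj[node]:
            if nb != par:
                stack.append((nb, node))
    steps = 0
    sets: dict[int, frozenset[int]] = {}
    for node, par in reversed(order):
        if len(adj[node]) == 1 and node < n_tips:
            sets[node] = frozenset({int(column[node])})
            continue
        acc: frozenset[int] | None = None
        for nb in adj[node]:
            if nb == par:
                continue
            s = sets[nb]
            if acc is None:
                acc = s
            elif acc & s:
                acc = acc & s
            else:
                acc = acc | s
                steps += 1
        sets[node] = acc
    return steps


def hypergeom_tail_enum(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by enumerating all C(N, n) draws (tiny N only)."""
    population = [1] * K + [0] * (N - K)
    total = hits = 0
    for draw in combinations(range(N), n):
        total += 1
        if sum(population[i] for i in draw) >= k:
            hits += 1
    return hits / total


def hypergeom_tail_compact(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by summing binomial products (exact integer arithmetic)."""
    num = sum(math.comb(K, i) * math.comb(N - K, n - i)
              for i in range(k, min(K, n) + 1) if n - i <= N - K)
    return num / math.comb(N, n)
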