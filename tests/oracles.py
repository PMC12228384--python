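"""Independent reference implementations used only by the tests.

These deliberately avoid sharing code paths with the package: brute-force
enumeration, rational arithmetic, and direct textbook definitions.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import networkx as nx
import numpy as np


def bh_stepup_oracle(p: np.ndarray) -> np.ndarray:
    """Textbook BH step-up: adj_(i) = min_{j >= i} p_(j) * n / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    for rank_pos in range(n):
        candidates = [p[order[j]] * n / (j + 1) for j in range(rank_pos, n)]
        adj[order[rank_pos]] = min(1.0, min(candidates))
    return adj


def betweenness_enumeration_oracle(g: nx.Graph) -> dict:
    """Ordered-pair betweenness by explicitly enumerating shortest paths."""
    bc = dict.fromkeys(g.nodes, 0.0)
    for s in g.nodes:
        for t in g.nodes:
            if s == t:
                continue
            try:
                paths = list(nx.all_shortest_paths(g, s, t))
            except nx.NetworkXNoPath:
                continue
            for v in g.nodes:
                if v in (s, t):
                    continue
                through = sum(v in path for path in paths)
                bc[v] += through / len(paths)
    return bc


def hypergeom_tail_rational(k: int, K: int, n: int, N: int) -> Fraction:
    """Exact P(X >= k) via rational binomial-coefficient arithmetic."""
    total = comb(N, n)
    return sum(
        (Fraction(comb(K, i) * comb(N - K, n - i), total)
         for i in range(k, min(K, n) + 1)),
        Fraction(0),
    )


def hypergeom_tail_enumeration(k: int, K: int, n: int, N: int) -> Fraction:
    """Exact P(X >= k) by enumerating every possible n-draw from N items."""
    marked = set(range(K))
    hits = 0
    total = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return Fraction(hits, total)


def random_connected_graph(rng: np.random.Generator, n_max: int = 8,
                           p_edge: float = 0.4) -> nx.Graph:
    """Random connected undirected graph with 2..n_max nodes."""
    while True:
        n = int(rng.integers(2, n_max + 1))
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p_edge:
                    g.add_edge(i, j)
        if nx.is_connected(g):
            return g
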