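"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library code paths they check:
components by hand-written breadth-first flood fill, betweenness by
explicit all-pairs geodesic enumeration, Fisher's test by exact
fixed-margin table enumeration with rational arithmetic, and the rank-sum
test by enumeration over rank assignments.
"""

from __future__ import annotations

import itertools
import math
from collections import deque
from fractions import Fraction

import numpy as np
import pytest

from mdset.core_network import ProteinNetwork


# -- graph construction helpers -------------------------------------------


def random_network(
    n: int, p: float, rng: np.random.Generator, prefix: str = "n"
) -> ProteinNetwork:
    """Erdős–Rényi G(n, p) over string node identifiers."""
    names = [f"{prefix}{i:03d}" for i in range(n)]
    edges = [
        (names[i], names[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return ProteinNetwork(edges, nodes=names)


def path_network(n: int) -> ProteinNetwork:
    names = [f"v{i}" for i in range(n)]
    return ProteinNetwork(list(zip(names, names[1:])), nodes=names)


def cycle_network(n: int) -> ProteinNetwork:
    names = [f"v{i}" for i in range(n)]
    edges = list(zip(names, names[1:])) + [(names[-1], names[0])]
    return ProteinNetwork(edges, nodes=names)


def star_network(n_leaves: int) -> ProteinNetwork:
    return ProteinNetwork([("hub", f"leaf{i}") for i in range(n_leaves)])


def complete_network(n: int) -> ProteinNetwork:
    names = [f"v{i}" for i in range(n)]
    return ProteinNetwork(
        [(a, b) for a, b in itertools.combinations(names, 2)]
    )


# -- independent oracles --------------------------------------------------


def flood_fill_components(net: ProteinNetwork) -> list[set[str]]:
    """Component partition by explicit breadth-first flooding."""
    unseen = set(net.nodes)
    out = []
    while unseen:
        start = unseen.pop()
        comp = {start}
        queue = deque([start])
        while queue:
            v = queue.popleft()
            for w in net.neighbors(v):
                if w in unseen:
                    unseen.discard(w)
                    comp.add(w)
                    queue.append(w)
        out.append(comp)
    return out


def brute_force_betweenness(net: ProteinNetwork) -> dict[str, float]:
    """c_B by enumerating every geodesic between every unordered pair."""

    def bfs_dist(src: str) -> dict[str, int]:
        dist = {src: 0}
        queue = deque([src])
        while queue:
            v = queue.popleft()
            for w in net.neighbors(v):
                if w not in dist:
                    dist[w] = dist[v] + 1
                    queue.append(w)
        return dist

    def all_shortest_paths(s: str, t: str, dist: dict[str, int]) -> list[list[str]]:
        if t not in dist:
            return []
        paths = []

        def extend(partial: list[str]) -> None:
            v = partial[-1]
            if v == t:
                paths.append(partial)
                return
            for w in net.neighbors(v):
                if dist.get(w, -1) == dist[v] + 1 and dist[t] >= dist[w]:
                    extend(partial + [w])

        extend([s])
        return paths

    scores = {v: 0.0 for v in net.nodes}
    order = net.node_order
    for i, s in enumerate(order):
        dist = bfs_dist(s)
        for t in order[i + 1 :]:
            paths = all_shortest_paths(s, t, dist)
            if not paths:
                continue
            sigma = len(paths)
            for v in net.nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p[1:-1])
                scores[v] += through / sigma
    return scores


def enumerate_fisher_upper_tail(
    n_nodes: int, n_mdset: int, n_marked: int, n_overlap: int
) -> float:
    """Exact one-sided Fisher p by summing fixed-margin table masses."""
    total = Fraction(0)
    denom = math.comb(n_nodes, n_mdset)
    for x in range(n_overlap, min(n_mdset, n_marked) + 1):
        total += Fraction(
            math.comb(n_marked, x) * math.comb(n_nodes - n_marked, n_mdset - x),
            denom,
        )
    return float(total)


def exact_ranksum_p(a: list[float], b: list[float]) -> float:
    """Two-sided rank-sum p by enumeration over all rank assignments."""
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # assumes no ties
    obs = sum(ranks[v] for v in a)
    n = len(pooled)
    na = len(a)
    mean = na * (n + 1) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, n + 1), na):
        total += 1
        if abs(sum(combo) - mean) >= abs(obs - mean) - 1e-12:
            count += 1
    return count / total


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
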