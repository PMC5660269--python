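"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they validate: betweenness is
computed by explicit enumeration of every shortest path, hypergeometric
tails by enumerating every possible draw, and cohesiveness by a direct
edge scan over a candidate set.
"""

from __future__ import annotations

import itertools
from collections import deque
from math import comb


def brute_force_betweenness(G) -> dict:
    """Normalized betweenness by enumerating all shortest paths per pair."""
    nodes = sorted(G.nodes)
    n = len(nodes)
    raw = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        dist = {s: 0}
        parents: dict = {s: []}
        q = deque([s])
        while q:
            u = q.popleft()
            for v in G[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    parents[v] = [u]
                    q.append(v)
                elif dist[v] == dist[u] + 1:
                    parents[v].append(u)
        if t not in dist:
            continue  # different components contribute nothing
        paths: list[list] = []

        def walk(v, acc):
            if v == s:
                paths.append(acc)
                return
            for p in parents[v]:
                walk(p, [p] + acc)

        walk(t, [t])
        for path in paths:
            for v in path[1:-1]:
                raw[v] += 1.0 / len(paths)
    scale = 2.0 / ((n - 1) * (n - 2)) if n >= 3 else 0.0
    return {v: raw[v] * scale for v in nodes}


def brute_force_hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by enumerating all C(N, n) draws from an N-item urn with K
    marked items."""
    hits = set(range(K))
    favourable = 0
    for draw in itertools.combinations(range(N), n):
        if len(hits.intersection(draw)) >= k:
            favourable += 1
    return favourable / comb(N, n)


def direct_cohesiveness(G, members, penalty: float = 0.0) -> float:
    """Cohesiveness by direct scan over all graph edges."""
    members = set(members)
    w_in = w_bound = 0.0
    for u, v, data in G.edges(data=True):
        w = data.get("weight", 1.0)
        inside = (u in members) + (v in members)
        if inside == 2:
            w_in += w
        elif inside == 1:
            w_bound += w
    denom = w_in + w_bound + penalty * len(members)
    return w_in / denom if denom > 0 else 0.0


def is_local_optimum(G, members, seed_node, penalty: float = 0.0) -> bool:
    """True when no single boundary addition or non-seed removal raises the
    directly recomputed cohesiveness."""
    members = set(members)
    base = direct_cohesiveness(G, members, penalty)
    boundary = {v for m in members for v in G[m] if v not in members}
    for v in boundary:
        if direct_cohesiveness(G, members | {v}, penalty) > base + 1e-9:
            return False
    for v in members - {seed_node}:
        if direct_cohesiveness(G, members - {v}, penalty) > base + 1e-9:
            return False
    return True
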