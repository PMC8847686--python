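"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths of the package: betweenness is
computed by exhaustive enumeration of all shortest paths over a hand-written
BFS, closeness/NC/LAC come straight from their textbook definitions, the
hypergeometric tail is an exact rational sum, and BH is a naive double loop
over the sorted p-values.
"""

from __future__ import annotations

from collections import deque
from fractions import Fraction
from math import comb


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


def _adjacency(graph) -> dict:
    return {v: sorted(graph.neighbors(v)) for v in graph.nodes}


def _enumerate_shortest_paths(adj, dist, s, t):
    """All shortest s-t paths, walked backwards along the BFS level structure."""
    paths = []

    def extend(node, suffix):
        if node == s:
            paths.append([s] + suffix)
            return
        for u in adj[node]:
            if dist.get(u) == dist[node] - 1:
                extend(u, [node] + suffix)

    if t in dist:
        extend(t, [])
    return paths


def brute_betweenness(graph) -> dict:
    adj = _adjacency(graph)
    nodes = sorted(graph.nodes)
    scores = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        dist = bfs_distances(adj, s)
        for t in nodes[i + 1:]:
            if t not in dist:
                continue
            paths = _enumerate_shortest_paths(adj, dist, s, t)
            sigma = len(paths)
            for path in paths:
                for v in path[1:-1]:
                    scores[v] += 1.0 / sigma
    return scores


def brute_closeness(graph) -> dict:
    adj = _adjacency(graph)
    out = {}
    for v in graph.nodes:
        dist = bfs_distances(adj, v)
        c = len(dist)  # component size
        if c < 2:
            out[v] = 0.0
        else:
            out[v] = (c - 1) / sum(dist.values())
    return out


def brute_degree(graph) -> dict:
    return {v: len(set(graph.neighbors(v))) for v in graph.nodes}


def brute_neighborhood_connectivity(graph) -> dict:
    deg = brute_degree(graph)
    out = {}
    for v in graph.nodes:
        nbrs = list(graph.neighbors(v))
        out[v] = sum(deg[u] for u in nbrs) / len(nbrs) if nbrs else 0.0
    return out


def brute_lac(graph) -> dict:
    out = {}
    for v in graph.nodes:
        nbrs = set(graph.neighbors(v))
        if not nbrs:
            out[v] = 0.0
            continue
        total = 0
        for w in nbrs:
            total += sum(1 for x in graph.neighbors(w) if x in nbrs)
        out[v] = total / len(nbrs)
    return out


def exact_hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """P[X >= k] as an exact rational: sum of C(K,i) C(N-K,n-i) / C(N,n)."""
    total = Fraction(0)
    denom = comb(N, n)
    for i in range(k, min(K, n) + 1):
        if n - i > N - K:
            continue
        total += Fraction(comb(K, i) * comb(N - K, n - i), denom)
    return total


def naive_bh(p_values):
    """Step-up q-values by the definition: q_(i) = min_{j>=i} p_(j) m / j."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    for rank_pos, idx in enumerate(order):
        best = min(
            p_values[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        )
        q[idx] = min(1.0, best)
    return q
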