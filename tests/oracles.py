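"""Brute-force oracles, independent of the library code they check.

Shortest paths are found by exhaustive simple-path enumeration (feasible
for graphs of <= 8 nodes), from which the three normalized centralities
are assembled directly from their defining formulas.
"""

from __future__ import annotations

import itertools


def enumerate_shortest_paths(nodes, edges, s, t):
    """(min length, count of minimal paths) from s to t; (None, 0) if unreachable."""
    adj = {v: [] for v in nodes}
    for u, v in edges:
        adj[u].append(v)
    best: list[int | None] = [None]
    count = [0]

    def walk(v, length, seen):
        if best[0] is not None and length > best[0]:
            return
        if v == t:
            if best[0] is None or length < best[0]:
                best[0], count[0] = length, 1
            elif length == best[0]:
                count[0] += 1
            return
        for w in adj[v]:
            if w not in seen:
                walk(w, length + 1, seen | {w})

    walk(s, 0, frozenset({s}))
    return best[0], count[0]


def all_pairs(nodes, edges):
    """dist[s][t] and sigma[s][t] (shortest-path count) by enumeration."""
    dist, sigma = {}, {}
    for s in nodes:
        dist[s], sigma[s] = {}, {}
        for t in nodes:
            if s == t:
                dist[s][t], sigma[s][t] = 0, 1
            else:
                d, c = enumerate_shortest_paths(nodes, edges, s, t)
                dist[s][t], sigma[s][t] = d, c
    return dist, sigma


def in_degree_centrality(nodes, edges):
    n = len(nodes)
    indeg = {v: 0 for v in nodes}
    for _u, v in edges:
        indeg[v] += 1
    return {v: indeg[v] / (n - 1) for v in nodes}


def betweenness_centrality(nodes, edges):
    """Directed, normalized by (n-1)(n-2); pair dependency via path counts."""
    n = len(nodes)
    dist, sigma = all_pairs(nodes, edges)
    out = {}
    for v in nodes:
        total = 0.0
        for s, t in itertools.permutations(nodes, 2):
            if v in (s, t) or dist[s][t] is None:
                continue
            dsv, dvt = dist[s][v], dist[v][t]
            if dsv is None or dvt is None or dsv + dvt != dist[s][t]:
                continue
            total += sigma[s][v] * sigma[v][t] / sigma[s][t]
        out[v] = total / ((n - 1) * (n - 2)) if n > 2 else 0.0
    return out


def closeness_centrality(nodes, edges):
    """Incoming-distance closeness with the reachable-component correction."""
    n = len(nodes)
    dist, _ = all_pairs(nodes, edges)
    out = {}
    for v in nodes:
        reachers = [u for u in nodes if u != v and dist[u][v] is not None]
        total = sum(dist[u][v] for u in reachers)
        if total == 0:
            out[v] = 0.0
        else:
            r = len(reachers)
            out[v] = (r / total) * (r / (n - 1))
    return out
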