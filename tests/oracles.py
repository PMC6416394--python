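"""Independent brute-force reference implementations used only by tests.

Everything here is written from the definitions with plain Python loops and
a dense Floyd–Warshall distance matrix — deliberately sharing no code with
the package's BFS/caching implementations.
"""

from __future__ import annotations

import math


def floyd_warshall(graph) -> tuple:
    """Dense all-pairs distances; returns (sorted nodes, dict-of-dict)."""
    nodes = sorted(graph.nodes)
    dist = {u: {v: math.inf for v in nodes} for u in nodes}
    for u in nodes:
        dist[u][u] = 0.0
    for u, v in graph.edges:
        dist[u][v] = 1.0
        dist[v][u] = 1.0
    for k in nodes:
        dk = dist[k]
        for i in nodes:
            dik = dist[i][k]
            if dik == math.inf:
                continue
            di = dist[i]
            for j in nodes:
                alt = dik + dk[j]
                if alt < di[j]:
                    di[j] = alt
    return nodes, dist


def _mean_finite(values):
    finite = [v for v in values if math.isfinite(v)]
    if not finite:
        return math.nan
    return sum(finite) / len(finite)


def brute_closest(dist, a_set, b_set) -> float:
    terms = []
    for a in a_set:
        terms.append(min(dist[a][b] for b in b_set))
    for b in b_set:
        terms.append(min(dist[a][b] for a in a_set))
    return _mean_finite(terms)


def brute_shortest(dist, a_set, b_set) -> float:
    return _mean_finite([dist[a][b] for a in a_set for b in b_set])


def brute_kernel(dist, a_set, b_set) -> float:
    terms = []
    for a in a_set:
        s = sum(math.exp(-(dist[a][b] + 1)) for b in b_set if math.isfinite(dist[a][b]))
        terms.append(-math.log(s / len(b_set)) if s > 0 else math.inf)
    for b in b_set:
        s = sum(math.exp(-(dist[a][b] + 1)) for a in a_set if math.isfinite(dist[a][b]))
        terms.append(-math.log(s / len(a_set)) if s > 0 else math.inf)
    return _mean_finite(terms)


def _brute_centres(dist, nodes) -> list:
    ranked = []
    for u in nodes:
        finite = [dist[v][u] for v in nodes if math.isfinite(dist[v][u])]
        ranked.append((u, (-len(finite), sum(finite))))
    best = min(r for _, r in ranked)
    return [u for u, r in ranked if r == best]


def brute_centre(dist, a_set, b_set) -> float:
    ca = _brute_centres(dist, sorted(a_set))
    cb = _brute_centres(dist, sorted(b_set))
    return _mean_finite([dist[a][b] for a in ca for b in cb])


def brute_within(dist, nodes) -> float:
    nodes = sorted(nodes)
    if len(nodes) == 1:
        return 0.0
    terms = []
    for a in nodes:
        terms.append(min(dist[a][b] for b in nodes if b != a))
    return _mean_finite(terms)


def brute_separation(dist, a_set, b_set) -> float:
    d_ab = brute_closest(dist, a_set, b_set)
    return d_ab - (brute_within(dist, a_set) + brute_within(dist, b_set)) / 2.0


def brute_components(graph) -> list:
    """Connected components by flood fill; list of frozensets."""
    seen = set()
    comps = []
    for start in graph.nodes:
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in graph.adj[u]:
                if v not in comp:
                    comp.add(v)
                    stack.append(v)
        seen |= comp
        comps.append(frozenset(comp))
    return comps
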