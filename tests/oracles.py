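"""Independent brute-force graph-metric oracles for unit-weight graphs.

Everything here works from an explicit edge set by exhaustive
enumeration (paths, triangles, partitions) — no shared code with the
implementation under test.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def _neighbors(n, edges):
    nbr = {i: set() for i in range(n)}
    for a, b in edges:
        nbr[a].add(b)
        nbr[b].add(a)
    return nbr


def _all_simple_paths(nbr, s, t):
    """Yield every simple path from s to t (DFS enumeration)."""
    stack = [(s, [s])]
    while stack:
        node, path = stack.pop()
        if node == t:
            yield path
            continue
        for nxt in nbr[node]:
            if nxt not in path:
                stack.append((nxt, path + [nxt]))


def shortest_paths(nbr, s, t):
    """All minimum-length simple paths between s and t (unit weights)."""
    paths = list(_all_simple_paths(nbr, s, t))
    if not paths:
        return []
    dmin = min(len(p) for p in paths)
    return [p for p in paths if len(p) == dmin]


def oracle_degree_density(n, edges):
    degs = [0] * n
    for a, b in edges:
        degs[a] += 1
        degs[b] += 1
    return float(np.mean(degs)), 2.0 * len(edges) / (n * (n - 1))


def oracle_clustering(n, edges):
    """Per-node binary clustering: edges among neighbours / (k choose 2)."""
    nbr = _neighbors(n, edges)
    eset = {frozenset(e) for e in edges}
    cs = []
    for v in range(n):
        k = len(nbr[v])
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(1 for a, b in combinations(sorted(nbr[v]), 2)
                    if frozenset((a, b)) in eset)
        cs.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(cs))


def oracle_transitivity(n, edges):
    eset = {frozenset(e) for e in edges}
    triangles = sum(1 for a, b, c in combinations(range(n), 3)
                    if {frozenset((a, b)), frozenset((b, c)),
                        frozenset((a, c))} <= eset)
    nbr = _neighbors(n, edges)
    triplets = sum(len(nbr[v]) * (len(nbr[v]) - 1) // 2 for v in range(n))
    return 3.0 * triangles / triplets if triplets else 0.0


def _distance(nbr, s, t):
    sp = shortest_paths(nbr, s, t)
    return (len(sp[0]) - 1) if sp else np.inf


def oracle_paths(n, edges):
    """(char path length over connected pairs, global efficiency)."""
    nbr = _neighbors(n, edges)
    dists = [_distance(nbr, s, t) for s, t in combinations(range(n), 2)]
    finite = [d for d in dists if np.isfinite(d)]
    cpl = float(np.mean(finite)) if finite else np.inf
    geff = float(np.mean([1.0 / d if np.isfinite(d) else 0.0 for d in dists]))
    return cpl, geff


def oracle_local_efficiency(n, edges):
    nbr = _neighbors(n, edges)
    eset = {frozenset(e) for e in edges}
    effs = []
    for v in range(n):
        nv = sorted(nbr[v])
        if len(nv) < 2:
            effs.append(0.0)
            continue
        sub_edges = [(a, b) for a, b in combinations(nv, 2)
                     if frozenset((a, b)) in eset]
        remap = {node: i for i, node in enumerate(nv)}
        sub = [(remap[a], remap[b]) for a, b in sub_edges]
        _, geff = oracle_paths(len(nv), sub)
        effs.append(geff)
    return float(np.mean(effs))


def oracle_betweenness(n, edges):
    """(mean nodal, mean edge) betweenness; ties split equally."""
    nbr = _neighbors(n, edges)
    node_bw = {v: 0.0 for v in range(n)}
    edge_bw = {frozenset(e): 0.0 for e in edges}
    for s, t in combinations(range(n), 2):
        sp = shortest_paths(nbr, s, t)
        if not sp:
            continue
        frac = 1.0 / len(sp)
        for path in sp:
            for v in path[1:-1]:
                node_bw[v] += frac
            for a, b in zip(path, path[1:]):
                edge_bw[frozenset((a, b))] += frac
    mean_nodal = float(np.mean(list(node_bw.values())))
    mean_edge = float(np.mean(list(edge_bw.values()))) if edge_bw else 0.0
    return mean_nodal, mean_edge


def oracle_assortativity(n, edges):
    """Newman r: Pearson correlation of endpoint degrees over directed edges."""
    degs = [0] * n
    for a, b in edges:
        degs[a] += 1
        degs[b] += 1
    xs, ys = [], []
    for a, b in edges:
        xs.extend([degs[a], degs[b]])
        ys.extend([degs[b], degs[a]])
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    vx = ((xs - xs.mean()) ** 2).mean()
    if vx == 0:
        return float("nan")
    return float(((xs - xs.mean()) * (ys - ys.mean())).mean() / vx)


def _partitions(items):
    """Every set partition of ``items`` (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def oracle_max_modularity(n, edges):
    """Maximum Newman modularity over all partitions (exhaustive)."""
    m = len(edges)
    degs = [0] * n
    for a, b in edges:
        degs[a] += 1
        degs[b] += 1
    eset = {frozenset(e) for e in edges}
    best = -np.inf
    for part in _partitions(range(n)):
        q = 0.0
        for block in part:
            lc = sum(1 for a, b in combinations(sorted(block), 2)
                     if frozenset((a, b)) in eset)
            dc = sum(degs[v] for v in block)
            q += lc / m - (dc / (2.0 * m)) ** 2
        best = max(best, q)
    return float(best)
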