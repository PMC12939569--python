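"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written for clarity over speed and deliberately avoids
the production code paths: cleavage sites are evaluated bond by bond with
explicit indexing, centralities come from exhaustive path/clique/subset
enumeration, and the exact edge-percolation expectation sums over all 2^E
edge subsets.
"""

from __future__ import annotations

import itertools
import math
from collections import deque


# --------------------------------------------------------------- digestion


def brute_cleavage_sites(residues: str, specs, exceptions) -> list[int]:
    """Per-bond evaluation of a cleavage rule.

    ``specs``/``exceptions`` are lists of dicts mapping 'p2'/'p1'/'p1prime'/
    'p2prime' to residue sets. A bond i (0-based, between residues i and
    i+1) is cleaved iff neither flanking residue is 'X', some spec matches,
    and no exception matches; a constraint on an out-of-range position
    fails.
    """

    def spec_matches(spec: dict, bond: int) -> bool:
        offsets = {"p2": bond - 1, "p1": bond, "p1prime": bond + 1, "p2prime": bond + 2}
        for pos, allowed in spec.items():
            if allowed is None:
                continue
            idx = offsets[pos]
            if idx < 0 or idx >= len(residues):
                return False
            if residues[idx] not in allowed:
                return False
        return True

    sites = []
    for bond in range(len(residues) - 1):
        if residues[bond] == "X" or residues[bond + 1] == "X":
            continue
        if any(spec_matches(s, bond) for s in specs) and not any(
            spec_matches(e, bond) for e in exceptions
        ):
            sites.append(bond)
    return sites


# ------------------------------------------------------------- centralities
# Graphs are given as (nodes, edges) with hashable nodes and undirected
# edge tuples; adjacency is rebuilt locally.


def _adj(nodes, edges):
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def _bfs_dist(adj, source):
    dist = {source: 0}
    q = deque([source])
    while q:
        v = q.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                q.append(w)
    return dist


def _all_shortest_paths(adj, s, t):
    """All shortest s-t paths by exhaustive DFS with pruning on distance."""
    dist_from_t = _bfs_dist(adj, t)
    if s not in dist_from_t:
        return []
    paths = []

    def walk(v, path):
        if v == t:
            paths.append(list(path))
            return
        for w in adj[v]:
            if w not in path and dist_from_t.get(w, math.inf) == dist_from_t[v] - 1:
                path.append(w)
                walk(w, path)
                path.pop()

    walk(s, [s])
    return paths


def brute_degree(nodes, edges):
    adj = _adj(nodes, edges)
    return {v: float(len(adj[v])) for v in nodes}


def brute_mnc(nodes, edges):
    adj = _adj(nodes, edges)
    scores = {}
    for v in nodes:
        nbrs = adj[v]
        if not nbrs:
            scores[v] = 0.0
            continue
        sub_edges = [(a, b) for a, b in edges if a in nbrs and b in nbrs]
        sub_adj = _adj(nbrs, sub_edges)
        best = 0
        seen = set()
        for u in nbrs:
            if u in seen:
                continue
            comp = set(_bfs_dist(sub_adj, u))
            seen |= comp
            best = max(best, len(comp))
        scores[v] = float(best)
    return scores


def brute_mcc(nodes, edges):
    """Maximal-clique centrality by subset enumeration."""
    nodes = list(nodes)
    eset = {frozenset(e) for e in edges}

    def is_clique(sub):
        return all(frozenset((a, b)) in eset for a, b in itertools.combinations(sub, 2))

    cliques = []
    for r in range(2, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if is_clique(sub):
                cliques.append(set(sub))
    maximal = [
        c for c in cliques if not any(c < d for d in cliques)
    ]
    scores = {v: 0.0 for v in nodes}
    for c in maximal:
        w = math.factorial(len(c) - 1)
        for v in c:
            scores[v] += w
    return scores


def brute_closeness(nodes, edges):
    adj = _adj(nodes, edges)
    scores = {}
    for v in nodes:
        dist = _bfs_dist(adj, v)
        scores[v] = sum(1.0 / d for u, d in dist.items() if u != v)
    return scores


def brute_betweenness(nodes, edges):
    adj = _adj(nodes, edges)
    scores = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(list(nodes), 2):
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            scores[v] += through / len(paths)
    return scores


def brute_stress(nodes, edges):
    adj = _adj(nodes, edges)
    scores = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(list(nodes), 2):
        for p in _all_shortest_paths(adj, s, t):
            for v in p[1:-1]:
                scores[v] += 1
    return scores


def brute_radiality(nodes, edges):
    adj = _adj(nodes, edges)
    scores = {v: 0.0 for v in nodes}
    seen = set()
    for v in nodes:
        if v in seen:
            continue
        comp = list(_bfs_dist(adj, v))
        seen |= set(comp)
        if len(comp) == 1:
            continue
        dists = {u: _bfs_dist(adj, u) for u in comp}
        diameter = max(max(d.values()) for d in dists.values())
        for u in comp:
            mean_d = sum(dists[u][w] for w in comp if w != u) / (len(comp) - 1)
            scores[u] = diameter + 1 - mean_d
    return scores


def exact_epc(nodes, edges, keep_prob=0.5):
    """Exact expected percolated-component size by summing over all 2^E
    edge subsets (feasible for graphs with few edges only)."""
    nodes = list(nodes)
    edges = list(edges)
    scores = {v: 0.0 for v in nodes}
    for mask in range(2 ** len(edges)):
        kept = [e for i, e in enumerate(edges) if mask >> i & 1]
        k = len(kept)
        prob = keep_prob**k * (1 - keep_prob) ** (len(edges) - k)
        adj = _adj(nodes, kept)
        seen = set()
        for v in nodes:
            if v in seen:
                continue
            comp = set(_bfs_dist(adj, v))
            seen |= comp
            for u in comp:
                scores[u] += prob * len(comp)
    return scores


BRUTE_METHODS = {
    "Degree": brute_degree,
    "MNC": brute_mnc,
    "MCC": brute_mcc,
    "Closeness": brute_closeness,
    "Betweenness": brute_betweenness,
    "Stress": brute_stress,
    "Radiality": brute_radiality,
}
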