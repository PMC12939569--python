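"""Network-pharmacology stage: hub-gene ranking and set statistics.

A gene-interaction network (e.g. a STRING export) is confidence-filtered at
load time, after which edges are unweighted: the confidence score gates an
edge and is then discarded. Hub genes are identified by ranking nodes under
eight topological centralities (the CytoHubba set) and intersecting the
top-k lists:

* Degree       - neighbour count
* MNC          - size of the largest connected component of the subgraph
                 induced on the node's neighbourhood (node excluded)
* MCC          - sum over maximal cliques C containing the node of (|C|-1)!
* EPC          - mean size of the node's connected component when each edge
                 is independently retained with probability p (Monte Carlo,
                 seeded)
* Closeness    - harmonic closeness, sum of 1/d(v,u) over reachable u
* Betweenness  - shortest-path betweenness (unnormalized)
* Radiality    - per connected component, (diameter + 1) minus the mean
                 shortest-path distance to the other component members
* Stress       - number of shortest paths with the node in their interior

Ties in a top-k list break lexicographically on gene symbol. Enrichment of
a selected gene set against a category is reported as fold enrichment with
an upper-tail hypergeometric p-value.
"""

from __future__ import annotations

import itertools
import math
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

METHODS = ("MCC", "MNC", "Degree", "EPC", "Closeness", "Betweenness", "Radiality", "Stress")


class NetworkError(ValueError):
    """Raised for malformed network input."""


@dataclass(frozen=True)
class GeneSet:
    label: str
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class CentralityResult:
    method: str
    scores: Mapping[str, float]
    top_k: tuple[str, ...]


def load_graph(path: str | Path, min_confidence: float = 0.9) -> nx.Graph:
    """Read an edge TSV (geneA, geneB, combined_score) into an unweighted graph.

    Edges with score strictly above ``min_confidence`` are kept; self-loops
    are rejected and nodes left isolated by the filter are dropped.
    """
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:2] == ["geneA", "geneB"]:
                continue
            if len(parts) != 3:
                raise NetworkError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            a, b, score_s = parts
            if not a or not b:
                raise NetworkError(f"{path}:{lineno}: empty gene symbol")
            if a == b:
                raise NetworkError(f"{path}:{lineno}: self-loop on {a!r}")
            try:
                score = float(score_s)
            except ValueError as exc:
                raise NetworkError(f"{path}:{lineno}: bad score {score_s!r}") from exc
            if score > min_confidence:
                g.add_edge(a, b)
    if g.number_of_edges() == 0:
        import logging

        logging.getLogger(__name__).warning(
            "no edges above confidence %s in %s", min_confidence, path
        )
    return g


def load_gene_set(path: str | Path, label: str | None = None) -> GeneSet:
    """Read a gene-set file (one symbol per line)."""
    members = set()
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                members.add(sym)
    return GeneSet(label=label or Path(path).stem, members=frozenset(members))


def overlap(peptide_sets: Sequence[GeneSet], disease: GeneSet) -> GeneSet:
    """(union of the per-peptide predicted target sets) intersected with the
    disease target set — the candidate targets carried into the network."""
    union: set[str] = set()
    for gs in peptide_sets:
        union |= gs.members
    return GeneSet(label="overlap", members=frozenset(union & disease.members))


# ---------------------------------------------------------------- centralities


def _mcc(g: nx.Graph) -> dict[str, float]:
    scores = {v: 0.0 for v in g}
    for clique in nx.find_cliques(g):
        if len(clique) < 2:
            continue
        w = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += w
    return scores


def _mnc(g: nx.Graph) -> dict[str, float]:
    scores = {}
    for v in g:
        nbrs = list(g.neighbors(v))
        if not nbrs:
            scores[v] = 0.0
            continue
        sub = g.subgraph(nbrs)
        scores[v] = float(max(len(c) for c in nx.connected_components(sub)))
    return scores


def _bfs_sigma(g: nx.Graph, source):
    """Distances and shortest-path counts from ``source`` (Brandes BFS)."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in g.neighbors(v):
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0
                queue.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
    return dist, sigma


def _stress(g: nx.Graph) -> dict[str, float]:
    # st(v) = sum over ordered pairs s<t of sigma_sv * sigma_vt when v lies
    # on a shortest s-t path; pairwise sigma/dist tables come from one BFS
    # per node.
    nodes = list(g)
    dist: dict[str, dict] = {}
    sigma: dict[str, dict] = {}
    for s in nodes:
        dist[s], sigma[s] = _bfs_sigma(g, s)
    scores = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        dst = dist[s].get(t)
        if dst is None:
            continue
        for v in nodes:
            if v is s or v is t:
                continue
            dsv = dist[s].get(v)
            if dsv is None or not 0 < dsv < dst:
                continue
            if dsv + dist[v][t] == dst:
                scores[v] += sigma[s][v] * sigma[v][t]
    return scores


def _radiality(g: nx.Graph) -> dict[str, float]:
    scores = {v: 0.0 for v in g}
    for comp in nx.connected_components(g):
        comp = list(comp)
        if len(comp) == 1:
            continue
        sub = g.subgraph(comp)
        lengths = dict(nx.all_pairs_shortest_path_length(sub))
        diameter = max(max(d.values()) for d in lengths.values())
        for v in comp:
            mean_d = sum(lengths[v][u] for u in comp if u != v) / (len(comp) - 1)
            scores[v] = diameter + 1 - mean_d
    return scores


def epc_scores(
    g: nx.Graph,
    reps: int = 1000,
    keep_prob: float = 0.5,
    seed: int | None = None,
) -> dict[str, float]:
    """Monte-Carlo edge-percolated component size per node.

    Each repetition retains every edge independently with ``keep_prob`` and
    credits every node with the size of its surviving component; scores are
    the mean over repetitions. A seed is mandatory for reproducibility.
    """
    if seed is None:
        raise NetworkError("EPC requires an explicit seed")
    rng = np.random.default_rng(seed)
    nodes = list(g)
    edges = list(g.edges())
    totals = {v: 0.0 for v in nodes}
    for _ in range(reps):
        keep = rng.random(len(edges)) < keep_prob
        h = nx.Graph()
        h.add_nodes_from(nodes)
        h.add_edges_from(e for e, k in zip(edges, keep) if k)
        for comp in nx.connected_components(h):
            size = float(len(comp))
            for v in comp:
                totals[v] += size
    return {v: t / reps for v, t in totals.items()}


def centrality(
    g: nx.Graph,
    method: str,
    k: int = 10,
    epc_reps: int = 1000,
    epc_keep_prob: float = 0.5,
    seed: int | None = None,
) -> CentralityResult:
    """Score all nodes under one method and rank the top k.

    Ranking is by score descending with lexicographic tie-break on the gene
    symbol.
    """
    if g.number_of_nodes() == 0:
        raise NetworkError("empty graph")
    if method == "Degree":
        scores = {v: float(d) for v, d in g.degree()}
    elif method == "MNC":
        scores = _mnc(g)
    elif method == "MCC":
        scores = _mcc(g)
    elif method == "Closeness":
        scores = {v: float(c) for v, c in nx.harmonic_centrality(g).items()}
    elif method == "Betweenness":
        scores = {v: float(c) for v, c in nx.betweenness_centrality(g, normalized=False).items()}
    elif method == "Stress":
        scores = _stress(g)
    elif method == "Radiality":
        scores = _radiality(g)
    elif method == "EPC":
        scores = epc_scores(g, reps=epc_reps, keep_prob=epc_keep_prob, seed=seed)
    else:
        raise NetworkError(f"unknown centrality method {method!r}; available: {METHODS}")
    ranked = sorted(scores, key=lambda v: (-scores[v], v))
    return CentralityResult(method=method, scores=scores, top_k=tuple(ranked[: min(k, len(ranked))]))


def consensus(results: Sequence[CentralityResult], k: int | None = None) -> GeneSet:
    """Hub consensus: strict intersection of the top-k lists of all methods."""
    if len(results) < 2:
        raise NetworkError("consensus needs at least two centrality results")
    sets = []
    for r in results:
        top = r.top_k if k is None else r.top_k[:k]
        sets.append(set(top))
    members = frozenset(set.intersection(*sets))
    return GeneSet(label="hub-consensus", members=members)


def hub_consensus(
    g: nx.Graph,
    k: int = 10,
    epc_reps: int = 1000,
    epc_keep_prob: float = 0.5,
    seed: int | None = None,
) -> tuple[GeneSet, list[CentralityResult]]:
    """Run all eight centralities and intersect their top-k lists."""
    results = [
        centrality(g, m, k=k, epc_reps=epc_reps, epc_keep_prob=epc_keep_prob, seed=seed)
        for m in METHODS
    ]
    return consensus(results), results


def enrichment(
    selected: GeneSet, category: GeneSet, background: GeneSet
) -> tuple[float, float]:
    """Fold enrichment and upper-tail hypergeometric p for a category.

    fold = (k/n) / (K/N) for k category hits among the n selected genes,
    with K category members in a background of N; p = P(X >= k) under the
    hypergeometric null.
    """
    if not background.members:
        raise NetworkError("empty background")
    if not selected.members <= background.members or not category.members <= background.members:
        raise NetworkError("selected and category sets must be subsets of the background")
    n = len(selected)
    big_n = len(background)
    big_k = len(category.members)
    k = len(selected.members & category.members)
    if n == 0 or big_k == 0:
        return 0.0, 1.0
    fold = (k / n) / (big_k / big_n)
    p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
    return fold, p


def bundled_hub_lists() -> list[CentralityResult]:
    """The shipped eight top-10 hub-gene lists for the collagen-peptide
    antihypertensive target network (scores not published; rank order only)."""
    import csv
    from importlib.resources import files

    text = files("collapep.data").joinpath("hub_top10.tsv").read_text()
    by_method: dict[str, list[tuple[int, str]]] = {}
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        by_method.setdefault(row["method"], []).append((int(row["rank"]), row["gene"]))
    results = []
    for method, entries in by_method.items():
        entries.sort()
        genes = tuple(g for _, g in entries)
        results.append(
            CentralityResult(
                method=method,
                scores={g: float(len(genes) - i) for i, g in enumerate(genes)},
                top_k=genes,
            )
        )
    return results


def write_centrality_tsv(results: Sequence[CentralityResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node\tmethod\tscore\trank\n")
        for r in results:
            ranked = sorted(r.scores, key=lambda v: (-r.scores[v], v))
            for rank, v in enumerate(ranked, start=1):
                fh.write(f"{v}\t{r.method}\t{r.scores[v]:.6g}\t{rank}\n")
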