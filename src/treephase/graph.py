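"""Read-graph construction and the tree-partition score.

Overlapping fragments form a weighted graph: the edge weight between two
reads is ``(s + d) * KL(E || 2*delta*(1-delta))`` where ``E = d/(d+s)`` is
the observed pairwise error fraction and ``delta`` the per-allele miscall
probability.  Two error-free reads from the same haplotype disagree at a
shared site with probability ``2*delta*(1-delta)``, so by the Chernoff bound
the weight is (asymptotically) the negative log p-value of a one-sided
binomial test of "same haplotype".  The sign is flipped when
``E < 2*delta*(1-delta)`` so that weight increases monotonically with E.

The sum over clusters of maximum-spanning-tree weight (the SMTP score) is
the quantity minimized by the local clustering heuristic; with the plain
``w = d`` weighting it upper-bounds the MEC score on fully-overlapping read
sets (up to one additive per-cluster term).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Set, Tuple

from .fragments import Fragment, Partition, pair_diff_same

EdgeKey = Tuple[str, str]  # lexicographically ordered pair of fragment ids


def _edge_key(u: str, v: str) -> EdgeKey:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class WeightParams:
    """Parameters of the probabilistic edge weight.

    delta is the per-allele miscall probability; the null disagreement rate
    between same-haplotype reads is p = 2*delta*(1-delta).
    """

    delta: float

    def __post_init__(self) -> None:
        if not (0.0 < self.delta < 0.5):
            raise ValueError(f"delta must be in (0, 0.5), got {self.delta}")

    @property
    def p_same(self) -> float:
        return 2.0 * self.delta * (1.0 - self.delta)


class ReadGraph:
    """Weighted overlap graph on fragments.

    Edges exist exactly between pairs with d + s > 0 and carry the tuple
    (weight, d, s) so scores can switch between the KL weight and w = d
    without rebuilding.
    """

    def __init__(self) -> None:
        self.vertices: Set[str] = set()
        self.edges: Dict[EdgeKey, Tuple[float, int, int]] = {}
        self.adj: Dict[str, Dict[str, Tuple[float, int, int]]] = {}

    def add_vertex(self, v: str) -> None:
        self.vertices.add(v)
        self.adj.setdefault(v, {})

    def add_edge(self, u: str, v: str, weight: float, d: int, s: int) -> None:
        self.add_vertex(u)
        self.add_vertex(v)
        self.edges[_edge_key(u, v)] = (weight, d, s)
        self.adj[u][v] = (weight, d, s)
        self.adj[v][u] = (weight, d, s)

    def has_edge(self, u: str, v: str) -> bool:
        return _edge_key(u, v) in self.edges

    def edge(self, u: str, v: str) -> Tuple[float, int, int]:
        return self.edges[_edge_key(u, v)]

    def weight(self, u: str, v: str) -> float:
        return self.edges[_edge_key(u, v)][0]

    def neighbors(self, v: str) -> Dict[str, Tuple[float, int, int]]:
        return self.adj.get(v, {})

    def subgraph(self, vertex_subset: Iterable[str]) -> "ReadGraph":
        keep = set(vertex_subset)
        sub = ReadGraph()
        for v in keep:
            sub.add_vertex(v)
        for (u, v), (w, d, s) in self.edges.items():
            if u in keep and v in keep:
                sub.add_edge(u, v, w, d, s)
        return sub


def error_fraction(d: int, s: int) -> float:
    """Observed disagreement fraction E = d/(d+s) between two reads."""
    if d + s <= 0:
        raise ValueError("error_fraction undefined for non-overlapping reads (d+s=0)")
    return d / (d + s)


def kl_bernoulli(a: float, p: float) -> float:
    """KL divergence between an a-coin and a p-coin (natural log).

    Zero iff a == p; the conventions 0*log(0) = 0 apply at the boundaries
    a = 0 and a = 1.
    """
    if not (0.0 <= a <= 1.0):
        raise ValueError(f"a must be in [0, 1], got {a}")
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must be in (0, 1), got {p}")
    out = 0.0
    if a > 0.0:
        out += a * math.log(a / p)
    if a < 1.0:
        out += (1.0 - a) * math.log((1.0 - a) / (1.0 - p))
    return out


def edge_weight(d: int, s: int, params: WeightParams) -> float:
    """KL edge weight (s+d) * KL(E || p_same), negated when E < p_same."""
    n = d + s
    e = error_fraction(d, s)
    p = params.p_same
    w = n * kl_bernoulli(e, p)
    if e < p:
        w = -w
    return w


def build_read_graph(
    fragments: Iterable[Fragment],
    params: WeightParams,
) -> ReadGraph:
    """Build the overlap graph: edges exactly where d + s > 0.

    Fragments are interval-sorted so only pairs whose covered ranges
    intersect are compared; within a range intersection the sparse allele
    maps decide whether an edge actually exists.
    """
    frs = sorted(fragments, key=lambda fr: (fr.first, fr.id))
    graph = ReadGraph()
    for fr in frs:
        graph.add_vertex(fr.id)
    active: List[Fragment] = []
    for fr in frs:
        still = []
        for other in active:
            if other.last >= fr.first:
                still.append(other)
                d, s = pair_diff_same(fr, other)
                if d + s > 0:
                    graph.add_edge(fr.id, other.id, edge_weight(d, s, params), d, s)
        active = still
        active.append(fr)
    return graph


class DisconnectedClusterError(ValueError):
    """A cluster does not induce a connected subgraph (invalid partition)."""


def _kruskal_max_tree(
    graph: ReadGraph, vertex_subset: Set[str], weight_index: int = 0
) -> List[Tuple[EdgeKey, Tuple[float, int, int]]]:
    """Maximum spanning tree of the induced subgraph via Kruskal.

    weight_index selects which stored edge annotation drives the tree
    (0 = KL weight, 1 = d).  Deterministic: edges sorted by (-weight,
    edge id); raises DisconnectedClusterError if the subset is not
    connected.
    """
    verts = sorted(vertex_subset)
    if len(verts) <= 1:
        return []
    parent = {v: v for v in verts}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    cand = [
        (key, data)
        for key, data in graph.edges.items()
        if key[0] in vertex_subset and key[1] in vertex_subset
    ]
    cand.sort(key=lambda item: (-item[1][weight_index], item[0]))
    tree = []
    for key, data in cand:
        ru, rv = find(key[0]), find(key[1])
        if ru != rv:
            parent[ru] = rv
            tree.append((key, data))
            if len(tree) == len(verts) - 1:
                break
    if len(tree) != len(verts) - 1:
        raise DisconnectedClusterError(
            f"vertex subset of size {len(verts)} is not connected "
            f"({len(tree) + 1} components reachable)"
        )
    return tree


def max_spanning_tree(graph: ReadGraph, vertex_subset: Iterable[str]) -> Set[EdgeKey]:
    """Edge set of the maximum spanning tree on the induced subgraph."""
    subset = set(vertex_subset)
    return {key for key, _ in _kruskal_max_tree(graph, subset)}


def _spanning_forest(
    graph: ReadGraph, vertex_subset: Set[str], weight_index: int = 0
) -> List[Tuple[EdgeKey, Tuple[float, int, int]]]:
    """Maximum spanning forest (per-component trees) -- tolerant variant."""
    verts = sorted(vertex_subset)
    parent = {v: v for v in verts}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    cand = [
        (key, data)
        for key, data in graph.edges.items()
        if key[0] in vertex_subset and key[1] in vertex_subset
    ]
    cand.sort(key=lambda item: (-item[1][weight_index], item[0]))
    forest = []
    for key, data in cand:
        ru, rv = find(key[0]), find(key[1])
        if ru != rv:
            parent[ru] = rv
            forest.append((key, data))
    return forest


def smtp_score(
    partition: Partition,
    graph: ReadGraph,
    weight_choice: str = "kl",
    strict: bool = True,
) -> float:
    """Sum over clusters of maximum-spanning-tree weight (the SMTP score).

    weight_choice 'kl' uses the stored probabilistic weights; 'd' uses the
    raw disagreement counts (the MEC-bounding variant).  With strict=True a
    disconnected cluster raises; strict=False falls back to the maximum
    spanning forest so diagnostics can still be reported.
    """
    if weight_choice not in ("kl", "d"):
        raise ValueError(f"weight_choice must be 'kl' or 'd', got {weight_choice!r}")
    widx = 0 if weight_choice == "kl" else 1
    total = 0.0
    for cl in partition.clusters:
        subset = set(cl)
        if len(subset) <= 1:
            continue
        tree = (
            _kruskal_max_tree(graph, subset, widx)
            if strict
            else _spanning_forest(graph, subset, widx)
        )
        total += sum(data[widx] for _, data in tree)
    return total
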