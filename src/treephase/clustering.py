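"""Local clustering: greedy min-max partitioning and UPEM refinement.

Two stages run on each local block of the read-graph:

1.  A clique-seeded greedy partitioner.  A greedy k-clique of mutually
    divergent reads (heaviest-edge seeds) initializes the k clusters; the
    remaining vertices are then assigned over ``n`` sweeps, each sweep
    taking the vertices with the largest guaranteed overlap to the current
    clusters first and placing each one in the cluster minimizing its
    worst (maximum-weight) edge into the cluster.  Minimizing the worst
    edge keeps the heaviest edges out of every cluster's maximum spanning
    tree, which is what the tree-partition objective penalizes.

2.  Kernighan-Lin-style refinement of the UPEM score: each round scores
    every single-read move between clusters, applies the best ceil(|S|/n)
    positive-gain moves, and reverts the round if the overall score
    dropped.  The returned partition therefore never scores below the
    input.

All tie-breaks are deterministic: smallest cluster index, then
lexicographic fragment id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Set, Tuple

from .fragments import FragmentSet, Partition
from .graph import ReadGraph
from .upem import ClusterCounts, UpemParams


@dataclass
class ClusterState:
    """Mutable state of the greedy partitioner over one block."""

    partition: Partition
    unassigned: Set[str]
    graph: ReadGraph


def find_max_clique(graph: ReadGraph, k: int) -> List[str]:
    """Greedy k-clique of mutually divergent reads used to seed clusters.

    Starts from the maximum-weight edge and repeatedly adds the vertex
    maximizing its minimum weight to the current members.  Vertices
    adjacent to every member are preferred; if none exists the minimum is
    taken over the edges the candidate does have (the block graph need not
    contain a true k-clique).
    """
    if len(graph.vertices) < k:
        raise ValueError(
            f"graph has {len(graph.vertices)} vertices, fewer than ploidy {k}"
        )
    if not graph.edges:
        raise ValueError("graph has no edges; cannot seed clusters")
    # heaviest edge, ties by lexicographic id pair
    best_key = max(graph.edges, key=lambda key: (graph.edges[key][0], key))
    members: List[str] = [best_key[0], best_key[1]]
    while len(members) < k:
        best: Optional[Tuple[int, float, str]] = None
        for v in sorted(graph.vertices):
            if v in members:
                continue
            ws = [graph.adj[v][u][0] for u in members if u in graph.adj[v]]
            if not ws:
                continue
            complete = int(len(ws) == len(members))
            cand = (complete, min(ws), v)
            # prefer fully-connected candidates, then max-min weight; strict
            # comparison over sorted ids -> smallest id wins exact ties
            if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                best = cand
        if best is None:
            # no remaining vertex touches the clique; take smallest id
            for v in sorted(graph.vertices):
                if v not in members:
                    best = (0, float("-inf"), v)
                    break
        assert best is not None
        members.append(best[2])
    return members


def _max_edge_to_cluster(graph: ReadGraph, v: str, cluster: Set[str]) -> Optional[float]:
    """Max weight from v over its edges into cluster; None if no edge."""
    nbrs = graph.adj.get(v, {})
    best: Optional[float] = None
    for u in cluster:
        data = nbrs.get(u)
        if data is not None and (best is None or data[0] > best):
            best = data[0]
    return best


def assign_vertex(v: str, state: ClusterState) -> Optional[int]:
    """Cluster index minimizing the maximum edge weight from v.

    Only clusters v has at least one edge into are candidates; ties go to
    the smallest index.  Returns None when v touches no cluster (the
    caller defers such vertices).
    """
    best_idx: Optional[int] = None
    best_val = math.inf
    for i, cl in enumerate(state.partition.clusters):
        val = _max_edge_to_cluster(state.graph, v, cl)
        if val is not None and val < best_val:
            best_val = val
            best_idx = i
    return best_idx


def _sweep_value(graph: ReadGraph, v: str, clusters: List[Set[str]]) -> float:
    """Sort key for a sweep: min over clusters of max overlap (s+d) to v."""
    nbrs = graph.adj.get(v, {})
    value = math.inf
    for cl in clusters:
        best = 0
        for u in cl:
            data = nbrs.get(u)
            if data is not None:
                ov = data[1] + data[2]
                if ov > best:
                    best = ov
        value = min(value, best)
    return value if value is not math.inf else 0.0


def greedy_min_max_partition(graph: ReadGraph, k: int, n: int = 10) -> Partition:
    """Clique-seeded greedy min-max partition of a block's read-graph.

    Per outer iteration the unassigned vertices are sorted (descending) by
    the minimum over clusters of their maximum overlap, the top
    ceil(|V|/n) are assigned via :func:`assign_vertex`, and clusters are
    updated between iterations.  Vertices touching no cluster are deferred
    and finally placed in the smallest cluster.
    """
    if len(graph.vertices) < k:
        raise ValueError(
            f"block has {len(graph.vertices)} reads, fewer than ploidy {k}"
        )
    if len(graph.vertices) == k:
        return Partition([{v} for v in sorted(graph.vertices)])
    seeds = find_max_clique(graph, k)
    partition = Partition([{s} for s in seeds])
    state = ClusterState(
        partition=partition,
        unassigned=set(graph.vertices) - set(seeds),
        graph=graph,
    )
    for _ in range(n):
        if not state.unassigned:
            break
        order = sorted(
            state.unassigned,
            key=lambda v: (-_sweep_value(graph, v, partition.clusters), v),
        )
        take = order[: math.ceil(len(order) / n)]
        deferred: List[str] = []
        for v in take:
            idx = assign_vertex(v, state)
            if idx is None:
                deferred.append(v)
                continue
            partition.clusters[idx].add(v)
            state.unassigned.discard(v)
        for v in deferred:
            idx = assign_vertex(v, state)
            if idx is None:
                sizes = [(len(cl), i) for i, cl in enumerate(partition.clusters)]
                idx = min(sizes)[1]
            partition.clusters[idx].add(v)
            state.unassigned.discard(v)
    # any stragglers after n sweeps (possible when ceil rounding lags)
    for v in sorted(state.unassigned):
        idx = assign_vertex(v, state)
        if idx is None:
            sizes = [(len(cl), i) for i, cl in enumerate(partition.clusters)]
            idx = min(sizes)[1]
        partition.clusters[idx].add(v)
    state.unassigned.clear()
    return partition


def upem_delta(
    r: str,
    src: int,
    dst: int,
    counts: ClusterCounts,
    params: UpemParams,
) -> float:
    """UPEM change from moving read r from cluster src to dst (not applied)."""
    return counts.move_delta(r, src, dst, params)


def refine_upem(
    partition: Partition,
    fragments: FragmentSet,
    params: UpemParams,
    n: int = 10,
) -> Partition:
    """Iteratively improve the UPEM score by single-read moves.

    Each round enumerates every positive-gain move against the partition
    frozen at round start, applies the best ceil(|S|/n) of them in gain
    order (a read moves at most once per round), and reverts the whole
    round if the realized score dropped.  Runs at most n rounds; the
    output never scores below the input.
    """
    if partition.k < 2:
        raise ValueError("refinement requires at least 2 clusters")
    part = partition.copy()
    counts = ClusterCounts(part, fragments)
    n_reads = sum(len(cl) for cl in part.clusters)
    if n_reads == 0:
        return part
    budget = math.ceil(n_reads / n)
    for _ in range(n):
        old_score = counts.score(params)
        moves: List[Tuple[float, str, int, int]] = []
        for i, cl in enumerate(part.clusters):
            for r in sorted(cl):
                for j in range(part.k):
                    if j == i:
                        continue
                    delta = counts.move_delta(r, i, j, params)
                    if delta > 0:
                        moves.append((delta, r, i, j))
        if not moves:
            break
        moves.sort(key=lambda mv: (-mv[0], mv[1], mv[2], mv[3]))
        applied: List[Tuple[str, int, int]] = []
        moved: Set[str] = set()
        taken = 0
        for delta, r, i, j in moves:
            if taken >= budget:
                break
            if r in moved:
                continue
            part.clusters[i].discard(r)
            part.clusters[j].add(r)
            counts.remove(r, i)
            counts.add(r, j)
            applied.append((r, i, j))
            moved.add(r)
            taken += 1
        new_score = counts.score(params)
        if new_score < old_score:
            for r, i, j in reversed(applied):
                part.clusters[j].discard(r)
                part.clusters[i].add(r)
                counts.remove(r, j)
                counts.add(r, i)
            return part
    return part
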