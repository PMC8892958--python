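"""End-to-end phasing pipeline.

The chromosome is cut into consecutive variant intervals of length b (the
lower-third quantile of read lengths, so most reads span a whole block);
each block's reads are partitioned locally (greedy min-max clustering +
UPEM refinement), low-scoring outlier blocks are re-phased by extending
their left neighbor, and the per-block partitions are chained left to
right by the read-overlap-maximizing cluster permutation.  The final
partition yields consensus haplotypes, optionally constrained by VCF
genotype dosages.

Model parameters are estimated from the data: sigma (the UPEM trial
normalizer) is the median read length divided by 25, and delta (the
per-allele miscall rate) is the bottom-decile per-cluster error rate after
a trial clustering of 10 random blocks at an initial guess of 0.03 -- a
deliberate underestimate, since some of the observed error is the
clustering's own.
"""

from __future__ import annotations

import logging
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from itertools import permutations
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .clustering import (
    _sweep_value,
    ClusterState,
    assign_vertex,
    greedy_min_max_partition,
    refine_upem,
)
from .fragments import FragmentSet, Partition, mec_score
from .graph import ReadGraph, WeightParams, build_read_graph, smtp_score
from .haplotypes import (
    GenotypeTable,
    constrained_haplotypes,
    unconstrained_haplotypes,
)
from .upem import ClusterCounts, UpemParams

logger = logging.getLogger(__name__)

DELTA_INITIAL = 0.03
DELTA_MIN = 1e-4
DELTA_MAX = 0.49
SIGMA_MIN = 0.01


@dataclass
class Block:
    """Reads overlapping one variant interval (inclusive endpoints)."""

    index: int
    interval: Tuple[int, int]
    fragment_ids: List[str]

    def __len__(self) -> int:
        return len(self.fragment_ids)


@dataclass
class PipelineConfig:
    ploidy: int
    block_length: Optional[int] = None
    delta: Optional[float] = None
    iterations: int = 10
    iqr_factor: float = 3.0
    fill_in: bool = True
    seed: int = 0
    threads: int = 1

    def __post_init__(self) -> None:
        if self.ploidy < 2:
            raise ValueError("ploidy must be >= 2")
        if self.iqr_factor <= 0:
            raise ValueError("iqr_factor must be > 0")
        if self.ploidy > 8:
            raise ValueError("ploidy > 8 not supported (merge search is k!)")


@dataclass
class PhasingResult:
    partition: Partition
    haplotypes: np.ndarray
    report: Dict[str, object]


def _lengths(fragments: FragmentSet) -> np.ndarray:
    return np.array([fr.length for fr in fragments], dtype=float)


def choose_block_length(fragments: FragmentSet) -> int:
    """Lower-third quantile of read lengths (linear interpolation), >= 1."""
    if len(fragments) == 0:
        raise ValueError("cannot choose block length from an empty fragment set")
    q = float(np.quantile(_lengths(fragments), 1.0 / 3.0))
    return max(1, int(math.floor(q + 0.5)))


def estimate_sigma(fragments: FragmentSet) -> float:
    """UPEM normalizer: median read length / 25, floored at a small constant."""
    if len(fragments) == 0:
        raise ValueError("cannot estimate sigma from an empty fragment set")
    return max(SIGMA_MIN, float(np.median(_lengths(fragments))) / 25.0)


def extract_blocks(fragments: FragmentSet, b: int) -> List[Block]:
    """All reads overlapping each shifted interval of b variants.

    Block i (1-based) spans site indices [b*(i-1), b*i] inclusive, so
    consecutive blocks share the boundary site and any read crossing it.
    """
    if b < 1:
        raise ValueError("block length must be >= 1")
    m = fragments.m
    n_blocks = max(1, math.ceil((m - 1) / b)) if m > 1 else 1
    blocks = []
    for i in range(n_blocks):
        lo, hi = b * i, b * (i + 1)
        members = []
        for fr in fragments:
            if fr.last < lo or fr.first > hi:
                continue
            if any(lo <= j <= hi for j in fr.alleles):
                members.append(fr.id)
        blocks.append(Block(index=i, interval=(lo, hi), fragment_ids=sorted(members)))
    return blocks


def merge_small_blocks(blocks: List[Block], k: int) -> List[Block]:
    """Fold blocks with fewer than k reads into their predecessor."""
    merged: List[Block] = []
    for blk in blocks:
        if merged and (len(blk) < k or len(merged[-1]) < k):
            prev = merged.pop()
            blk = Block(
                index=prev.index,
                interval=(prev.interval[0], blk.interval[1]),
                fragment_ids=sorted(set(prev.fragment_ids) | set(blk.fragment_ids)),
            )
        merged.append(blk)
    while len(merged) > 1 and len(merged[-1]) < k:
        last = merged.pop()
        prev = merged.pop()
        merged.append(
            Block(
                index=prev.index,
                interval=(prev.interval[0], last.interval[1]),
                fragment_ids=sorted(
                    set(prev.fragment_ids) | set(last.fragment_ids)
                ),
            )
        )
    for i, blk in enumerate(merged):
        blk.index = i
    return merged


def _phase_one_block(
    block: Block,
    fragments: FragmentSet,
    wparams: WeightParams,
    uparams: UpemParams,
    k: int,
    iterations: int,
) -> Tuple[Partition, ReadGraph]:
    frs = [fragments[fid] for fid in block.fragment_ids]
    graph = build_read_graph(frs, wparams)
    ids = sorted(block.fragment_ids)
    if len(ids) <= k:
        clusters: List[Set[str]] = [set() for _ in range(k)]
        for i, fid in enumerate(ids):
            clusters[i % k].add(fid)
        return Partition(clusters), graph
    try:
        part = greedy_min_max_partition(graph, k, n=iterations)
    except ValueError:
        # no edges at all (degenerate block): round-robin by id
        clusters = [set() for _ in range(k)]
        for i, fid in enumerate(ids):
            clusters[i % k].add(fid)
        part = Partition(clusters)
    part = refine_upem(part, fragments, uparams, n=iterations)
    return part, graph


def phase_blocks(
    blocks: Sequence[Block],
    fragments: FragmentSet,
    wparams: WeightParams,
    uparams: UpemParams,
    config: PipelineConfig,
) -> List[Tuple[Partition, ReadGraph]]:
    """Phase every block independently; output order matches input.

    Blocks are independent, so the result does not depend on the thread
    count.
    """
    work = lambda blk: _phase_one_block(
        blk, fragments, wparams, uparams, config.ploidy, config.iterations
    )
    if config.threads > 1 and len(blocks) > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            return list(pool.map(work, blocks))
    return [work(blk) for blk in blocks]


def estimate_delta(
    fragments: FragmentSet,
    config: PipelineConfig,
    blocks: Optional[Sequence[Block]] = None,
    sigma: Optional[float] = None,
) -> float:
    """Bottom-decile per-cluster error rate after a trial clustering.

    Clusters 10 randomly chosen blocks (all blocks when fewer exist) at
    the initial guess delta = 0.03, computes D/(D+S) for each resulting
    cluster and returns the 1/10-quantile, clamped to [1e-4, 0.49].
    """
    if sigma is None:
        sigma = estimate_sigma(fragments)
    if blocks is None:
        b = config.block_length or choose_block_length(fragments)
        blocks = merge_small_blocks(extract_blocks(fragments, b), config.ploidy)
    usable = [blk for blk in blocks if len(blk) >= config.ploidy]
    if not usable:
        return DELTA_INITIAL
    rng = np.random.default_rng(config.seed)
    n_pick = min(10, len(usable))
    picked_idx = sorted(rng.choice(len(usable), size=n_pick, replace=False))
    wparams = WeightParams(DELTA_INITIAL)
    uparams = UpemParams(delta=DELTA_INITIAL, sigma=sigma)
    errors: List[float] = []
    for bi in picked_idx:
        part, _ = _phase_one_block(
            usable[bi], fragments, wparams, uparams, config.ploidy, config.iterations
        )
        counts = ClusterCounts(part, fragments)
        for D, S in counts.ds_counts():
            if D + S > 0:
                errors.append(D / (D + S))
    if not errors:
        return DELTA_INITIAL
    est = float(np.quantile(np.array(errors), 0.1))
    return min(DELTA_MAX, max(DELTA_MIN, est))


def detect_outlier_blocks(
    upem_scores: Sequence[float], iqr_factor: float = 3.0
) -> Set[int]:
    """Indices scoring below Q1 - iqr_factor * IQR (low UPEM = bad block)."""
    if len(upem_scores) < 4:
        return set()
    scores = np.array(upem_scores, dtype=float)
    q1, q3 = np.percentile(scores, [25.0, 75.0])
    threshold = q1 - iqr_factor * (q3 - q1)
    return {i for i, x in enumerate(scores) if x < threshold}


def fill_in_block(
    prev_partition: Partition,
    block: Block,
    prev_block: Block,
    fragments: FragmentSet,
    wparams: WeightParams,
) -> Partition:
    """Re-phase an outlier block by extending its left neighbor's partition.

    The neighbor's clusters seed the assignment; the clique-finding step
    is skipped and only the reads new to this block are placed, each by
    the usual min-max rule.
    """
    assigned = prev_partition.assigned_ids()
    new_ids = sorted(set(block.fragment_ids) - assigned)
    union_ids = sorted(assigned | set(block.fragment_ids))
    graph = build_read_graph((fragments[fid] for fid in union_ids), wparams)
    part = prev_partition.copy()
    state = ClusterState(partition=part, unassigned=set(new_ids), graph=graph)
    order = sorted(
        new_ids, key=lambda v: (-_sweep_value(graph, v, part.clusters), v)
    )
    for v in order:
        idx = assign_vertex(v, state)
        if idx is None:
            sizes = [(len(cl), i) for i, cl in enumerate(part.clusters)]
            idx = min(sizes)[1]
        part.clusters[idx].add(v)
        state.unassigned.discard(v)
    return part


def merge_partitions(
    accumulated: Partition, nxt: Partition, k: int
) -> Tuple[Partition, Tuple[int, ...]]:
    """Chain two block partitions under the intersection-maximizing permutation.

    sigma = argmax over S_k of sum_j |acc[j] & nxt[sigma(j)]|; exhaustive
    over k! (exact for k <= 8), ties to the lexicographically smallest
    permutation.  Reads already placed keep their cluster.
    """
    inter = [
        [len(accumulated.clusters[j] & nxt.clusters[l]) for l in range(k)]
        for j in range(k)
    ]
    if sum(map(sum, inter)) == 0:
        logger.warning("no shared reads between consecutive blocks; using identity")
        best_perm: Tuple[int, ...] = tuple(range(k))
    else:
        best_perm = tuple(range(k))
        best_score = -1
        for perm in permutations(range(k)):
            score = sum(inter[j][perm[j]] for j in range(k))
            if score > best_score:
                best_score = score
                best_perm = perm
    already = accumulated.assigned_ids()
    clusters = []
    for j in range(k):
        clusters.append(
            set(accumulated.clusters[j])
            | (nxt.clusters[best_perm[j]] - already)
        )
    return Partition(clusters), best_perm


def run_pipeline(
    fragments: FragmentSet,
    genotypes: Optional[GenotypeTable],
    config: PipelineConfig,
) -> PhasingResult:
    """Full chain: parameters -> blocks -> local phasing -> fill-in -> merge."""
    if len(fragments) == 0:
        raise ValueError("no fragments to phase")
    k = config.ploidy
    sigma = estimate_sigma(fragments)
    b = config.block_length or choose_block_length(fragments)
    blocks = merge_small_blocks(extract_blocks(fragments, b), k)
    delta = config.delta if config.delta is not None else estimate_delta(
        fragments, config, blocks=blocks, sigma=sigma
    )
    delta = min(DELTA_MAX, max(DELTA_MIN, float(delta)))
    wparams = WeightParams(delta)
    uparams = UpemParams(delta=delta, sigma=sigma)

    phased = phase_blocks(blocks, fragments, wparams, uparams, config)
    partitions = [part for part, _ in phased]
    graphs = [graph for _, graph in phased]
    upem_scores = [
        ClusterCounts(part, fragments).score(uparams) for part in partitions
    ]

    outliers: Set[int] = set()
    if config.fill_in:
        outliers = detect_outlier_blocks(upem_scores, config.iqr_factor)
        for i in sorted(outliers):
            donor = None
            for j in range(i - 1, -1, -1):
                if j not in outliers:
                    donor = j
                    break
            if donor is None:
                continue  # leading outlier: kept as-is
            partitions[i] = fill_in_block(
                partitions[donor], blocks[i], blocks[donor], fragments, wparams
            )

    final = partitions[0]
    merge_perms: List[Tuple[int, ...]] = []
    for nxt in partitions[1:]:
        final, perm = merge_partitions(final, nxt, k)
        merge_perms.append(perm)

    if genotypes is not None:
        haplotypes = constrained_haplotypes(final, genotypes, fragments)
    else:
        haplotypes = unconstrained_haplotypes(final, fragments, m=fragments.m)

    block_mec = [mec_score(part, fragments) for part in partitions]
    block_smtp = [
        smtp_score(part, graph, weight_choice="d", strict=False)
        for part, graph in zip(partitions, graphs)
    ]
    report: Dict[str, object] = {
        "ploidy": k,
        "n_variants": fragments.m,
        "n_fragments": len(fragments),
        "block_length": b,
        "n_blocks": len(blocks),
        "sigma": sigma,
        "delta": delta,
        "outlier_blocks": sorted(outliers),
        "block_upem": upem_scores,
        "block_mec": block_mec,
        "block_smtp_d": block_smtp,
        "final_mec": mec_score(final, fragments),
    }
    return PhasingResult(partition=final, haplotypes=haplotypes, report=report)
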