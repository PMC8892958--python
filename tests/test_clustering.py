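"""Greedy min-max partitioning and UPEM refinement."""

import itertools

import numpy as np
import pytest

from treephase import (
    Fragment,
    FragmentSet,
    Partition,
    UpemParams,
    WeightParams,
    build_read_graph,
    find_max_clique,
    greedy_min_max_partition,
    mec_score,
    refine_upem,
    upem,
)
from treephase.clustering import ClusterState, assign_vertex
from treephase.graph import ReadGraph

from conftest import fully_overlapping_set, random_partition


def toy_graph(edges):
    g = ReadGraph()
    for (u, v), w in edges.items():
        g.add_edge(u, v, w, 1, 1)
    return g


def simulate_block(rng, k=4, n_per=10, sites=12, error=0.0):
    """Noiseless (or noisy) fully-overlapping reads from k distinct haplotypes."""
    haps = np.zeros((k, sites), dtype=int)
    for j in range(sites):
        carriers = rng.choice(k, size=int(rng.integers(1, k)), replace=False)
        haps[carriers, j] = 1
    # ensure pairwise distinct
    for a, b in itertools.combinations(range(k), 2):
        if np.array_equal(haps[a], haps[b]):
            haps[b, 0] = 1 - haps[b, 0]
    frs, labels = [], {}
    for c in range(k):
        for i in range(n_per):
            alleles = {}
            for j in range(sites):
                a = int(haps[c, j])
                if error > 0 and rng.random() < error:
                    a = 1 - a
                alleles[j] = a
            fid = f"c{c}r{i}"
            frs.append(Fragment(id=fid, alleles=alleles))
            labels[fid] = c
    return FragmentSet(fragments=frs, m=sites), labels


def matches_truth(partition, labels, k):
    for perm in itertools.permutations(range(k)):
        if all(
            labels[fid] == perm[ci]
            for ci, cl in enumerate(partition.clusters)
            for fid in cl
        ):
            return True
    return False


class TestFindMaxClique:
    def test_unique_heaviest_edge_seeds_pair(self):
        g = toy_graph({("a", "b"): 5, ("a", "c"): 1, ("b", "c"): 1})
        assert set(find_max_clique(g, 2)) == {"a", "b"}

    def test_triangle_forced_at_k3(self):
        g = toy_graph({("a", "b"): 5, ("a", "c"): 1, ("b", "c"): 1})
        assert set(find_max_clique(g, 3)) == {"a", "b", "c"}

    def test_too_few_vertices_rejected(self):
        g = toy_graph({("a", "b"): 1})
        with pytest.raises(ValueError):
            find_max_clique(g, 3)

    def test_matches_greedy_resimulation(self, rng):
        """Independent step-by-step replay of the greedy rule."""
        for _ in range(10):
            g = ReadGraph()
            names = [f"v{i:02d}" for i in range(15)]
            for u, v in itertools.combinations(names, 2):
                if rng.random() < 0.6:
                    g.add_edge(u, v, float(rng.normal()), 1, 1)
            if not g.edges:
                continue
            got = find_max_clique(g, 4)

            best_key = max(g.edges, key=lambda key: (g.edges[key][0], key))
            members = [best_key[0], best_key[1]]
            while len(members) < 4:
                cands = []
                for v in sorted(g.vertices):
                    if v in members:
                        continue
                    ws = [g.adj[v][u][0] for u in members if u in g.adj[v]]
                    if ws:
                        cands.append((int(len(ws) == len(members)), min(ws), v))
                if not cands:
                    members.append(
                        sorted(set(names) - set(members))[0]
                    )
                    continue
                top = max(cands, key=lambda c: (c[0], c[1]))
                # replicate smallest-id tie-break
                winners = [c for c in cands if (c[0], c[1]) == (top[0], top[1])]
                members.append(min(w[2] for w in winners))
            assert got == members


class TestAssignVertex:
    def test_prefers_smaller_worst_edge(self):
        g = toy_graph({("v", "a"): 2.0, ("v", "b"): 5.0})
        state = ClusterState(Partition([{"a"}, {"b"}]), {"v"}, g)
        assert assign_vertex("v", state) == 0

    def test_single_candidate_cluster(self):
        g = toy_graph({("v", "b"): 5.0})
        state = ClusterState(Partition([{"a"}, {"b"}]), {"v"}, g)
        assert assign_vertex("v", state) == 1

    def test_no_overlap_returns_none(self):
        g = toy_graph({("a", "b"): 1.0})
        g.add_vertex("v")
        state = ClusterState(Partition([{"a"}, {"b"}]), {"v"}, g)
        assert assign_vertex("v", state) is None

    def test_matches_min_max_brute_force(self, rng):
        for _ in range(20):
            g = ReadGraph()
            names = [f"v{i}" for i in range(10)]
            for u, v in itertools.combinations(names, 2):
                if rng.random() < 0.7:
                    g.add_edge(u, v, float(rng.normal()), 1, 1)
            part = random_partition(rng, names[:-1], 3)
            v = names[-1]
            g.add_vertex(v)
            state = ClusterState(part, {v}, g)
            got = assign_vertex(v, state)
            best = None
            for i, cl in enumerate(part.clusters):
                ws = [g.adj[v][u][0] for u in cl if u in g.adj.get(v, {})]
                if not ws:
                    continue
                if best is None or max(ws) < best[0]:
                    best = (max(ws), i)
            assert got == (best[1] if best else None)


class TestGreedyMinMaxPartition:
    def test_recovers_noiseless_groups(self, rng):
        fs, labels = simulate_block(rng, k=4, n_per=10, sites=12)
        g = build_read_graph(fs, WeightParams(0.03))
        part = greedy_min_max_partition(g, 4)
        assert matches_truth(part, labels, 4)

    def test_ploidy_equals_read_count_gives_singletons(self, rng):
        fs = fully_overlapping_set(rng, 5, 4)
        g = build_read_graph(fs, WeightParams(0.03))
        part = greedy_min_max_partition(g, 5)
        assert sorted(map(len, part.clusters)) == [1, 1, 1, 1, 1]

    def test_partition_is_disjoint_and_exhaustive(self, rng):
        for _ in range(5):
            fs = fully_overlapping_set(rng, 20, 8)
            g = build_read_graph(fs, WeightParams(0.03))
            part = greedy_min_max_partition(g, 3)
            ids = [fid for cl in part.clusters for fid in cl]
            assert sorted(ids) == sorted(fs.ids())


class TestRefineUpem:
    def params(self, fs):
        return UpemParams(delta=0.03, sigma=max(0.5, fs.m / 5))

    def test_never_decreases_upem(self, rng):
        for _ in range(30):
            fs = fully_overlapping_set(rng, 15, 10)
            part = random_partition(rng, fs.ids(), int(rng.integers(2, 5)))
            params = self.params(fs)
            refined = refine_upem(part, fs, params)
            assert upem(refined, fs, params) >= upem(part, fs, params) - 1e-12

    def test_repairs_planted_mislabels_on_noiseless_data(self, rng):
        fs, labels = simulate_block(rng, k=3, n_per=8, sites=10)
        clusters = [set() for _ in range(3)]
        for fid, c in labels.items():
            clusters[c].add(fid)
        # swap two reads across clusters
        clusters[0].discard("c0r0"); clusters[1].add("c0r0")
        clusters[1].discard("c1r0"); clusters[0].add("c1r0")
        part = Partition(clusters)
        refined = refine_upem(part, fs, self.params(fs))
        assert mec_score(refined, fs) == 0
        assert matches_truth(refined, labels, 3)

    def test_local_optimum_returned_unchanged(self, rng):
        fs, labels = simulate_block(rng, k=2, n_per=6, sites=8)
        clusters = [set() for _ in range(2)]
        for fid, c in labels.items():
            clusters[c].add(fid)
        part = Partition(clusters)
        refined = refine_upem(part, fs, self.params(fs))
        assert refined.clusters == part.clusters


class TestEndToEndBlock:
    def test_noiseless_block_fully_recovered(self, rng):
        fs, labels = simulate_block(rng, k=4, n_per=10, sites=12)
        g = build_read_graph(fs, WeightParams(0.03))
        part = greedy_min_max_partition(g, 4)
        part = refine_upem(part, fs, UpemParams(delta=0.03, sigma=2.0))
        assert mec_score(part, fs) == 0
        assert matches_truth(part, labels, 4)
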