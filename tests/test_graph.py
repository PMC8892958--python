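"""Read graph, KL edge weights, spanning trees, SMTP score."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from treephase import (
    Fragment,
    FragmentSet,
    Partition,
    DisconnectedClusterError,
    WeightParams,
    build_read_graph,
    consensus,
    edge_weight,
    error_fraction,
    kl_bernoulli,
    max_spanning_tree,
    mec_score,
    pair_diff_same,
    smtp_score,
)
from treephase.graph import ReadGraph

from conftest import fully_overlapping_set, random_fragment_set, random_partition

DELTA = 0.03
P_SAME = 2 * DELTA * (1 - DELTA)  # 0.0582


class TestErrorFraction:
    @pytest.mark.parametrize("d, s, expected", [(0, 10, 0.0), (10, 0, 1.0), (3, 7, 0.3)])
    def test_values(self, d, s, expected):
        assert error_fraction(d, s) == pytest.approx(expected)

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError):
            error_fraction(0, 0)


class TestKlBernoulli:
    def test_zero_at_equal_rates(self):
        assert kl_bernoulli(P_SAME, P_SAME) == pytest.approx(0.0, abs=1e-15)

    def test_boundary_closed_form(self):
        assert kl_bernoulli(1.0, P_SAME) == pytest.approx(-math.log(P_SAME))

    def test_matches_two_term_formula(self):
        a, p = 0.3, P_SAME
        expected = a * math.log(a / p) + (1 - a) * math.log((1 - a) / (1 - p))
        assert kl_bernoulli(a, p) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_reference_rejected(self):
        for p in (0.0, 1.0):
            with pytest.raises(ValueError):
                kl_bernoulli(0.5, p)

    def test_nonnegative_on_grid(self):
        for a in np.linspace(0, 1, 21):
            assert kl_bernoulli(float(a), 0.1) >= 0.0


class TestEdgeWeight:
    def test_zero_at_null_rate(self):
        # d/(d+s) == 2*delta*(1-delta) exactly: 582 of 10000
        params = WeightParams(DELTA)
        assert edge_weight(582, 10000 - 582, params) == pytest.approx(0.0, abs=1e-12)

    def test_agreeing_reads_get_negative_weight(self):
        assert edge_weight(0, 20, WeightParams(DELTA)) < 0.0

    def test_approximates_binomial_tail_log_pvalue(self):
        """Chernoff-exponent interpretation: the weight is close to the
        negative log tail probability of the same-haplotype binomial null."""
        w = edge_weight(30, 70, WeightParams(DELTA))
        exact = -float(stats.binom.logsf(29, 100, P_SAME))  # P(X >= 30)
        assert w == pytest.approx(exact, rel=0.15)

    def test_strictly_increasing_in_d_at_fixed_total(self):
        params = WeightParams(DELTA)
        weights = [edge_weight(d, 50 - d, params) for d in range(0, 51)]
        assert all(b > a for a, b in zip(weights, weights[1:]))


class TestChernoffBound:
    def test_exact_binomial_tail_below_kl_bound(self):
        """P(Binom(n,p) >= a*n) <= exp(-n*KL(a||p)) over the whole grid."""
        for p in (0.01, P_SAME, 0.2):
            for n in range(1, 61):
                for a in np.arange(p + 0.05, 1.0, 0.05):
                    a = float(a)
                    t = math.ceil(a * n)
                    tail = float(stats.binom.sf(t - 1, n, p))  # P(X >= a*n)
                    bound = math.exp(-n * kl_bernoulli(a, p))
                    assert tail <= bound * (1 + 1e-12)


class TestBuildReadGraph:
    def test_disjoint_fragments_share_no_edge(self):
        fs = FragmentSet(
            fragments=[
                Fragment(id="a", alleles={0: 1, 1: 0}),
                Fragment(id="b", alleles={5: 1, 6: 0}),
            ],
            m=7,
        )
        g = build_read_graph(fs, WeightParams(DELTA))
        assert g.vertices == {"a", "b"} and not g.edges

    def test_fully_overlapping_reads_form_complete_graph(self, rng):
        fs = fully_overlapping_set(rng, 6, 5)
        g = build_read_graph(fs, WeightParams(DELTA))
        assert len(g.edges) == 15

    def test_edges_match_all_pairs_oracle(self, rng):
        fs = random_fragment_set(rng, 20, 25, n_alleles=2)
        g = build_read_graph(fs, WeightParams(DELTA))
        frs = list(fs)
        expected = {}
        for r1, r2 in itertools.combinations(frs, 2):
            d, s = pair_diff_same(r1, r2)
            if d + s > 0:
                key = tuple(sorted([r1.id, r2.id]))
                expected[key] = (d, s)
        assert set(g.edges) == set(expected)
        for key, (d, s) in expected.items():
            w, gd, gs = g.edges[key]
            assert (gd, gs) == (d, s)
            assert w == pytest.approx(edge_weight(d, s, WeightParams(DELTA)))


def toy_graph(edges):
    g = ReadGraph()
    for (u, v), w in edges.items():
        g.add_edge(u, v, w, 1, 1)
    return g


class TestMaxSpanningTree:
    def test_drops_lightest_cycle_edge(self):
        g = toy_graph({("a", "b"): 5, ("a", "c"): 4, ("b", "c"): 1})
        tree = max_spanning_tree(g, {"a", "b", "c"})
        assert tree == {("a", "b"), ("a", "c")}

    def test_tree_input_returned_whole(self):
        g = toy_graph({("a", "b"): 1, ("b", "c"): 2, ("c", "d"): 3})
        assert max_spanning_tree(g, {"a", "b", "c", "d"}) == set(g.edges)

    def test_total_weight_matches_networkx(self, rng):
        nx = pytest.importorskip("networkx")
        for _ in range(10):
            n = 8
            g = ReadGraph()
            names = [f"v{i}" for i in range(n)]
            for u, v in itertools.combinations(names, 2):
                if rng.random() < 0.5:
                    g.add_edge(u, v, float(rng.normal()), 1, 1)
            gx = nx.Graph()
            gx.add_nodes_from(names)
            for (u, v), (w, _, _) in g.edges.items():
                gx.add_edge(u, v, weight=w)
            if not nx.is_connected(gx):
                continue
            tree = max_spanning_tree(g, set(names))
            total = sum(g.edges[e][0] for e in tree)
            expected = sum(
                d["weight"]
                for _, _, d in nx.maximum_spanning_tree(gx).edges(data=True)
            )
            assert total == pytest.approx(expected)

    def test_disconnected_subset_raises(self):
        g = toy_graph({("a", "b"): 1, ("c", "d"): 1})
        with pytest.raises(DisconnectedClusterError):
            max_spanning_tree(g, {"a", "b", "c", "d"})


class TestSmtpScore:
    def test_singleton_clusters_score_zero(self, rng):
        fs = fully_overlapping_set(rng, 3, 4)
        g = build_read_graph(fs, WeightParams(DELTA))
        part = Partition([{fid} for fid in fs.ids()])
        assert smtp_score(part, g, "d") == 0.0

    def test_noiseless_true_clusters_have_zero_d_score(self):
        h = [{j: 0 for j in range(5)}, {j: 1 for j in range(5)}]
        frs = [
            Fragment(id=f"c{c}r{i}", alleles=dict(h[c]))
            for c in range(2)
            for i in range(3)
        ]
        fs = FragmentSet(fragments=frs, m=5)
        g = build_read_graph(fs, WeightParams(DELTA))
        part = Partition([
            {f"c0r{i}" for i in range(3)},
            {f"c1r{i}" for i in range(3)},
        ])
        assert smtp_score(part, g, "d") == 0.0

    def test_tree_bound_on_fully_overlapping_sets(self, rng):
        """SMTP(w=d) + sum_i min_r d(r, H(R_i)) >= MEC when every read
        covers the same interval (star-graph argument)."""
        for _ in range(200):
            k = int(rng.integers(2, 5))
            n = int(rng.integers(k, 31))
            sites = int(rng.integers(2, 13))
            fs = fully_overlapping_set(rng, n, sites)
            g = build_read_graph(fs, WeightParams(DELTA))
            part = random_partition(rng, fs.ids(), k)
            smtp = smtp_score(part, g, "d")
            slack = 0
            for cl in part.clusters:
                members = [fs[fid] for fid in cl]
                hap = consensus(members, m=sites)
                slack += min(
                    sum(1 for j, a in fr.alleles.items() if hap[j] != a)
                    for fr in members
                )
            assert smtp + slack >= mec_score(part, fs)


class TestKlHypothesisProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=1e-6, max_value=1.0 - 1e-6),
    )
    @settings(derandomize=True, max_examples=200)
    def test_kl_nonnegative_and_zero_only_at_reference(self, a, p):
        value = kl_bernoulli(a, p)
        assert value >= 0.0
        if abs(a - p) > 1e-6:
            assert value > 0.0
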