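"""Modularity, Louvain, eigenvector roots, and temporal matching."""

import itertools

import networkx as nx
import numpy as np
import pytest

from comorbnet.communities import (
    CommunityPartition,
    _exact_overlap_p,
    community_roots,
    louvain_partition,
    match_and_correlate,
    modularity,
)


def weighted(edges):
    g = nx.Graph()
    for a, b, w in edges:
        g.add_edge(a, b, weight=w)
    return g


def modularity_oracle(g, membership):
    """Pairwise-sum definition, independent of the edge-loop implementation."""
    nodes = list(g.nodes)
    two_m = 2 * sum(d.get("weight", 1.0) for _, _, d in g.edges(data=True))
    if two_m == 0:
        return 0.0
    k = dict(g.degree(weight="weight"))
    q = 0.0
    for u in nodes:
        for v in nodes:
            if membership[u] != membership[v]:
                continue
            a = g.edges[u, v]["weight"] if g.has_edge(u, v) else 0.0
            q += a - k[u] * k[v] / two_m
    return q / two_m


def set_partitions(items):
    """All partitions of a list (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1 :]
        yield [[first]] + smaller


def two_triangles():
    return weighted(
        [("A", "B", 1), ("B", "C", 1), ("C", "A", 1),
         ("D", "E", 1), ("E", "F", 1), ("F", "D", 1)]
    )


class TestModularity:
    def test_two_disjoint_triangles_q_half(self):
        g = two_triangles()
        membership = {v: 0 if v in "ABC" else 1 for v in g.nodes}
        assert modularity(g, membership) == pytest.approx(0.5)

    def test_single_community_q_zero(self):
        g = two_triangles()
        assert modularity(g, {v: 0 for v in g.nodes}) == pytest.approx(0.0)

    def test_matches_pairwise_oracle_on_random_partitions(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            g = nx.gnp_random_graph(n, 0.6, seed=int(rng.integers(1 << 30)))
            for u, v in g.edges:
                g.edges[u, v]["weight"] = float(rng.uniform(0.1, 1))
            if g.number_of_edges() == 0:
                continue
            membership = {v: int(rng.integers(0, 3)) for v in g.nodes}
            assert modularity(g, membership) == pytest.approx(
                modularity_oracle(g, membership), abs=1e-12
            )

    def test_agrees_with_networkx(self):
        g = two_triangles()
        membership = {v: 0 if v in "ABC" else 1 for v in g.nodes}
        q_nx = nx.community.modularity(g, [{"A", "B", "C"}, {"D", "E", "F"}], weight="weight")
        assert modularity(g, membership) == pytest.approx(q_nx, abs=1e-12)

    def test_uncovered_node_errors(self):
        g = two_triangles()
        with pytest.raises(ValueError):
            modularity(g, {"A": 0})


class TestLouvain:
    def test_recovers_two_triangles(self):
        part = louvain_partition(two_triangles(), seed=0)
        assert part.q == pytest.approx(0.5)
        assert len(set(part.membership.values())) == 2
        assert part.membership["A"] == part.membership["B"] == part.membership["C"]

    def test_single_edge_graph(self):
        g = weighted([("A", "B", 1.0)])
        part = louvain_partition(g, seed=0)
        # exhaustive enumeration: one community and two singletons both give Q=0
        best = max(
            modularity(g, {v: i for i, block in enumerate(p) for v in block})
            for p in set_partitions(list(g.nodes))
        )
        assert part.q == pytest.approx(best)

    def test_q_self_consistent_and_beats_baselines(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            g = nx.gnp_random_graph(10, 0.4, seed=int(rng.integers(1 << 30)))
            for u, v in g.edges:
                g.edges[u, v]["weight"] = float(rng.uniform(0.1, 1))
            if g.number_of_edges() == 0:
                continue
            part = louvain_partition(g, seed=1)
            assert part.q == pytest.approx(modularity(g, part.membership), abs=1e-12)
            singletons = {v: i for i, v in enumerate(g.nodes)}
            one = {v: 0 for v in g.nodes}
            assert part.q >= modularity(g, singletons) - 1e-12
            assert part.q >= modularity(g, one) - 1e-12

    def test_empty_network_errors(self):
        with pytest.raises(ValueError):
            louvain_partition(nx.Graph(), seed=0)


class TestRoots:
    def test_star_root_is_center(self):
        g = weighted([("Z", "A", 1), ("Z", "B", 1), ("Z", "C", 1), ("Z", "D", 1)])
        roots, eigen = community_roots(g, {v: 0 for v in g.nodes})
        assert roots[0] == "Z"
        assert eigen["Z"] == max(eigen.values())

    def test_symmetric_cycle_tie_breaks_lexicographically(self):
        g = weighted([("A", "B", 1), ("B", "C", 1), ("C", "D", 1), ("D", "A", 1)])
        roots, _ = community_roots(g, {v: 0 for v in g.nodes})
        assert roots[0] == "A"

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(6)
        for _ in range(15):
            n = int(rng.integers(3, 13))
            g = nx.gnp_random_graph(n, 0.6, seed=int(rng.integers(1 << 30)))
            for u, v in g.edges:
                g.edges[u, v]["weight"] = float(rng.uniform(0.1, 1))
            if not nx.is_connected(g) or g.number_of_edges() == 0:
                continue
            _, eigen = community_roots(g, {v: 0 for v in g.nodes})
            nodes = sorted(g.nodes)
            a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
            w, vecs = np.linalg.eigh(a)
            principal = np.abs(vecs[:, np.argmax(w)])
            principal /= np.linalg.norm(principal)
            for i, v in enumerate(nodes):
                assert eigen[v] == pytest.approx(principal[i], abs=1e-6)


def _partition(groups):
    membership = {}
    roots = {}
    eigen = {}
    for ci, group in enumerate(groups):
        for j, node in enumerate(sorted(group)):
            membership[node] = ci
            eigen[node] = 1.0 / (j + 1)
        roots[ci] = sorted(group)[0]
    return CommunityPartition(membership=membership, q=0.3, roots=roots, eigen=eigen)


class TestMatching:
    def test_identical_communities_full_correlation(self):
        p0 = _partition([{"A", "B", "C", "D"}, {"E", "F", "G"}])
        rows = match_and_correlate(p0, p0)
        assert len(rows) == 2
        for row in rows:
            assert row.r == pytest.approx(1.0)
            assert row.n_shared in (3, 4)

    def test_disjoint_communities_dropped(self):
        p0 = _partition([{"A", "B", "C"}])
        p1 = _partition([{"X", "Y", "Z"}])
        assert match_and_correlate(p0, p1) == []

    def test_hand_example_matches_direct_pearson(self):
        from scipy import stats as ss

        others = set("GHIJKLMNOP")  # widen the universe so 3-of-4 is surprising
        p0 = _partition([{"A", "B", "C", "D"}, {"E", "F"}, others])
        p1 = _partition([{"A", "B", "C", "X"}, {"E", "F"}, others])
        rows = match_and_correlate(p0, p1)
        universe = sorted(set(p0.membership) | set(p1.membership))
        big = next(r for r in rows if r.n_shared == 3)
        v0 = np.array([n in {"A", "B", "C", "D"} for n in universe], float)
        v1 = np.array([n in {"A", "B", "C", "X"} for n in universe], float)
        assert big.r == pytest.approx(float(ss.pearsonr(v0, v1)[0]))

    def test_exact_overlap_p_matches_hypergeometric_enumeration(self):
        from scipy.stats import hypergeom

        n, s0, s1 = 30, 6, 8
        for o in range(0, 7):
            p = _exact_overlap_p(n, s0, s1, o)
            assert 0.0 <= p <= 1.0
        # upper tail at the mean is ~1
        assert _exact_overlap_p(n, s0, s1, 0) == pytest.approx(1.0)
        # a full overlap is maximally surprising
        assert _exact_overlap_p(n, s0, s1, 6) <= hypergeom(n, s0, s1).sf(4)
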