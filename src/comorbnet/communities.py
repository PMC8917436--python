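"""Community detection, community roots, and year-over-year community trends.

Communities are found with the weighted Louvain heuristic (best modularity Q
over seeded restarts).  Each community's *root* is its member with the
largest weighted eigenvector centrality in the full network.  Temporal
trends rebuild the whole pipeline on single calendar years, match
communities across consecutive years by shared membership, and score each
matched pair with the Pearson correlation of the two binary
membership-indicator vectors over the union of nodes; matches with p > .05
are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CommunityPartition:
    """A node->community map with its modularity and per-community root."""

    membership: dict[str, int]
    q: float
    roots: dict[int, str]
    eigen: dict[str, float]

    def communities(self) -> dict[int, frozenset[str]]:
        out: dict[int, set[str]] = {}
        for node, c in self.membership.items():
            out.setdefault(c, set()).add(node)
        return {c: frozenset(v) for c, v in out.items()}


@dataclass(frozen=True)
class TrendRow:
    """One matched community pair across consecutive years."""

    community_t: int
    community_t1: int
    root_t: str
    root_t1: str
    r: float
    p: float
    n_shared: int


def modularity(net: nx.Graph, membership: Mapping[str, int]) -> float:
    """Weighted Newman-Girvan modularity of a partition.

    Q = (1/2m) * sum_ij (A_ij - k_i k_j / 2m) delta(c_i, c_j), with k the
    weighted degree and m the total edge weight.
    """
    for node in net.nodes:
        if node not in membership:
            raise ValueError(f"membership does not cover node {node!r}")
    two_m = 2.0 * sum(d.get("weight", 1.0) for _, _, d in net.edges(data=True))
    if two_m == 0:
        return 0.0
    strength = dict(net.degree(weight="weight"))
    intra = 0.0
    for u, v, d in net.edges(data=True):
        if membership[u] == membership[v]:
            intra += d.get("weight", 1.0)
    expected = 0.0
    by_comm: dict[int, float] = {}
    for node, s in strength.items():
        by_comm[membership[node]] = by_comm.get(membership[node], 0.0) + s
    for s_sum in by_comm.values():
        expected += (s_sum / two_m) ** 2
    return 2.0 * intra / two_m - expected


def community_roots(
    net: nx.Graph,
    membership: Mapping[str, int],
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[dict[int, str], dict[str, float]]:
    """Roots (argmax weighted eigenvector centrality per community) and scores.

    Centrality is computed by power iteration on the full weighted
    adjacency matrix, L2-normalized; lexicographic tie-break on codes.
    """
    nodes = sorted(net.nodes)
    n = len(nodes)
    if n == 0:
        return {}, {}
    idx = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((n, n))
    for u, v, d in net.edges(data=True):
        w = d.get("weight", 1.0)
        a[idx[u], idx[v]] = w
        a[idx[v], idx[u]] = w
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        # shifted iteration (A + I)x: same eigenvectors, but the principal
        # eigenvalue strictly dominates even on bipartite graphs
        y = a @ x + x
        norm = np.linalg.norm(y)
        if norm == 0:
            break  # edgeless graph: centrality degenerates to the start vector
        y /= norm
        if np.max(np.abs(y - x)) < tol:
            x = y
            break
        x = y
    else:
        raise RuntimeError("eigenvector centrality power iteration did not converge")

    eigen = {v: float(x[idx[v]]) for v in nodes}
    roots: dict[int, str] = {}
    for node in nodes:  # lexicographic order makes ties deterministic
        c = membership[node]
        if c not in roots or eigen[node] > eigen[roots[c]]:
            roots[c] = node
    return roots, eigen


def louvain_partition(
    net: nx.Graph, seed: int = 0, n_restarts: int = 10
) -> CommunityPartition:
    """Weighted Louvain partition; best modularity over seeded restarts."""
    if net.number_of_edges() == 0:
        raise ValueError("community detection needs a network with >= 1 edge")
    best_membership: dict[str, int] | None = None
    best_q = -np.inf
    for i in range(n_restarts):
        comms = nx.community.louvain_communities(
            net, weight="weight", seed=int(seed) + i
        )
        membership = {
            node: ci
            for ci, comm in enumerate(sorted(comms, key=lambda c: min(c)))
            for node in comm
        }
        q = modularity(net, membership)
        if q > best_q:
            best_q = q
            best_membership = membership
    assert best_membership is not None
    roots, eigen = community_roots(net, best_membership)
    return CommunityPartition(
        membership=best_membership, q=best_q, roots=roots, eigen=eigen
    )


def _exact_overlap_p(n: int, s0: int, s1: int, overlap: int) -> float:
    """Exact two-sided permutation p-value of the binary-indicator correlation.

    Under random placement of the two membership sets (margins fixed) the
    overlap is hypergeometric; the correlation is monotone in the overlap,
    so the two-sided p sums both hypergeometric tails at least as extreme
    in |r|.
    """
    hg = stats.hypergeom(n, s0, s1)
    mean = s0 * s1 / n
    upper = hg.sf(overlap - 1)  # P(X >= overlap)
    # lower tail: overlaps at least as far below the mean
    lo = int(np.floor(mean - (overlap - mean)))
    lower = hg.cdf(lo) if overlap >= mean else 1.0
    return float(min(1.0, upper + lower if overlap >= mean else 1.0))


def match_and_correlate(
    partition_t: CommunityPartition,
    partition_t1: CommunityPartition,
    alpha: float = 0.05,
) -> list[TrendRow]:
    """Match communities across two consecutive years and score similarity.

    Matching is greedy on shared-member count (ties: Jaccard, then the
    lexicographically smaller root pair).  Similarity is the Pearson
    correlation of the binary membership indicators over the union of all
    nodes present in either year; pairs with p > alpha are dropped.

    The p-value is the exact two-sided permutation p of the correlation
    given the community sizes, i.e. a hypergeometric tail on the overlap
    count.  (The asymptotic t-based p of a Pearson correlation is badly
    anticonservative for sparse binary vectors: over ~150 nodes it calls
    a chance overlap of 2 codes between two 8-code communities
    "significant".)
    """
    comms_t = partition_t.communities()
    comms_t1 = partition_t1.communities()
    universe = sorted(set(partition_t.membership) | set(partition_t1.membership))
    if not universe:
        return []

    candidates = []
    for c0, m0 in comms_t.items():
        for c1, m1 in comms_t1.items():
            shared = len(m0 & m1)
            if shared == 0:
                continue
            jac = shared / len(m0 | m1)
            candidates.append((shared, jac, c0, c1))
    candidates.sort(
        key=lambda t: (
            -t[0],
            -t[1],
            partition_t.roots.get(t[2], ""),
            partition_t1.roots.get(t[3], ""),
        )
    )

    used_t: set[int] = set()
    used_t1: set[int] = set()
    rows: list[TrendRow] = []
    for shared, _jac, c0, c1 in candidates:
        if c0 in used_t or c1 in used_t1:
            continue
        used_t.add(c0)
        used_t1.add(c1)
        v0 = np.array([node in comms_t[c0] for node in universe], dtype=float)
        v1 = np.array([node in comms_t1[c1] for node in universe], dtype=float)
        if v0.std() == 0 or v1.std() == 0:
            continue
        r, _ = stats.pearsonr(v0, v1)
        p = _exact_overlap_p(
            n=len(universe), s0=len(comms_t[c0]), s1=len(comms_t1[c1]), overlap=shared
        )
        if p > alpha:
            continue
        rows.append(
            TrendRow(
                community_t=c0,
                community_t1=c1,
                root_t=partition_t.roots.get(c0, ""),
                root_t1=partition_t1.roots.get(c1, ""),
                r=float(r),
                p=float(p),
                n_shared=shared,
            )
        )
    return rows


def yearly_networks(
    records,
    years,
    chronic_codes,
    sex_specific,
    symptom_prefixes=("R",),
    alpha: float = 0.01,
    prevalence_threshold: float = 0.01,
):
    """Re-run the full pipeline with a one-year window per calendar year.

    Multimorbidity and the prevalence screen are re-evaluated within each
    single year, so a patient multimorbid only across two different years
    is multimorbid in neither year's network.  Returns
    ``{year: {sex: merged sex-level network}}``.
    """
    from .analysis import analyze_window

    out = {}
    for year in years:
        wa = analyze_window(
            records,
            window=(year, year),
            chronic_codes=chronic_codes,
            sex_specific=sex_specific,
            symptom_prefixes=symptom_prefixes,
            alpha=alpha,
            prevalence_threshold=prevalence_threshold,
        )
        out[year] = {sex: sn.merged for sex, sn in wa.by_sex.items()}
    return out


def temporal_trends(
    networks_by_year: Mapping[int, nx.Graph],
    seed: int = 0,
    n_restarts: int = 10,
    alpha: float = 0.05,
) -> tuple[dict[int, CommunityPartition], dict[tuple[int, int], list[TrendRow]]]:
    """Partition each year's network and match communities across years.

    Years whose network has no edge get no partition and break the chain
    of consecutive-year comparisons at that point.
    """
    partitions: dict[int, CommunityPartition] = {}
    for year in sorted(networks_by_year):
        net = networks_by_year[year]
        if net.number_of_edges() > 0:
            partitions[year] = louvain_partition(net, seed=seed, n_restarts=n_restarts)
    trends: dict[tuple[int, int], list[TrendRow]] = {}
    years = sorted(partitions)
    for y0, y1 in zip(years, years[1:]):
        if y1 - y0 == 1:
            trends[(y0, y1)] = match_and_correlate(
                partitions[y0], partitions[y1], alpha=alpha
            )
    return partitions, trends


__all__ = [
    "CommunityPartition",
    "TrendRow",
    "modularity",
    "community_roots",
    "louvain_partition",
    "match_and_correlate",
    "yearly_networks",
    "temporal_trends",
]
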