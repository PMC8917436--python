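"""Multimorbidity network assembly and topology metrics.

Networks are undirected :class:`networkx.Graph` objects.  Nodes are
3-character disease codes annotated with ``prevalence`` (unique-patient
proportion) and ``chapter`` (the ICD-10 chapter letter); edges carry the
Salton cosine index as ``weight``.  Per-stratum networks are merged into a
sex-level network whose edge weight is the maximum SCI across contributing
strata (per-stratum values are retained in edge metadata).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx

from .pairs import CutoffResult


@dataclass(frozen=True)
class TopologyReport:
    """Global structural indices of one network.

    Path-based metrics use unweighted shortest paths; on disconnected
    networks the diameter is the maximum over components and the average
    path length is the mean over all connected node pairs.  Closeness uses
    the Wasserman-Faust component scaling; betweenness is unnormalized.
    """

    n_nodes: int
    n_edges: int
    density: float
    diameter: float
    avg_path_length: float
    avg_degree: float
    avg_weighted_degree: float
    avg_closeness: float
    avg_betweenness: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density": self.density,
            "diameter": self.diameter,
            "avg_path_length": self.avg_path_length,
            "avg_degree": self.avg_degree,
            "avg_weighted_degree": self.avg_weighted_degree,
            "avg_closeness": self.avg_closeness,
            "avg_betweenness": self.avg_betweenness,
        }


def build_stratum_network(
    cutoff: CutoffResult,
    sex: str,
    stratum_label: str,
    prevalences: Mapping[str, float] | None = None,
) -> nx.Graph:
    """Network of one sex-age group: kept pairs as edges, endpoints as nodes.

    Isolated codes are excluded by construction.  ``prevalences`` maps a
    code to its unique-patient prevalence in the group (n_a / N_total).
    """
    g = nx.Graph(sex=sex, stratum=stratum_label)
    for p in cutoff.kept:
        a, b = p.counts.code_a, p.counts.code_b
        g.add_edge(a, b, weight=p.sci, rr=p.rr, phi=p.phi, n_ab=p.counts.n_ab)
    for node in g.nodes:
        g.nodes[node]["chapter"] = node[0]
        prev = None if prevalences is None else prevalences.get(node)
        g.nodes[node]["prevalence"] = float(prev) if prev is not None else float("nan")
    return g


def merge_networks(
    networks: Sequence[nx.Graph],
    prevalences: Mapping[str, float] | None = None,
) -> nx.Graph:
    """Union of one sex's stratum networks into the sex-level network.

    The merged weight of an edge is the maximum SCI over the strata where
    it appears; ``strata`` and ``sci_by_stratum`` edge attributes keep the
    provenance.  Node prevalence is taken from ``prevalences`` (intended:
    prevalence among the sex's multimorbid patients); without it the
    maximum stratum prevalence is carried over.
    """
    sexes = {g.graph.get("sex") for g in networks}
    if len(sexes) > 1:
        raise ValueError(f"cannot merge networks of different sexes: {sexes}")
    merged = nx.Graph(sex=next(iter(sexes)) if sexes else None, stratum="all-ages")

    for g in networks:
        label = g.graph.get("stratum", "?")
        for a, b, data in g.edges(data=True):
            w = data["weight"]
            if merged.has_edge(a, b):
                e = merged.edges[a, b]
                e["sci_by_stratum"][label] = w
                e["strata"].append(label)
                if w > e["weight"]:
                    e["weight"] = w
            else:
                merged.add_edge(
                    a, b, weight=w, strata=[label], sci_by_stratum={label: w}
                )
        for node, data in g.nodes(data=True):
            if node not in merged:
                continue
            old = merged.nodes[node].get("prevalence", float("nan"))
            new = data.get("prevalence", float("nan"))
            if math.isnan(old) or (not math.isnan(new) and new > old):
                merged.nodes[node]["prevalence"] = new
            merged.nodes[node]["chapter"] = node[0]

    if prevalences is not None:
        for node in merged.nodes:
            if node in prevalences:
                merged.nodes[node]["prevalence"] = float(prevalences[node])
    return merged


def topology_metrics(net: nx.Graph) -> TopologyReport:
    """Compute the structural indices; NaN path metrics for n < 2."""
    n = net.number_of_nodes()
    m = net.number_of_edges()
    nan = float("nan")
    if n < 2:
        return TopologyReport(n, m, nan, nan, nan, nan, nan, nan, nan)

    density = 2.0 * m / (n * (n - 1))
    avg_degree = 2.0 * m / n
    avg_weighted_degree = 2.0 * sum(d["weight"] for _, _, d in net.edges(data=True)) / n

    diameter = 0.0
    path_sum = 0.0
    path_pairs = 0
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        k = len(comp)
        if k < 2:
            continue
        ecc = nx.eccentricity(sub)
        diameter = max(diameter, max(ecc.values()))
        path_sum += nx.average_shortest_path_length(sub) * k * (k - 1)
        path_pairs += k * (k - 1)
    avg_path = path_sum / path_pairs if path_pairs else nan
    if path_pairs == 0:
        diameter = nan

    closeness = nx.closeness_centrality(net, wf_improved=True)
    betweenness = nx.betweenness_centrality(net, normalized=False)
    return TopologyReport(
        n_nodes=n,
        n_edges=m,
        density=density,
        diameter=float(diameter),
        avg_path_length=avg_path,
        avg_degree=avg_degree,
        avg_weighted_degree=avg_weighted_degree,
        avg_closeness=sum(closeness.values()) / n,
        avg_betweenness=sum(betweenness.values()) / n,
    )


__all__ = ["TopologyReport", "build_stratum_network", "merge_networks", "topology_metrics"]
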