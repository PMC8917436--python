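"""Disease roles: central diseases, hubs, and degree-leap bursts.

Within each sex-age network, *central diseases* are the top-10-percentile
nodes by weighted PageRank and *hubs* are the top-10-percentile nodes by
connectivity (sum of incident SCI weights).  Across the 16 age strata of
one sex, each disease has a degree trajectory; a *burst* is a disease whose
degree jumps by >= 6 between consecutive strata at least twice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .strata import N_STRATA, STRATUM_LABELS


@dataclass(frozen=True)
class RoleConfig:
    """Tunables for role detection (defaults follow common practice)."""

    damping: float = 0.85       # PageRank teleport probability complement
    epsilon: float = 0.001      # PageRank convergence tolerance (max change)
    percentile: float = 90.0    # top (100 - percentile)% are central/hubs
    leap_threshold: int = 6     # minimum degree increase counting as a leap
    min_leaps: int = 2          # leaps needed for a burst

    def __post_init__(self) -> None:
        if not 0 < self.damping < 1:
            raise ValueError("damping must lie in (0, 1)")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must lie in (0, 100)")
        if self.leap_threshold < 1:
            raise ValueError("leap_threshold must be >= 1")


@dataclass(frozen=True)
class DegreeTrajectory:
    """Per-stratum network degree of one disease for one sex."""

    code: str
    sex: str
    degrees: tuple[int, ...]  # length 16, 0 where the code is absent

    def leap_flags(self, threshold: int = 6) -> tuple[bool, ...]:
        """Flag per consecutive-stratum boundary: degree rises >= threshold."""
        return tuple(
            self.degrees[i + 1] - self.degrees[i] >= threshold
            for i in range(len(self.degrees) - 1)
        )


def pagerank_scores(net: nx.Graph, config: RoleConfig = RoleConfig()) -> dict[str, float]:
    """Weighted PageRank on the undirected network.

    Each edge acts as two directed arcs with transition probability
    proportional to its SCI weight; iteration stops when the largest score
    change falls below ``config.epsilon``.  Scores sum to 1.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("PageRank needs a non-empty network")
    nodes = sorted(net.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((n, n))
    for u, v, data in net.edges(data=True):
        w = data.get("weight", 1.0)
        a[idx[u], idx[v]] = w
        a[idx[v], idx[u]] = w
    strength = a.sum(axis=1)
    p = np.divide(a, strength[:, None], out=np.full_like(a, 1.0 / n), where=strength[:, None] > 0)

    d = config.damping
    r = np.full(n, 1.0 / n)
    for _ in range(1000):
        r_new = (1.0 - d) / n + d * (p.T @ r)
        if np.max(np.abs(r_new - r)) < config.epsilon:
            r = r_new
            break
        r = r_new
    return {v: float(r[idx[v]]) for v in nodes}


def percentile_select(values: Mapping[str, float], percentile: float = 90.0) -> set[str]:
    """Top (100 - percentile)% of keys by value, ties at the cutoff included.

    The selected count before ties is m = n - ceil(n * percentile / 100),
    floored at 1 so every non-empty group names at least one disease.
    """
    n = len(values)
    if n == 0:
        return set()
    m = max(1, n - math.ceil(n * percentile / 100.0))
    cutoff = sorted(values.values(), reverse=True)[m - 1]
    return {k for k, v in values.items() if v >= cutoff}


def central_diseases(
    scores: Mapping[str, float], config: RoleConfig = RoleConfig()
) -> set[str]:
    """Central diseases of one stratum: top-percentile PageRank nodes."""
    return percentile_select(scores, config.percentile)


def connectivity(net: nx.Graph) -> dict[str, float]:
    """Weighted degree: sum of incident SCI weights (0 for isolated nodes)."""
    return {v: float(s) for v, s in net.degree(weight="weight")}


def hubs(
    connectivity_scores: Mapping[str, float], config: RoleConfig = RoleConfig()
) -> set[str]:
    """Hubs of one stratum: top-percentile connectivity nodes."""
    return percentile_select(connectivity_scores, config.percentile)


def degree_trajectories(
    stratum_networks: Sequence[nx.Graph], sex: str
) -> dict[str, DegreeTrajectory]:
    """Per-disease degree (k) across the 16 age strata of one sex."""
    if len(stratum_networks) != N_STRATA:
        raise ValueError(f"expected {N_STRATA} stratum networks")
    codes = sorted({v for g in stratum_networks for v in g.nodes})
    out = {}
    for code in codes:
        degrees = tuple(
            int(g.degree(code)) if code in g else 0 for g in stratum_networks
        )
        out[code] = DegreeTrajectory(code=code, sex=sex, degrees=degrees)
    return out


def detect_bursts(traj: DegreeTrajectory, config: RoleConfig = RoleConfig()) -> bool:
    """True iff the trajectory has >= min_leaps degree leaps >= leap_threshold."""
    return sum(traj.leap_flags(config.leap_threshold)) >= config.min_leaps


def first_leap_age(
    traj: DegreeTrajectory, threshold: int = 6
) -> str | None:
    """Label of the stratum entered at the earliest leap, or None."""
    for i, flag in enumerate(traj.leap_flags(threshold)):
        if flag:
            return STRATUM_LABELS[i + 1]
    return None


__all__ = [
    "RoleConfig",
    "DegreeTrajectory",
    "pagerank_scores",
    "percentile_select",
    "central_diseases",
    "connectivity",
    "hubs",
    "degree_trajectories",
    "detect_bursts",
    "first_leap_age",
]
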