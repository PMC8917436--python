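"""One-window analysis: records -> profiles -> pair stats -> networks.

This is the computational core shared by the end-to-end pipeline and the
year-by-year temporal analysis: apply the eligibility filters, build
patient profiles over the window, screen diseases at >=1% prevalence,
compute pair statistics and the SCI cutoff per sex-age group, build the 16
stratum networks per sex and merge them into the sex-level network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .cohort import (
    DischargeRecord,
    ExclusionLog,
    PatientProfile,
    SEXES,
    build_profiles,
    filter_records,
    prevalence_filter,
)
from .network import build_stratum_network, merge_networks
from .pairs import (
    CutoffResult,
    PairStats,
    compute_pair_stats,
    count_pairs,
    exclude_negative_pairs,
    find_sci_cutoff,
)
from .strata import N_STRATA, STRATUM_LABELS


@dataclass
class StratumAnalysis:
    """Pair statistics and network of one sex-age group."""

    sex: str
    stratum_index: int
    n_total: int
    pair_stats: list[PairStats]          # after the RR/phi exclusion
    cutoff: CutoffResult
    network: nx.Graph


@dataclass
class SexNetworks:
    """All per-stratum analyses of one sex plus the merged network."""

    sex: str
    strata: list[StratumAnalysis]
    merged: nx.Graph

    @property
    def stratum_networks(self) -> list[nx.Graph]:
        return [s.network for s in self.strata]


@dataclass
class WindowAnalysis:
    """Full analysis of one calendar window."""

    window: tuple[int, int]
    exclusions: ExclusionLog
    profiles: list[PatientProfile]
    retained: dict[str, frozenset[str]]
    by_sex: dict[str, SexNetworks]


def multimorbid_prevalences(
    profiles: Sequence[PatientProfile], sex: str
) -> dict[str, float]:
    """Per-code prevalence among one sex's multimorbid patients."""
    mm = [p for p in profiles if p.sex == sex and p.is_multimorbid]
    if not mm:
        return {}
    counts: dict[str, int] = {}
    for p in mm:
        for c in p.chronic_codes:
            counts[c] = counts.get(c, 0) + 1
    return {c: n / len(mm) for c, n in counts.items()}


def analyze_window(
    records: Sequence[DischargeRecord],
    window: tuple[int, int],
    chronic_codes: Iterable[str],
    sex_specific: Mapping[str, str],
    symptom_prefixes: Iterable[str] = ("R",),
    alpha: float = 0.01,
    prevalence_threshold: float = 0.01,
) -> WindowAnalysis:
    """Run the full filtering/screening/network construction for one window."""
    kept, log = filter_records(records, sex_specific, symptom_prefixes)
    profiles = build_profiles(kept, chronic_codes, window)
    retained, profiles = prevalence_filter(profiles, prevalence_threshold)

    by_sex: dict[str, SexNetworks] = {}
    for sex in SEXES:
        sex_profiles = [p for p in profiles if p.sex == sex]
        strata_results: list[StratumAnalysis] = []
        for idx in range(N_STRATA):
            cell = [p for p in sex_profiles if p.stratum.index == idx]
            counts = count_pairs(cell, sorted(retained[sex]))
            stats = compute_pair_stats(counts.pairs, alpha)
            positive = exclude_negative_pairs(stats)
            cutoff = find_sci_cutoff(positive, alpha)
            prevalences = {
                c: n / counts.n_total if counts.n_total else 0.0
                for c, n in counts.marginals.items()
            }
            net = build_stratum_network(
                cutoff, sex, STRATUM_LABELS[idx], prevalences
            )
            strata_results.append(
                StratumAnalysis(
                    sex=sex,
                    stratum_index=idx,
                    n_total=counts.n_total,
                    pair_stats=positive,
                    cutoff=cutoff,
                    network=net,
                )
            )
        merged = merge_networks(
            [s.network for s in strata_results],
            prevalences=multimorbid_prevalences(profiles, sex),
        )
        merged.graph["sex"] = sex
        by_sex[sex] = SexNetworks(sex=sex, strata=strata_results, merged=merged)

    return WindowAnalysis(
        window=window,
        exclusions=log,
        profiles=profiles,
        retained=retained,
        by_sex=by_sex,
    )


__all__ = [
    "StratumAnalysis",
    "SexNetworks",
    "WindowAnalysis",
    "analyze_window",
    "multimorbid_prevalences",
]
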