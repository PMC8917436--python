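"""End-to-end pipeline: cohort -> pairs -> networks -> roles -> communities -> trends.

Every run writes a manifest (config, config hash, seed) and an exclusion
log mirroring the cohort selection flow.  Outputs are plain CSV/GraphML/
JSON, written deterministically: identical config and seed reproduce
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .analysis import WindowAnalysis, analyze_window
from .cohort import SEXES, summarize_cohort
from .communities import CommunityPartition, louvain_partition, temporal_trends, yearly_networks
from .config import PipelineConfig
from .defaults import DEFAULT_CHRONIC_CODES, DEFAULT_SEX_SPECIFIC
from .io import read_chronic_list, read_records, read_sex_specific, write_graphml
from .network import topology_metrics
from .roles import (
    central_diseases,
    connectivity,
    degree_trajectories,
    detect_bursts,
    first_leap_age,
    hubs,
    pagerank_scores,
)
from .strata import STRATUM_LABELS

_FLOAT_FMT = "%.10g"


@dataclass
class ReportBundle:
    """In-memory results of one pipeline run."""

    analysis: WindowAnalysis
    cohort_summary: pd.DataFrame
    pair_table: pd.DataFrame
    topology: pd.DataFrame
    roles: pd.DataFrame
    bursts: pd.DataFrame
    partitions: dict[str, CommunityPartition]
    memberships: pd.DataFrame
    trends: pd.DataFrame
    exclusions: dict[str, int] = field(default_factory=dict)


def _pair_table(analysis: WindowAnalysis) -> pd.DataFrame:
    rows = []
    for sex in SEXES:
        for sa in analysis.by_sex[sex].strata:
            kept = {(p.counts.code_a, p.counts.code_b) for p in sa.cutoff.kept}
            for p in sa.pair_stats:
                c = p.counts
                rows.append(
                    {
                        "sex": sex,
                        "stratum": STRATUM_LABELS[sa.stratum_index],
                        "code_a": c.code_a,
                        "code_b": c.code_b,
                        "n_a": c.n_a,
                        "n_b": c.n_b,
                        "n_ab": c.n_ab,
                        "n_total": c.n_total,
                        "rr": p.rr,
                        "phi": p.phi,
                        "phi_significant": p.phi_significant,
                        "sci": p.sci,
                        "kept": (c.code_a, c.code_b) in kept,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "sex", "stratum", "code_a", "code_b", "n_a", "n_b", "n_ab",
            "n_total", "rr", "phi", "phi_significant", "sci", "kept",
        ],
    )


def _topology_table(analysis: WindowAnalysis) -> pd.DataFrame:
    rows = []
    for sex in SEXES:
        sn = analysis.by_sex[sex]
        for sa in sn.strata:
            rows.append(
                {"sex": sex, "stratum": STRATUM_LABELS[sa.stratum_index]}
                | topology_metrics(sa.network).as_dict()
            )
        rows.append({"sex": sex, "stratum": "all-ages"} | topology_metrics(sn.merged).as_dict())
    return pd.DataFrame(rows)


def _role_tables(analysis: WindowAnalysis, config: PipelineConfig):
    role_rows, burst_rows = [], []
    for sex in SEXES:
        sn = analysis.by_sex[sex]
        for sa in sn.strata:
            net = sa.network
            if net.number_of_nodes() == 0:
                continue
            scores = pagerank_scores(net, config.roles)
            central = central_diseases(scores, config.roles)
            conn = connectivity(net)
            hub_set = hubs(conn, config.roles)
            for code in sorted(net.nodes):
                role_rows.append(
                    {
                        "sex": sex,
                        "stratum": STRATUM_LABELS[sa.stratum_index],
                        "code": code,
                        "pagerank": scores[code],
                        "is_central": code in central,
                        "connectivity": conn[code],
                        "is_hub": code in hub_set,
                    }
                )
        trajectories = degree_trajectories(sn.stratum_networks, sex)
        for code in sorted(trajectories):
            traj = trajectories[code]
            burst_rows.append(
                {
                    "sex": sex,
                    "code": code,
                    "is_burst": detect_bursts(traj, config.roles),
                    "first_leap_age": first_leap_age(traj, config.roles.leap_threshold)
                    or "",
                    "degrees": "|".join(str(d) for d in traj.degrees),
                }
            )
    return pd.DataFrame(role_rows), pd.DataFrame(burst_rows)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage and write all artifacts under ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []

    def stage(name):
        def wrap(fn):
            try:
                result = fn()
            except Exception as exc:  # annotate failures with the stage name
                _write_manifest(config, out, completed, failed=name)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            completed.append(name)
            return result
        return wrap

    records, n_malformed = stage("read")(
        lambda: read_records(config.records_path)
    )
    chronic = (
        read_chronic_list(config.chronic_list_path)
        if config.chronic_list_path
        else frozenset(DEFAULT_CHRONIC_CODES)
    )
    sex_specific = (
        read_sex_specific(config.sex_specific_path)
        if config.sex_specific_path
        else dict(DEFAULT_SEX_SPECIFIC)
    )

    analysis = stage("cohort+networks")(
        lambda: analyze_window(
            records,
            window=config.window,
            chronic_codes=chronic,
            sex_specific=sex_specific,
            symptom_prefixes=config.symptom_prefixes,
            alpha=config.alpha,
            prevalence_threshold=config.prevalence_threshold,
        )
    )

    summary = stage("summary")(lambda: summarize_cohort(analysis.profiles))
    pair_table = stage("pairs")(lambda: _pair_table(analysis))
    topology = stage("topology")(lambda: _topology_table(analysis))
    roles_df, bursts_df = stage("roles")(lambda: _role_tables(analysis, config))

    def _communities():
        partitions: dict[str, CommunityPartition] = {}
        rows = []
        for sex in SEXES:
            merged = analysis.by_sex[sex].merged
            if merged.number_of_edges() == 0:
                continue
            part = louvain_partition(
                merged, seed=config.seed, n_restarts=config.louvain_restarts
            )
            partitions[sex] = part
            for code in sorted(part.membership):
                comm = part.membership[code]
                rows.append(
                    {
                        "year": "all",
                        "sex": sex,
                        "code": code,
                        "community": comm,
                        "eigen": part.eigen[code],
                        "is_root": part.roots[comm] == code,
                        "q": part.q,
                    }
                )
        return partitions, pd.DataFrame(rows)

    partitions, memberships = stage("communities")(_communities)

    def _trends():
        nets_by_year = yearly_networks(
            records,
            config.years(),
            chronic_codes=chronic,
            sex_specific=sex_specific,
            symptom_prefixes=config.symptom_prefixes,
            alpha=config.alpha,
            prevalence_threshold=config.prevalence_threshold,
        )
        rows = []
        for sex in SEXES:
            by_year = {y: nets[sex] for y, nets in nets_by_year.items()}
            _parts, trend_map = temporal_trends(
                by_year, seed=config.seed, n_restarts=config.louvain_restarts
            )
            for (y0, y1), trend_rows in sorted(trend_map.items()):
                for t in trend_rows:
                    rows.append(
                        {
                            "sex": sex,
                            "year_t": y0,
                            "year_t1": y1,
                            "community_t": t.community_t,
                            "community_t1": t.community_t1,
                            "root_t": t.root_t,
                            "root_t1": t.root_t1,
                            "r": t.r,
                            "p": t.p,
                            "n": t.n_shared,
                        }
                    )
        return pd.DataFrame(
            rows,
            columns=[
                "sex", "year_t", "year_t1", "community_t", "community_t1",
                "root_t", "root_t1", "r", "p", "n",
            ],
        )

    trends = stage("trends")(_trends)

    # ---- write artifacts -------------------------------------------------
    exclusions = analysis.exclusions.as_dict() | {"malformed_codes": n_malformed}
    (out / "exclusions.json").write_text(json.dumps(exclusions, indent=2, sort_keys=True))
    summary.to_csv(out / "cohort_summary.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(
        [
            {"sex": sex, "code": code}
            for sex in SEXES
            for code in sorted(analysis.retained[sex])
        ]
    ).to_csv(out / "retained_codes.csv", index=False)
    pair_table.to_csv(out / "pair_stats.csv", index=False, float_format=_FLOAT_FMT)
    topology.to_csv(out / "topology.csv", index=False, float_format=_FLOAT_FMT)
    roles_df.to_csv(out / "roles.csv", index=False, float_format=_FLOAT_FMT)
    bursts_df.to_csv(out / "bursts.csv", index=False, float_format=_FLOAT_FMT)
    memberships.to_csv(out / "communities.csv", index=False, float_format=_FLOAT_FMT)
    trends.to_csv(out / "trends.csv", index=False, float_format=_FLOAT_FMT)
    for sex in SEXES:
        write_graphml(analysis.by_sex[sex].merged, out / f"network_{sex}.graphml")
    completed.append("write")
    _write_manifest(config, out, completed, failed=None)

    return ReportBundle(
        analysis=analysis,
        cohort_summary=summary,
        pair_table=pair_table,
        topology=topology,
        roles=roles_df,
        bursts=bursts_df,
        partitions=partitions,
        memberships=memberships,
        trends=trends,
        exclusions=exclusions,
    )


def _write_manifest(
    config: PipelineConfig, out: Path, completed: list[str], failed: str | None
) -> None:
    manifest = {
        "config": config.as_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "completed_stages": completed,
        "failed_stage": failed,
        "inputs": {
            "records": config.records_path,
            "chronic_list": config.chronic_list_path or "<packaged default>",
            "sex_specific": config.sex_specific_path or "<packaged default>",
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


__all__ = ["ReportBundle", "run_pipeline"]
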