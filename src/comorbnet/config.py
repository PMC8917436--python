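"""End-to-end pipeline configuration.

Defaults follow the analysis constants used throughout the package:
significance level alpha = .01, prevalence screen >= 1%, PageRank damping
.85 with tolerance .001, degree-leap threshold 6, top-10-percentile
central diseases and hubs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .roles import RoleConfig


@dataclass
class PipelineConfig:
    records_path: str
    output_dir: str
    chronic_list_path: str | None = None   # None -> packaged illustrative default
    sex_specific_path: str | None = None   # None -> packaged default
    window: tuple[int, int] = (2015, 2019)
    alpha: float = 0.01
    prevalence_threshold: float = 0.01
    symptom_prefixes: tuple[str, ...] = ("R",)
    roles: RoleConfig = field(default_factory=RoleConfig)
    louvain_restarts: int = 10
    seed: int = 0
    trend_years: tuple[int, ...] | None = None  # None -> every year in window

    def years(self) -> tuple[int, ...]:
        if self.trend_years is not None:
            return tuple(self.trend_years)
        return tuple(range(self.window[0], self.window[1] + 1))

    def as_dict(self) -> dict:
        d = asdict(self)
        d["roles"] = asdict(self.roles)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        roles = RoleConfig(**data.pop("roles", {}))
        for key in ("window", "symptom_prefixes", "trend_years"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(roles=roles, **data)


__all__ = ["PipelineConfig"]
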