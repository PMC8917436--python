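"""The 16 age bands used for all stratified analyses.

Bands: <7, 7-14, then 5-year bands from 15-19 up to 75-79, and an
open-ended 80+ band. Band bounds are inclusive on both ends.
"""

from __future__ import annotations

from dataclasses import dataclass

N_STRATA = 16

STRATUM_LABELS: tuple[str, ...] = (
    "<7",
    "7-14",
    "15-19",
    "20-24",
    "25-29",
    "30-34",
    "35-39",
    "40-44",
    "45-49",
    "50-54",
    "55-59",
    "60-64",
    "65-69",
    "70-74",
    "75-79",
    "80+",
)

# (low, high) in completed years; high is inclusive, None = open-ended.
STRATUM_BOUNDS: tuple[tuple[int, int | None], ...] = (
    (0, 6),
    (7, 14),
    (15, 19),
    (20, 24),
    (25, 29),
    (30, 34),
    (35, 39),
    (40, 44),
    (45, 49),
    (50, 54),
    (55, 59),
    (60, 64),
    (65, 69),
    (70, 74),
    (75, 79),
    (80, None),
)


@dataclass(frozen=True)
class AgeStratum:
    """One age band: its index (0-15), printable label and year bounds."""

    index: int
    label: str
    low: int
    high: int | None  # inclusive; None for the open-ended 80+ band


AGE_STRATA: tuple[AgeStratum, ...] = tuple(
    AgeStratum(i, STRATUM_LABELS[i], *STRATUM_BOUNDS[i]) for i in range(N_STRATA)
)


def stratum_index(age_years: int) -> int:
    """Map an age in completed years to its stratum index (0-15)."""
    if age_years < 0:
        raise ValueError(f"age must be non-negative, got {age_years}")
    if age_years < 7:
        return 0
    if age_years < 15:
        return 1
    if age_years >= 80:
        return 15
    return 2 + (age_years - 15) // 5


def stratum_of(age_years: int) -> AgeStratum:
    """Return the :class:`AgeStratum` containing ``age_years``."""
    return AGE_STRATA[stratum_index(age_years)]
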