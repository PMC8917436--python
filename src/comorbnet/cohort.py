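"""Cohort construction: from raw discharge records to chronic-disease profiles.

A hospitalization is a :class:`DischargeRecord`; a patient observed over an
analysis window becomes a :class:`PatientProfile` holding the set of distinct
chronic 3-character diagnosis codes accumulated over all their admissions in
the window.  Multimorbidity is the co-existence of two or more chronic
conditions in one patient within the window.

The eligibility filters mirror routine discharge-data cleaning:

* admissions coded *only* with general symptoms (by default the R chapter)
  are dropped;
* patients carrying a diagnosis restricted to the opposite sex are removed
  entirely (a data-quality signal, so removal is patient-level);
* codes outside the disease range A00-R99 are stripped from records.

Diseases are then screened for >=1% unique-patient prevalence in at least
one sex-age stratum before any pairwise analysis.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .strata import AgeStratum, N_STRATA, stratum_index, stratum_of

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}$")

SEXES = ("M", "F")


def normalize_code(code: str) -> str:
    """Upper-case and truncate a diagnosis code to its 3-character category."""
    return code.strip().upper()[:3]


def is_valid_code(code: str) -> bool:
    return bool(_CODE_RE.match(code))


def in_disease_range(code: str) -> bool:
    """True for codes in the disease range A00-R99."""
    return is_valid_code(code) and "A" <= code[0] <= "R"


@dataclass(frozen=True)
class DischargeRecord:
    """One hospitalization: patient, sex, age at admission, year, diagnoses.

    ``codes`` holds the principal plus secondary 3-character diagnosis
    codes, de-duplicated, order preserved.
    """

    patient_id: str
    sex: str
    age_years: int
    year: int
    codes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age_years < 0:
            raise ValueError("age_years must be non-negative")
        if not self.codes:
            raise ValueError("a record needs at least one diagnosis code")
        deduped = tuple(dict.fromkeys(normalize_code(c) for c in self.codes))
        object.__setattr__(self, "codes", deduped)


@dataclass(frozen=True)
class PatientProfile:
    """One patient in one analysis window."""

    patient_id: str
    sex: str
    stratum: AgeStratum
    chronic_codes: frozenset[str]

    @property
    def is_multimorbid(self) -> bool:
        return len(self.chronic_codes) >= 2


@dataclass
class ExclusionLog:
    """Counts of records/patients removed by each eligibility rule."""

    symptom_only_records: int = 0
    sex_conflict_patients: int = 0
    sex_conflict_records: int = 0
    out_of_range_codes: int = 0
    empty_after_code_screen: int = 0

    def records_removed(self) -> int:
        return (
            self.symptom_only_records
            + self.sex_conflict_records
            + self.empty_after_code_screen
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "symptom_only_records": self.symptom_only_records,
            "sex_conflict_patients": self.sex_conflict_patients,
            "sex_conflict_records": self.sex_conflict_records,
            "out_of_range_codes": self.out_of_range_codes,
            "empty_after_code_screen": self.empty_after_code_screen,
        }


def filter_records(
    records: Sequence[DischargeRecord],
    sex_specific: Mapping[str, str],
    symptom_prefixes: Iterable[str] = ("R",),
) -> tuple[list[DischargeRecord], ExclusionLog]:
    """Apply the eligibility filters; returns kept records and an exclusion log.

    Rules (disjoint, so their order only affects which rule a doubly
    excluded record is attributed to):

    1. admissions whose *every* code starts with a symptom prefix are dropped;
    2. codes outside A00-R99 are stripped; records left empty are dropped;
    3. any patient with a diagnosis whose mapped sex conflicts with the
       recorded sex loses *all* their records.
    """
    prefixes = tuple(symptom_prefixes)
    log = ExclusionLog()

    stage1: list[DischargeRecord] = []
    for rec in records:
        if prefixes and all(c.startswith(prefixes) for c in rec.codes):
            log.symptom_only_records += 1
            continue
        kept_codes = tuple(c for c in rec.codes if in_disease_range(c))
        log.out_of_range_codes += len(rec.codes) - len(kept_codes)
        if not kept_codes:
            log.empty_after_code_screen += 1
            continue
        stage1.append(replace(rec, codes=kept_codes))

    conflicted: set[str] = set()
    for rec in stage1:
        for c in rec.codes:
            required = sex_specific.get(c)
            if required is not None and required != rec.sex:
                conflicted.add(rec.patient_id)
                break

    kept = [r for r in stage1 if r.patient_id not in conflicted]
    log.sex_conflict_patients = len(conflicted)
    log.sex_conflict_records = len(stage1) - len(kept)
    return kept, log


def assign_stratum(records: Sequence[DischargeRecord]) -> AgeStratum:
    """Stratum of a patient: age at their first admission in the window.

    Patients can age across band boundaries inside a multi-year window;
    using the first admission pins each patient to exactly one stratum so
    unique-patient denominators add up.
    """
    if not records:
        raise ValueError("patient has no records in the window")
    first = min(records, key=lambda r: (r.year, r.age_years))
    return stratum_of(first.age_years)


def build_profiles(
    records: Sequence[DischargeRecord],
    chronic_codes: Iterable[str],
    window: tuple[int, int],
) -> list[PatientProfile]:
    """One profile per patient with >=1 admission in ``window`` (inclusive).

    ``chronic_codes`` is the chronic-condition indicator list; a profile's
    code set is the union of that patient's chronic codes over every
    admission in the window.  Patients whose admissions carry no chronic
    code are retained with an empty set (they count in denominators).
    """
    lo, hi = window
    if lo > hi:
        raise ValueError(f"empty window {window}")
    chronic = frozenset(normalize_code(c) for c in chronic_codes)

    by_patient: dict[str, list[DischargeRecord]] = defaultdict(list)
    for rec in records:
        if lo <= rec.year <= hi:
            by_patient[rec.patient_id].append(rec)

    profiles: list[PatientProfile] = []
    for pid in sorted(by_patient):
        recs = by_patient[pid]
        codes = frozenset(c for r in recs for c in r.codes if c in chronic)
        profiles.append(
            PatientProfile(
                patient_id=pid,
                sex=recs[0].sex,
                stratum=assign_stratum(recs),
                chronic_codes=codes,
            )
        )
    return profiles


def prevalence_filter(
    profiles: Sequence[PatientProfile],
    threshold: float = 0.01,
) -> tuple[dict[str, frozenset[str]], list[PatientProfile]]:
    """Retain, per sex, codes reaching ``threshold`` prevalence in >=1 stratum.

    Prevalence of a code in a sex-stratum cell is the number of unique
    patients carrying it divided by all unique patients in the cell
    (multimorbid or not).  Returns the retained code set per sex and the
    profiles with their code sets intersected with the retained set.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")

    totals: dict[tuple[str, int], int] = defaultdict(int)
    carrier: dict[tuple[str, int], dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for p in profiles:
        key = (p.sex, p.stratum.index)
        totals[key] += 1
        for c in p.chronic_codes:
            carrier[key][c] += 1

    retained: dict[str, set[str]] = {s: set() for s in SEXES}
    for (sex, _idx), counts in carrier.items():
        n_total = totals[(sex, _idx)]
        if n_total == 0:
            continue
        for code, n in counts.items():
            if n / n_total >= threshold:
                retained[sex].add(code)

    retained_frozen = {s: frozenset(v) for s, v in retained.items()}
    filtered = [
        replace(p, chronic_codes=p.chronic_codes & retained_frozen[p.sex])
        for p in profiles
    ]
    return retained_frozen, filtered


def summarize_cohort(profiles: Sequence[PatientProfile]) -> pd.DataFrame:
    """Per (sex, stratum): unique patients, multimorbid count/percent, mean codes.

    ``mean_codes_multimorbid`` is the mean chronic-code count among
    multimorbid patients; NaN where a cell has none.
    """
    rows = []
    by_cell: dict[tuple[str, int], list[PatientProfile]] = defaultdict(list)
    for p in profiles:
        by_cell[(p.sex, p.stratum.index)].append(p)

    from .strata import AGE_STRATA

    for sex in SEXES:
        for idx in range(N_STRATA):
            cell = by_cell.get((sex, idx), [])
            n_total = len(cell)
            mm = [p for p in cell if p.is_multimorbid]
            rows.append(
                {
                    "sex": sex,
                    "stratum_index": idx,
                    "stratum": AGE_STRATA[idx].label,
                    "n_total": n_total,
                    "n_multimorbid": len(mm),
                    "pct_multimorbid": (100.0 * len(mm) / n_total) if n_total else 0.0,
                    "mean_codes_multimorbid": (
                        sum(len(p.chronic_codes) for p in mm) / len(mm)
                        if mm
                        else float("nan")
                    ),
                }
            )
    return pd.DataFrame(rows)


__all__ = [
    "DischargeRecord",
    "PatientProfile",
    "ExclusionLog",
    "filter_records",
    "assign_stratum",
    "build_profiles",
    "prevalence_filter",
    "summarize_cohort",
    "normalize_code",
    "in_disease_range",
    "stratum_index",
    "SEXES",
]
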