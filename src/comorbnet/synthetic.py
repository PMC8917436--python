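"""Synthetic discharge-record generator with planted, recoverable structure.

The generator emulates the shape of a regional hospital-discharge database
— five calendar years, two sexes, 16 age strata, ICD-10-like 3-character
codes with age-increasing prevalence — while planting known structure that
every downstream stage can be scored against:

* **communities** — each patient joins each planted community
  independently with probability ``membership_rate``; codes of a joined
  community have their inclusion odds multiplied by ``1 + within_boost``.
  Codes of the same community become positively associated while codes of
  different communities stay (near) independent, so a community detector
  has a clean planted partition to recover.  Per-community membership
  (rather than a single affiliation) keeps the within-community signal
  independent of the number of planted communities.
* **hubs** — hub codes condition directly on the patient's burden of
  planted codes: their odds are multiplied by ``(1 + hub_boost)**min(K, 3)``
  where K is the number of planted community codes the patient drew.  This
  creates first-order association with *every* planted code, i.e. high
  connectivity, without an implausible marginal prevalence.
* **bursts** — a burst code conditions, like a hub, on the planted-code
  burden, but only counts codes of the communities *activated* so far:
  crossing each planted leap stratum activates one more community, so the
  code's network degree jumps by roughly one community size per leap.

All boosts are *excess* odds multipliers: a boost of 0 leaves the code
exactly independent of everything else, which makes the null generator an
analytic oracle (patient-level indicators are independent Bernoulli draws
with the configured per-stratum probabilities).

Patients age through the window: each patient has an implicit birth year,
so their age advances with the calendar year of each admission and can
cross stratum boundaries — the same ambiguity the cohort module resolves
with its first-admission rule.  Symptom-only admissions and sex-conflicting
diagnoses are injected at low rates so the eligibility filters are
exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .cohort import DischargeRecord
from .defaults import (
    DEFAULT_ACUTE_CODES,
    DEFAULT_CHRONIC_CODES,
    DEFAULT_SEX_SPECIFIC,
    SYMPTOM_CODES,
)
from .strata import N_STRATA, stratum_index

# Default share of patients per age stratum: mildly elderly-skewed, as in
# hospital data.  Sums to 1.
DEFAULT_STRATUM_WEIGHTS: tuple[float, ...] = (
    0.08, 0.05, 0.04, 0.05, 0.05, 0.05, 0.05, 0.06,
    0.06, 0.07, 0.07, 0.08, 0.08, 0.07, 0.07, 0.07,
)

# Preferred planting order: clinically coherent clusters first.
_PLANTED_POOL: tuple[str, ...] = (
    "I10", "I11", "I25", "I50", "I63", "I67", "I70", "E11",
    "E77", "E78", "J42", "J44", "I27", "N18", "D64", "K76",
    "M15", "M47", "G47", "K21", "E03", "H25", "I48", "F32",
)

_AGE_DECAY = 0.95  # per-stratum geometric decay of prevalence toward youth
_BURDEN_CAP = 3    # boost saturates after this many planted codes


class ConfigError(ValueError):
    """A simulation configuration field is invalid; the message names it."""


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int
    years: tuple[int, int] = (2015, 2019)
    disease_universe: tuple[str, ...] = ()
    acute_codes: tuple[str, ...] = DEFAULT_ACUTE_CODES  # non-chronic fillers
    communities: tuple[tuple[str, ...], ...] = ()
    within_boost: float = 0.0
    hub_codes: tuple[str, ...] = ()
    hub_boost: float = 0.0
    burst_plan: Mapping[str, tuple[int, ...]] = field(default_factory=dict)
    burst_gamma: float = 3.5
    base_prevalence_by_stratum: Mapping[str, tuple[float, ...]] = field(
        default_factory=dict
    )
    admissions_per_patient_year: float = 1.2
    recurrence_rate: float = 0.8  # chance a chronic code is re-coded per admission
    max_dx_per_admission: int = 16
    membership_rate: float = 0.1
    stratum_weights: tuple[float, ...] = DEFAULT_STRATUM_WEIGHTS
    sex_specific: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_SEX_SPECIFIC))
    symptom_rate: float = 0.01
    sex_conflict_rate: float = 0.01
    seed: int = 0

    @property
    def n_communities(self) -> int:
        return len(self.communities)

    @property
    def planted_codes(self) -> tuple[str, ...]:
        return tuple(c for comm in self.communities for c in comm)

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        if self.years[0] > self.years[1]:
            raise ConfigError("years must be an inclusive (first, last) range")
        universe = set(self.disease_universe)
        if not universe:
            raise ConfigError("disease_universe must be non-empty")
        planted = self.planted_codes
        if len(set(planted)) != len(planted):
            raise ConfigError("communities must be disjoint")
        if any(len(c) == 0 for c in self.communities):
            raise ConfigError("communities must be non-empty")
        if not set(planted) <= universe:
            raise ConfigError("communities must be a subset of disease_universe")
        if not set(self.hub_codes) <= universe:
            raise ConfigError("hub_codes must be a subset of disease_universe")
        if self.within_boost < 0:
            raise ConfigError("within_boost must be non-negative")
        if self.hub_boost < 0:
            raise ConfigError("hub_boost must be non-negative")
        for code, strata in self.burst_plan.items():
            if code not in universe:
                raise ConfigError(f"burst_plan code {code!r} not in disease_universe")
            if any(not 0 <= s < N_STRATA for s in strata):
                raise ConfigError(f"burst_plan strata for {code!r} out of range")
        for code in self.disease_universe:
            probs = self.base_prevalence_by_stratum.get(code)
            if probs is None or len(probs) != N_STRATA:
                raise ConfigError(
                    f"base_prevalence_by_stratum must give {N_STRATA} values for {code!r}"
                )
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise ConfigError(f"base_prevalence_by_stratum[{code!r}] outside [0, 1]")
        if self.admissions_per_patient_year < 0:
            raise ConfigError("admissions_per_patient_year must be non-negative")
        if not 0.0 <= self.recurrence_rate <= 1.0:
            raise ConfigError("recurrence_rate must lie in [0, 1]")
        if not 1 <= self.max_dx_per_admission <= 16:
            raise ConfigError("max_dx_per_admission must lie in [1, 16]")
        if not 0.0 <= self.membership_rate <= 1.0:
            raise ConfigError("membership_rate must lie in [0, 1]")
        if len(self.stratum_weights) != N_STRATA or any(
            w < 0 for w in self.stratum_weights
        ):
            raise ConfigError("stratum_weights must be 16 non-negative values")
        if not 0.0 <= self.symptom_rate <= 1.0:
            raise ConfigError("symptom_rate must lie in [0, 1]")
        if not 0.0 <= self.sex_conflict_rate <= 1.0:
            raise ConfigError("sex_conflict_rate must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: community membership, hubs, burst degree profiles."""

    community_of: dict[str, int]
    hubs: frozenset[str]
    burst_trajectories: dict[str, tuple[int, ...]]


def _default_prevalence(
    universe: Sequence[str], chronic: set[str]
) -> dict[str, tuple[float, ...]]:
    """Deterministic per-code, per-stratum base probabilities.

    Chronic codes get an old-age prevalence in [0.05, 0.12] decaying
    geometrically toward younger strata; acute filler codes are age-flat.
    The floor keeps marginals well away from the sparse-table regime in
    which the t-approximation of the phi test is anticonservative.
    """
    rng = np.random.default_rng(1729)
    out: dict[str, tuple[float, ...]] = {}
    for code in sorted(universe):
        if code in chronic:
            p_old = float(rng.uniform(0.05, 0.12))
            out[code] = tuple(p_old * _AGE_DECAY ** (15 - s) for s in range(N_STRATA))
        else:
            out[code] = tuple([0.03] * N_STRATA)
    return out


def default_config(
    n_patients: int,
    seed: int = 0,
    n_communities: int = 2,
    community_size: int = 8,
    within_boost: float = 0.0,
    hub_codes: Sequence[str] = (),
    hub_boost: float = 0.0,
    **overrides,
) -> SimulationConfig:
    """Study-shaped configuration over the illustrative code universe."""
    universe = tuple(sorted(set(DEFAULT_CHRONIC_CODES) | set(DEFAULT_ACUTE_CODES)))
    pool = [c for c in _PLANTED_POOL if c not in set(hub_codes)]
    pool += [
        c
        for c in sorted(DEFAULT_CHRONIC_CODES)
        if c not in set(pool) and c not in set(hub_codes)
    ]
    if n_communities * community_size > len(pool):
        raise ConfigError("not enough pool codes for the requested communities")
    communities = tuple(
        tuple(pool[j * community_size : (j + 1) * community_size])
        for j in range(n_communities)
    )
    cfg = SimulationConfig(
        n_patients=n_patients,
        disease_universe=universe,
        communities=communities,
        within_boost=within_boost,
        hub_codes=tuple(hub_codes),
        hub_boost=hub_boost,
        base_prevalence_by_stratum=_default_prevalence(
            universe, set(DEFAULT_CHRONIC_CODES)
        ),
        seed=seed,
        **overrides,
    )
    cfg.validate()
    return cfg


def synthetic_universe(
    codes_per_chapter: int = 9,
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """A paper-scale synthetic code universe: (chronic codes, acute codes).

    16 chapter letters x ``codes_per_chapter`` chronic codes (144 by
    default, close to the ~150-disease universes typical of large
    discharge databases) plus the default acute fillers.
    """
    chronic = tuple(
        f"{ch}{i:02d}"
        for ch in "ABCDEFGHIJKLMNPQ"
        for i in range(20, 20 + codes_per_chapter)
    )
    return chronic, DEFAULT_ACUTE_CODES


def paper_scale_config(
    n_patients: int,
    seed: int = 0,
    n_communities: int = 18,
    community_size: int = 8,
    within_boost: float = 16.0,
    **overrides,
) -> SimulationConfig:
    """Config over a ~150-code universe with communities covering it.

    Used for temporal-stability studies where both the disease universe
    and the community count should be at the scale of a real discharge
    database; community prevalence is drawn deterministically in
    [0.03, 0.07] at old age.
    """
    chronic, acute = synthetic_universe()
    universe = tuple(sorted(set(chronic) | set(acute)))
    if n_communities * community_size > len(chronic):
        raise ConfigError("not enough chronic codes for the requested communities")
    rng = np.random.default_rng(1729)
    prev: dict[str, tuple[float, ...]] = {}
    for code in sorted(universe):
        if code in set(chronic):
            p_old = float(rng.uniform(0.03, 0.07))
            prev[code] = tuple(p_old * _AGE_DECAY ** (15 - s) for s in range(N_STRATA))
        else:
            prev[code] = tuple([0.03] * N_STRATA)
    pool = sorted(chronic)
    communities = tuple(
        tuple(pool[j * community_size : (j + 1) * community_size])
        for j in range(n_communities)
    )
    cfg = SimulationConfig(
        n_patients=n_patients,
        disease_universe=universe,
        communities=communities,
        within_boost=within_boost,
        base_prevalence_by_stratum=prev,
        sex_specific={},
        seed=seed,
        **overrides,
    )
    cfg.validate()
    return cfg


def plant_burst(
    config: SimulationConfig, code: str, leap_strata: Sequence[int]
) -> SimulationConfig:
    """Return a config in which ``code`` gains degree leaps at ``leap_strata``.

    Each leap stratum activates one more planted community as the code's
    co-occurrence partners, so from that stratum onward its expected
    network degree rises by about one community size (>= 6 with the
    default community size of 8).  Requires at least as many planted
    communities as leaps.
    """
    if code not in config.disease_universe:
        raise ConfigError(f"burst code {code!r} not in disease_universe")
    strata = tuple(sorted(int(s) for s in leap_strata))
    if not strata:
        return config
    if any(not 0 <= s < N_STRATA for s in strata):
        raise ConfigError(f"leap strata {strata} out of range 0-{N_STRATA - 1}")
    if len(strata) > config.n_communities:
        raise ConfigError(
            "need at least one planted community per leap "
            f"({len(strata)} leaps, {config.n_communities} communities)"
        )
    plan = dict(config.burst_plan)
    plan[code] = strata
    return replace(config, burst_plan=plan)


def intended_burst_profile(config: SimulationConfig, code: str) -> tuple[int, ...]:
    """Intended degree profile: active-partner count per stratum."""
    strata = config.burst_plan.get(code, ())
    sizes = [len(c) for c in config.communities]
    profile = []
    for s in range(N_STRATA):
        k_active = sum(1 for ls in strata if s >= ls)
        profile.append(sum(sizes[:k_active]))
    return tuple(profile)


def _rebalance(admissions: list[list[str]], cap: int, years: list[int]) -> None:
    """Move overflow codes to admissions with room, adding admissions if needed."""
    i = 0
    while i < len(admissions):
        adm = admissions[i]
        while len(adm) > cap:
            extra = adm.pop()
            target = min(
                (j for j in range(len(admissions)) if j != i),
                key=lambda j: len(admissions[j]),
                default=None,
            )
            if target is not None and len(admissions[target]) < cap:
                admissions[target].append(extra)
            else:
                admissions.append([extra])
                years.append(years[i])
        i += 1


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[DischargeRecord], GroundTruth]:
    """Generate the discharge records and the planted ground truth.

    Identical config (including seed) reproduces identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    y0, y1 = config.years
    n_years = y1 - y0 + 1
    n = config.n_patients

    codes = list(config.disease_universe)
    c_idx = {c: j for j, c in enumerate(codes)}
    n_codes = len(codes)
    base = np.array(
        [config.base_prevalence_by_stratum[c] for c in codes], dtype=float
    ).T  # (16, n_codes)

    planted = config.planted_codes
    planted_idx = np.array([c_idx[c] for c in planted], dtype=np.int64)
    comm_cols = [np.array([c_idx[c] for c in comm]) for comm in config.communities]
    hub_idx = np.array([c_idx[c] for c in config.hub_codes], dtype=np.int64)
    burst_items = sorted(config.burst_plan.items())

    # --- patient-level latent state -------------------------------------
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    stratum0 = rng.choice(
        N_STRATA, size=n, p=np.asarray(config.stratum_weights) / sum(config.stratum_weights)
    )
    band_low = np.array([0, 7, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60, 65, 70, 75, 80])
    band_span = np.array([7, 8, 5, 5, 5, 5, 5, 5, 5, 5, 5, 5, 5, 5, 5, 15])
    age0 = band_low[stratum0] + rng.integers(0, band_span[stratum0])

    m_adm = np.maximum(
        1, rng.poisson(config.admissions_per_patient_year * n_years, size=n)
    )
    if config.n_communities > 0:
        membership = rng.random((n, config.n_communities)) < config.membership_rate
    else:
        membership = np.zeros((n, 0), dtype=bool)

    # admission years per patient (sorted); first-admission age sets the
    # stratum used for that patient's configured prevalences — exactly the
    # stratum the cohort module will later assign.
    adm_years = [np.sort(rng.integers(y0, y1 + 1, size=int(m))) for m in m_adm]
    s_assigned = np.array(
        [stratum_index(int(age0[i]) + int(adm_years[i][0]) - y0) for i in range(n)]
    )

    # --- stage 1: ordinary codes (community mechanism) -------------------
    p = base[s_assigned, :].copy()  # (n, n_codes)
    for code, required_sex in sorted(config.sex_specific.items()):
        j = c_idx.get(code)
        if j is not None:
            p[sex != required_sex, j] = 0.0
    odds = np.divide(p, 1.0 - p, out=np.full_like(p, np.inf), where=p < 1.0)
    if config.within_boost > 0:
        for j, cols in enumerate(comm_cols):
            members = np.nonzero(membership[:, j])[0]
            if members.size:
                odds[np.ix_(members, cols)] *= 1.0 + config.within_boost
    special = set(hub_idx.tolist()) | {c_idx[c] for c, _ in burst_items}
    p_eff = np.where(np.isinf(odds), 1.0, odds / (1.0 + odds))
    draws = rng.random((n, n_codes)) < p_eff
    # special codes are drawn in stage 2, conditional on the stage-1 burden
    for j in special:
        draws[:, j] = False

    # --- stage 2: hubs and bursts (burden-conditioned) -------------------
    if planted_idx.size:
        burden = np.minimum(draws[:, planted_idx].sum(axis=1), _BURDEN_CAP)
    else:
        burden = np.zeros(n, dtype=np.int64)
    for j in sorted(special):
        code = codes[j]
        o = odds[:, j].copy()
        if j in hub_idx and config.hub_boost > 0:
            o = o * (1.0 + config.hub_boost) ** burden
        if code in config.burst_plan:
            leaps = config.burst_plan[code]
            k_active = np.array(
                [sum(1 for ls in leaps if s >= ls) for s in range(N_STRATA)]
            )[s_assigned]
            if comm_cols:
                active_burden = np.zeros(n, dtype=np.int64)
                for ci, cols in enumerate(comm_cols):
                    active_burden += np.where(
                        k_active > ci, draws[:, cols].sum(axis=1), 0
                    )
                active_burden = np.minimum(active_burden, _BURDEN_CAP)
                o = o * config.burst_gamma ** np.where(k_active > 0, active_burden, 0)
        pj = np.where(np.isinf(o), 1.0, o / (1.0 + o))
        draws[:, j] = rng.random(n) < pj

    # --- assemble admissions ---------------------------------------------
    acute = [c for c in codes if c in set(config.acute_codes)]
    conflict_pool = {
        s: sorted(c for c, cs in config.sex_specific.items() if cs != s)
        for s in ("M", "F")
    }
    records: list[DischargeRecord] = []
    truth_hubs = frozenset(config.hub_codes) if config.hub_boost > 0 else frozenset()
    code_arr = np.array(codes)

    for i in range(n):
        years = adm_years[i].tolist()
        m = len(years)
        admissions: list[list[str]] = [[] for _ in range(m)]
        my_codes = code_arr[draws[i]].tolist()
        if my_codes:
            # each code has a home admission and recurs elsewhere: chronic
            # conditions are re-coded at most hospitalizations
            slots = rng.integers(0, m, size=len(my_codes))
            recur = rng.random((len(my_codes), m)) < config.recurrence_rate
            for ci, (c, home) in enumerate(zip(my_codes, slots.tolist())):
                for a in range(m):
                    if a == home or recur[ci, a]:
                        admissions[a].append(c)
            for a in range(m):
                if not admissions[a]:  # repeat a known diagnosis; union unchanged
                    admissions[a].append(
                        my_codes[int(rng.integers(0, len(my_codes)))]
                    )
        else:
            filler = acute[int(rng.integers(0, len(acute)))] if acute else codes[0]
            for a in range(m):
                admissions[a].append(filler)
        _rebalance(admissions, config.max_dx_per_admission, years)

        if config.sex_conflict_rate > 0 and rng.random() < config.sex_conflict_rate:
            pool = conflict_pool[str(sex[i])]
            if pool:
                code = pool[int(rng.integers(0, len(pool)))]
                a = int(rng.integers(0, len(admissions)))
                if len(admissions[a]) < config.max_dx_per_admission:
                    admissions[a].append(code)
                else:
                    admissions.append([code])
                    years.append(years[a])
        if config.symptom_rate > 0 and rng.random() < config.symptom_rate:
            admissions.append(
                [SYMPTOM_CODES[int(rng.integers(0, len(SYMPTOM_CODES)))]]
            )
            years.append(int(years[int(rng.integers(0, m))]))

        pid = f"P{i:07d}"
        for a, (yr, adm) in enumerate(zip(years, admissions)):
            records.append(
                DischargeRecord(
                    patient_id=pid,
                    sex=str(sex[i]),
                    age_years=int(age0[i]) + int(yr) - y0,
                    year=int(yr),
                    codes=tuple(adm),
                )
            )

    truth = GroundTruth(
        community_of={
            c: j for j, comm in enumerate(config.communities) for c in comm
        },
        hubs=truth_hubs,
        burst_trajectories={
            code: intended_burst_profile(config, code) for code in config.burst_plan
        },
    )
    return records, truth


def shuffle_codes_by_year(
    records: Sequence[DischargeRecord],
    seed: int = 0,
    keep: Sequence[str] = tuple(DEFAULT_SEX_SPECIFIC),
) -> list[DischargeRecord]:
    """Negative control: relabel diagnosis codes independently per year.

    Each calendar year's records get their codes mapped through an
    independent random permutation of the code universe, preserving every
    within-year co-occurrence structure while destroying any
    correspondence of disease identities — and hence communities — across
    years.  Codes in ``keep`` (by default the sex-specific ones) are left
    fixed so no artificial sex conflicts are created.
    """
    rng = np.random.default_rng(seed)
    universe = sorted({c for r in records for c in r.codes} - set(keep))
    years = sorted({r.year for r in records})
    mapping: dict[int, dict[str, str]] = {}
    for year in years:
        perm = rng.permutation(len(universe))
        mapping[year] = {universe[i]: universe[int(j)] for i, j in enumerate(perm)}
    out = []
    for r in records:
        m = mapping[r.year]
        out.append(replace(r, codes=tuple(m.get(c, c) for c in r.codes)))
    return out


__all__ = [
    "ConfigError",
    "SimulationConfig",
    "GroundTruth",
    "default_config",
    "plant_burst",
    "intended_burst_profile",
    "generate_cohort",
    "DEFAULT_STRATUM_WEIGHTS",
]
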