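"""Shared fixtures: tiny cohorts, random strata, and one session-scoped
study-sized null cohort reused by the expensive statistical checks."""

from __future__ import annotations

import numpy as np
import pytest

from comorbnet.cohort import PatientProfile
from comorbnet.strata import AGE_STRATA


def make_profiles(code_sets, sex="M", stratum=10):
    """Build one-stratum profiles from an iterable of code collections."""
    return [
        PatientProfile(
            patient_id=f"P{i:04d}",
            sex=sex,
            stratum=AGE_STRATA[stratum],
            chronic_codes=frozenset(codes),
        )
        for i, codes in enumerate(code_sets)
    ]


def random_stratum(rng: np.random.Generator, max_patients=200, max_codes=15):
    """A random one-stratum cohort and its code list."""
    n = int(rng.integers(10, max_patients + 1))
    k = int(rng.integers(3, max_codes + 1))
    codes = [f"{chr(65 + j // 10)}{j % 10}{j % 10}" for j in range(k)]
    p = rng.uniform(0.05, 0.5, size=k)
    draws = rng.random((n, k)) < p
    sets = [[codes[j] for j in range(k) if draws[i, j]] for i in range(n)]
    return make_profiles(sets), codes


@pytest.fixture(scope="session")
def null_cohorts():
    """Ten independent null cohorts (no planted structure), study-sized.

    Shared between the independence-screen and burst-false-flag checks so
    generation and analysis run once.
    """
    import comorbnet as cn
    from comorbnet.analysis import analyze_window
    from comorbnet.defaults import DEFAULT_CHRONIC_CODES, DEFAULT_SEX_SPECIFIC

    out = []
    for seed in range(10):
        cfg = cn.default_config(n_patients=20000, seed=seed, n_communities=0)
        records, _ = cn.generate_cohort(cfg)
        wa = analyze_window(
            records,
            (2015, 2019),
            chronic_codes=DEFAULT_CHRONIC_CODES,
            sex_specific=DEFAULT_SEX_SPECIFIC,
        )
        out.append((cfg, records, wa))
    return out
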