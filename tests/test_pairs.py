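"""Pair statistics against brute-force oracles and closed-form identities."""

import math

import numpy as np
import pytest
from scipy import stats

from comorbnet.pairs import (
    CutoffResult,
    PairCounts,
    PairStats,
    compute_pair_stats,
    count_pairs,
    exclude_negative_pairs,
    find_sci_cutoff,
    phi_correlation,
    phi_significance,
    relative_risk,
    salton_cosine,
)

from conftest import make_profiles, random_stratum


def brute_force_stats(profiles, codes):
    """Independent oracle: explicit indicator vectors, per-pair loops."""
    x = {c: np.array([c in p.chronic_codes for p in profiles], dtype=float) for c in codes}
    n = len(profiles)
    out = {}
    for i, a in enumerate(codes):
        for b in codes[i + 1 :]:
            na, nb = int(x[a].sum()), int(x[b].sum())
            nab = int((x[a] * x[b]).sum())
            rr = nab * n / (na * nb) if na and nb else float("nan")
            sci = nab / math.sqrt(na * nb) if na and nb else float("nan")
            if 0 < na < n and 0 < nb < n:
                phi = float(np.corrcoef(x[a], x[b])[0, 1])
            else:
                phi = float("nan")
            out[(a, b)] = (na, nb, nab, rr, phi, sci)
    return out


def test_counts_and_statistics_match_indicator_oracle():
    """RR/phi/SCI/counts agree with the exhaustive oracle to 1e-12."""
    rng = np.random.default_rng(42)
    for _ in range(50):
        profiles, codes = random_stratum(rng)
        oracle = brute_force_stats(profiles, codes)
        sc = count_pairs(profiles, codes)
        stats_ = compute_pair_stats(sc.pairs)
        assert sc.n_total == len(profiles)
        for ps in stats_:
            c = ps.counts
            na, nb, nab, rr, phi, sci = oracle[(c.code_a, c.code_b)]
            assert (c.n_a, c.n_b, c.n_ab) == (na, nb, nab)
            assert ps.rr == pytest.approx(rr, abs=1e-12)
            assert ps.sci == pytest.approx(sci, abs=1e-12)
            if not math.isnan(phi):
                assert ps.phi == pytest.approx(phi, abs=1e-12)
        # pairs with nab = 0 are omitted; marginals still reported
        for (a, b), (na, nb, nab, *_rest) in oracle.items():
            if nab == 0:
                assert all(
                    not (p.code_a == a and p.code_b == b) for p in sc.pairs
                )
        for c in codes:
            expected = sum(1 for p in profiles if c in p.chronic_codes)
            assert sc.marginals[c] == expected


def test_three_patient_worked_example():
    """{A00,B00}, {A00}, {B00}: marginals 2/2, one co-occurrence of 1."""
    profiles = make_profiles([["A00", "B00"], ["A00"], ["B00"]])
    sc = count_pairs(profiles, ["A00", "B00"])
    assert sc.marginals == {"A00": 2, "B00": 2}
    (pair,) = sc.pairs
    assert (pair.n_a, pair.n_b, pair.n_ab, pair.n_total) == (2, 2, 1, 3)


@pytest.mark.parametrize(
    "counts, rr, phi, sci",
    [
        # worked example: RR = 10*1000/(100*50) = 2, SCI = 10/sqrt(5000)
        (PairCounts("A00", "B00", 100, 50, 10, 1000), 2.0, 0.07648, 0.141421),
        # exact independence: n_ab = n_a n_b / N
        (PairCounts("A00", "B00", 100, 50, 5, 1000), 1.0, 0.0, 0.070711),
        # perfect overlap
        (PairCounts("A00", "B00", 7, 7, 7, 100), 100 / 7, 1.0, 1.0),
    ],
)
def test_closed_form_values(counts, rr, phi, sci):
    assert relative_risk(counts) == pytest.approx(rr, rel=1e-6)
    assert phi_correlation(counts) == pytest.approx(phi, abs=5e-5)
    assert salton_cosine(counts) == pytest.approx(sci, abs=1e-6)


def test_zero_and_degenerate_cases():
    zero = PairCounts("A00", "B00", 100, 50, 0, 1000)
    assert relative_risk(zero) == 0.0
    assert salton_cosine(zero) == 0.0
    degenerate = PairCounts("A00", "B00", 0, 5, 0, 100)
    assert math.isnan(relative_risk(degenerate))
    assert math.isnan(salton_cosine(degenerate))
    assert math.isnan(phi_correlation(degenerate))
    full = PairCounts("A00", "B00", 100, 5, 5, 100)
    assert math.isnan(phi_correlation(full))


def test_phi_equals_pearson_of_indicators():
    """phi from the 2x2 table equals np.corrcoef of indicator vectors."""
    rng = np.random.default_rng(7)
    for _ in range(1000):
        n = int(rng.integers(4, 60))
        xa = rng.random(n) < rng.uniform(0.2, 0.8)
        xb = rng.random(n) < rng.uniform(0.2, 0.8)
        na, nb = int(xa.sum()), int(xb.sum())
        if na in (0, n) or nb in (0, n):
            continue
        nab = int((xa & xb).sum())
        c = PairCounts("A00", "B00", na, nb, nab, n)
        assert phi_correlation(c) == pytest.approx(
            float(np.corrcoef(xa, xb)[0, 1]), abs=1e-12
        )


def test_phi_significance_against_t_quantiles():
    assert not phi_significance(0.0, 1000)
    # t = 0.0765*sqrt(998)/sqrt(1-0.0765^2) ~ 2.42 < 2.581
    assert not phi_significance(0.0765, 1000, alpha=0.01)
    assert phi_significance(0.5, 1000, alpha=0.01)
    assert phi_significance(1.0, 10)
    with pytest.raises(ValueError):
        phi_significance(0.5, 2)
    # alpha = 1 makes any nonzero phi significant (limiting case)
    assert phi_significance(1e-6, 100, alpha=1.0)


def test_significance_agrees_with_pearsonr_pvalue():
    """The t-screen equals thresholding scipy's pearsonr p-value."""
    rng = np.random.default_rng(3)
    for _ in range(200):
        n = int(rng.integers(10, 200))
        xa = (rng.random(n) < 0.4).astype(float)
        xb = (rng.random(n) < 0.4).astype(float)
        if xa.std() == 0 or xb.std() == 0:
            continue
        r, p = stats.pearsonr(xa, xb)
        c = PairCounts(
            "A00", "B00", int(xa.sum()), int(xb.sum()), int((xa * xb).sum()), n
        )
        assert phi_significance(phi_correlation(c), n, 0.01) == (p < 0.01)


def test_sci_bounds_symmetry_and_sample_size_invariance():
    rng = np.random.default_rng(11)
    for _ in range(200):
        na, nb = int(rng.integers(1, 50)), int(rng.integers(1, 50))
        nab = int(rng.integers(0, min(na, nb) + 1))
        for n_total in (na + nb, 10_000):
            c = PairCounts("A00", "B00", na, nb, nab, max(n_total, na + nb - nab))
            s = salton_cosine(c)
            assert 0.0 <= s <= 1.0
            flipped = PairCounts("A00", "B00", nb, na, nab, c.n_total)
            assert salton_cosine(flipped) == pytest.approx(s)
        small = PairCounts("A00", "B00", na, nb, nab, na + nb)
        big = PairCounts("A00", "B00", na, nb, nab, 10_000)
        assert salton_cosine(small) == salton_cosine(big)


# ---------------------------------------------------------------------------
# SCI cutoff (Steps 1-4)


def brute_force_cutoff(pairs, alpha=0.01):
    """Independent enumeration of the 4-step cutoff procedure."""
    sig = [p for p in pairs if p.phi_significant]
    if not sig:
        return None
    s = len(sig)
    # largest threshold t with #{n_ab >= t} >= s, by scanning all t
    best_t = None
    for t in range(0, max(p.counts.n_ab for p in pairs) + 1):
        if sum(1 for p in pairs if p.counts.n_ab >= t) >= s:
            best_t = t
    q = sum(1 for p in pairs if p.counts.n_ab >= best_t)
    cutoff = sorted((p.sci for p in pairs), reverse=True)[q - 1]
    kept = {(p.counts.code_a, p.counts.code_b) for p in pairs if p.sci >= cutoff}
    return best_t, q, cutoff, kept


def _mk_pair(a, b, na, nb, nab, n, significant):
    c = PairCounts(a, b, na, nb, nab, n)
    return PairStats(
        counts=c,
        rr=relative_risk(c),
        phi=phi_correlation(c),
        phi_significant=significant,
        sci=salton_cosine(c),
    )


def test_cutoff_matches_brute_force_on_random_tables():
    rng = np.random.default_rng(5)
    for _ in range(100):
        n = 500
        pairs = []
        m = int(rng.integers(3, 15))
        for i in range(m):
            na, nb = int(rng.integers(5, 60)), int(rng.integers(5, 60))
            nab = int(rng.integers(1, min(na, nb) + 1))
            pairs.append(
                _mk_pair(f"A{i:02d}", f"B{i:02d}", na, nb, nab, n, bool(rng.random() < 0.5))
            )
        oracle = brute_force_cutoff(pairs)
        res = find_sci_cutoff(pairs)
        if oracle is None:
            assert res.sci_cutoff is None and res.kept_pairs == 0
            continue
        t, q, cutoff, kept = oracle
        assert res.n_ab_minimum == t
        assert res.q == q
        assert res.sci_cutoff == pytest.approx(cutoff)
        assert {(p.counts.code_a, p.counts.code_b) for p in res.kept} == kept


def test_cutoff_singleton_and_tie_cases():
    single = [_mk_pair("A00", "B00", 20, 20, 10, 500, True)]
    res = find_sci_cutoff(single)
    assert res.q == 1 and res.kept_pairs == 1
    assert res.sci_cutoff == pytest.approx(single[0].sci)

    # two pairs tied at the cutoff SCI are both kept
    tied = [
        _mk_pair("A00", "B00", 20, 20, 10, 500, True),
        _mk_pair("C00", "D00", 20, 20, 10, 500, False),
        _mk_pair("E00", "F00", 40, 40, 4, 500, False),
    ]
    res = find_sci_cutoff(tied)
    t, q, cutoff, kept = brute_force_cutoff(tied)
    assert (res.n_ab_minimum, res.q) == (t, q)
    assert {(p.counts.code_a, p.counts.code_b) for p in res.kept} == kept


def test_cutoff_no_significant_pairs_signals_empty_network():
    pairs = [_mk_pair("A00", "B00", 20, 20, 5, 500, False)]
    res = find_sci_cutoff(pairs)
    assert res.sci_cutoff is None and res.kept == () and res.n_ab_minimum is None


def test_removing_subthreshold_nonsignificant_pair_keeps_threshold():
    rng = np.random.default_rng(9)
    pairs = []
    for i in range(10):
        na, nb = int(rng.integers(10, 40)), int(rng.integers(10, 40))
        nab = int(rng.integers(2, min(na, nb) + 1))
        pairs.append(_mk_pair(f"A{i:02d}", f"B{i:02d}", na, nb, nab, 500, i < 4))
    res = find_sci_cutoff(pairs)
    removable = [
        p
        for p in pairs
        if not p.phi_significant and p.counts.n_ab < res.n_ab_minimum
    ]
    if removable:
        reduced = [p for p in pairs if p is not removable[0]]
        assert find_sci_cutoff(reduced).n_ab_minimum == res.n_ab_minimum


from hypothesis import given, settings
from hypothesis import strategies as st


@st.composite
def pair_counts_strategy(draw):
    n = draw(st.integers(min_value=4, max_value=500))
    na = draw(st.integers(min_value=1, max_value=n - 1))
    nb = draw(st.integers(min_value=1, max_value=n - 1))
    lo = max(0, na + nb - n)
    nab = draw(st.integers(min_value=lo, max_value=min(na, nb)))
    return PairCounts("A00", "B00", na, nb, nab, n)


@given(pair_counts_strategy())
@settings(max_examples=300, derandomize=True)
def test_property_sci_in_unit_interval_and_rr_sign(c):
    s = salton_cosine(c)
    assert 0.0 <= s <= 1.0
    assert (s == 0.0) == (c.n_ab == 0)
    assert relative_risk(c) >= 0.0


@given(pair_counts_strategy())
@settings(max_examples=300, derandomize=True)
def test_property_phi_bounded_with_independence_identity(c):
    phi = phi_correlation(c)
    if not np.isnan(phi):
        assert -1.0 - 1e-12 <= phi <= 1.0 + 1e-12
    # exact independence iff phi exactly zero
    if c.n_ab * c.n_total == c.n_a * c.n_b and not np.isnan(phi):
        assert phi == pytest.approx(0.0, abs=1e-12)


def test_exclude_negative_pairs():
    keep = _mk_pair("A00", "B00", 50, 50, 10, 500, True)   # RR = 2
    drop_rr = _mk_pair("C00", "D00", 100, 100, 10, 500, False)  # RR = 0.5
    kept = exclude_negative_pairs([keep, drop_rr])
    assert kept == [keep]
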