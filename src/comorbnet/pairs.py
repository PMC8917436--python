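"""Pairwise co-occurrence statistics and the significance-matched SCI cutoff.

For a disease pair (a, b) in one sex-age group of N_total unique patients,
with n_a, n_b patients carrying each disease and n_ab carrying both:

* relative risk        RR  = n_ab * N_total / (n_a * n_b)
* phi coefficient      phi = (n_ab*N - n_a*n_b) / sqrt(n_a*n_b*(N-n_a)*(N-n_b)),
  i.e. the Pearson correlation of the two patient-level indicator vectors;
* Salton cosine index  SCI = n_ab / sqrt(n_a * n_b)

phi is screened with the usual t-test for a correlation coefficient at
alpha = .01.  SCI, being insensitive to N_total, is the edge weight; its
cutoff is calibrated so that the SCI network has (up to ties) the same
number of edges as the phi-significant network:

  Step 1  mark pairs phi-significant at alpha; S = their number;
  Step 2  n_ab_minimum = the largest co-occurrence threshold t such that
          at least S pairs have n_ab >= t (when significance is monotone
          in n_ab this is exactly the minimum n_ab among significant pairs);
  Step 3  q = number of pairs with n_ab >= n_ab_minimum (q >= S, exceeding
          it only by n_ab tie multiplicity);
  Step 4  sci_cutoff = the q-th largest SCI; keep sci >= cutoff (ties kept).

The calibration makes the SCI network carry, up to ties, the same number
of edges as the phi-significant network.

Mutually exclusive pairs (RR < 1 or phi < 0) are excluded before the
cutoff is calibrated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats


@lru_cache(maxsize=4096)
def _t_critical(alpha: float, df: int) -> float:
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))

from .cohort import PatientProfile


@dataclass(frozen=True)
class PairCounts:
    """Unique-patient counts for one unordered disease pair in one group."""

    code_a: str
    code_b: str
    n_a: int
    n_b: int
    n_ab: int
    n_total: int

    def __post_init__(self) -> None:
        if self.code_a >= self.code_b:
            raise ValueError("codes must satisfy code_a < code_b")
        if not 0 <= self.n_ab <= min(self.n_a, self.n_b):
            raise ValueError("n_ab must lie in [0, min(n_a, n_b)]")
        if self.n_a + self.n_b - self.n_ab > self.n_total:
            raise ValueError("counts exceed the group size")


@dataclass(frozen=True)
class PairStats:
    """Derived statistics for one pair."""

    counts: PairCounts
    rr: float
    phi: float
    phi_significant: bool
    sci: float


@dataclass(frozen=True)
class StratumPairCounts:
    """All pair counts of one sex-age group plus the code marginals."""

    n_total: int
    marginals: dict[str, int]
    pairs: tuple[PairCounts, ...]


@dataclass(frozen=True)
class CutoffResult:
    """Outcome of the 4-step SCI cutoff calibration for one group."""

    alpha: float
    p_max_edges: int          # n(n-1)/2 over nodes in significant pairs
    n_ab_minimum: int | None  # None when no pair is significant
    q: int
    sci_cutoff: float | None
    kept: tuple[PairStats, ...]

    @property
    def kept_pairs(self) -> int:
        return len(self.kept)


def count_pairs(
    profiles: Sequence[PatientProfile],
    retained_codes: Sequence[str],
) -> StratumPairCounts:
    """Unique-patient marginal and pairwise co-occurrence counts.

    ``profiles`` must all belong to one sex-age group; codes outside
    ``retained_codes`` are ignored.  Pairs with zero co-occurrence are
    omitted from ``pairs`` (their counts are recoverable from marginals).
    """
    codes = sorted(set(retained_codes))
    idx = {c: j for j, c in enumerate(codes)}
    n, m = len(profiles), len(codes)
    x = np.zeros((n, m), dtype=np.int64)
    for i, p in enumerate(profiles):
        for c in p.chronic_codes:
            j = idx.get(c)
            if j is not None:
                x[i, j] = 1

    marg = x.sum(axis=0)
    co = x.T @ x
    pairs = []
    a_idx, b_idx = np.nonzero(np.triu(co, k=1))
    for a, b in zip(a_idx.tolist(), b_idx.tolist()):
        pairs.append(
            PairCounts(
                code_a=codes[a],
                code_b=codes[b],
                n_a=int(marg[a]),
                n_b=int(marg[b]),
                n_ab=int(co[a, b]),
                n_total=n,
            )
        )
    return StratumPairCounts(
        n_total=n,
        marginals={c: int(marg[j]) for c, j in idx.items()},
        pairs=tuple(pairs),
    )


def relative_risk(c: PairCounts) -> float:
    """RR = n_ab * N_total / (n_a * n_b); NaN when a marginal is zero."""
    if c.n_a == 0 or c.n_b == 0:
        return float("nan")
    return c.n_ab * c.n_total / (c.n_a * c.n_b)


def phi_correlation(c: PairCounts) -> float:
    """Pearson correlation of the two indicator vectors (2x2-table phi).

    NaN when either marginal is degenerate (0 or N_total).
    """
    n, na, nb, nab = c.n_total, c.n_a, c.n_b, c.n_ab
    if na in (0, n) or nb in (0, n):
        return float("nan")
    return (nab * n - na * nb) / math.sqrt(na * nb * (n - na) * (n - nb))


def phi_significance(phi: float, n_total: int, alpha: float = 0.01) -> bool:
    """Two-sided t-test for a correlation coefficient.

    t = phi * sqrt(N-2) / sqrt(1 - phi^2) is compared with the two-sided
    critical value of Student's t on N-2 degrees of freedom.
    """
    if n_total < 3:
        raise ValueError("phi significance needs N_total >= 3")
    if math.isnan(phi) or abs(phi) > 1:
        return False
    if abs(phi) == 1.0:
        return True
    t = phi * math.sqrt(n_total - 2) / math.sqrt(1.0 - phi * phi)
    return abs(t) > _t_critical(alpha, n_total - 2)


def salton_cosine(c: PairCounts) -> float:
    """SCI = n_ab / sqrt(n_a * n_b); NaN when a marginal is zero."""
    if c.n_a == 0 or c.n_b == 0:
        return float("nan")
    return c.n_ab / math.sqrt(c.n_a * c.n_b)


def compute_pair_stats(
    counts: Sequence[PairCounts], alpha: float = 0.01
) -> list[PairStats]:
    """Attach RR, phi, the phi significance flag and SCI to each pair."""
    out = []
    for c in counts:
        phi = phi_correlation(c)
        out.append(
            PairStats(
                counts=c,
                rr=relative_risk(c),
                phi=phi,
                phi_significant=(
                    c.n_total >= 3 and phi_significance(phi, c.n_total, alpha)
                ),
                sci=salton_cosine(c),
            )
        )
    return out


def exclude_negative_pairs(pairs: Sequence[PairStats]) -> list[PairStats]:
    """Drop mutually exclusive pairs: RR < 1 or phi < 0 (NaN also dropped)."""
    return [
        p
        for p in pairs
        if not math.isnan(p.rr)
        and not math.isnan(p.phi)
        and p.rr >= 1.0
        and p.phi >= 0.0
    ]


def find_sci_cutoff(pairs: Sequence[PairStats], alpha: float = 0.01) -> CutoffResult:
    """Run cutoff Steps 1-4 on pairs already screened of negative associations.

    With no phi-significant pair the group yields an empty network
    (``sci_cutoff`` is None and ``kept`` is empty).
    """
    significant = [p for p in pairs if p.phi_significant]
    nodes = {c for p in significant for c in (p.counts.code_a, p.counts.code_b)}
    n_nodes = len(nodes)
    p_max = n_nodes * (n_nodes - 1) // 2

    if not significant:
        return CutoffResult(alpha, p_max, None, 0, None, ())

    s = len(significant)
    n_ab_values = sorted((p.counts.n_ab for p in pairs), reverse=True)
    # largest threshold t with at least s pairs at n_ab >= t: the s-th
    # largest n_ab (significant pairs all have n_ab >= 1, so s <= len(pairs))
    n_ab_min = n_ab_values[s - 1]
    q = sum(1 for p in pairs if p.counts.n_ab >= n_ab_min)
    sci_sorted = sorted((p.sci for p in pairs), reverse=True)
    cutoff = sci_sorted[q - 1]
    kept = tuple(
        sorted(
            (p for p in pairs if p.sci >= cutoff),
            key=lambda p: (p.counts.code_a, p.counts.code_b),
        )
    )
    return CutoffResult(alpha, p_max, n_ab_min, q, cutoff, kept)


__all__ = [
    "PairCounts",
    "PairStats",
    "StratumPairCounts",
    "CutoffResult",
    "count_pairs",
    "relative_risk",
    "phi_correlation",
    "phi_significance",
    "salton_cosine",
    "compute_pair_stats",
    "exclude_negative_pairs",
    "find_sci_cutoff",
]
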