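# Methods

This note documents the statistical model behind `comorbnet`, the design
of its synthetic-data generator, and the numerical conventions chosen
where several were defensible. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## 1. Cohort construction

A *discharge record* is one hospitalization with up to 16 ICD-10
3-character diagnosis codes. Analysis proceeds per calendar window
(default 2015–2019 for the main analysis; single years for temporal
trends):

1. **Symptom-only admissions** — records whose every code starts with a
   symptom prefix (default: the whole R chapter, R00–R99) are dropped.
   The prefix set is configurable because operational definitions of
   "general symptoms" vary between coding guidelines.
2. **Disease range** — codes outside A00–R99 are stripped from records
   (external-cause, injury and Z codes are not diseases in this analysis).
3. **Sex conflicts** — a patient carrying any diagnosis restricted to the
   opposite sex (e.g. prostatic hyperplasia coded on a female patient)
   loses *all* records. Removal is patient-level because a conflicting
   code makes the patient's identity linkage suspect, not just one row.
4. **Profiles** — each patient's chronic codes are accumulated over every
   admission in the window (chronic conditions do not resolve within one
   hospitalization, so the window, not the admission, is the unit).
   Chronicity is decided by an input code list; the packaged default is a
   small illustrative list of ~60 codes across chapters, *not* the
   licensed Chronic Condition Indicator, which users should supply.
   A patient is *multimorbid* when the profile holds ≥ 2 distinct chronic
   codes. Patients with zero chronic codes keep an (empty) profile so
   denominators count all inpatients.
5. **Age stratum** — 16 bands (<7, 7-14, five-year bands to 75-79, 80+).
   A patient ageing across a band boundary within the window is assigned
   by age at their **first** admission in the window. This is a
   convention of this package: it gives exactly one stratum per patient,
   so unique-patient denominators add up across strata. The alternative
   (age at each admission) double-counts patients.
6. **Prevalence screen** — a code is retained, per sex, when its
   unique-patient prevalence reaches ≥ 1% (inclusive) in at least one
   stratum; the denominator is all inpatients of the sex-stratum cell,
   not only the multimorbid ones. Profiles are then intersected with the
   retained set.

## 2. Pair statistics and the SCI cutoff

All counts are unique-patient counts within one sex-age cell of `N`
patients. For a pair (a, b): `RR = n_ab·N/(n_a·n_b)`; `φ` is the Pearson
correlation of the two patient-level indicator vectors, computed in
closed form from the 2×2 table; `SCI = n_ab/√(n_a·n_b)` is the cosine of
the indicator vectors and does not depend on `N`. Pairs with RR < 1 or
φ < 0 (mutual exclusion) are removed before any thresholding. Degenerate
marginals (0 or N) yield NaN, reported as not-available.

φ is screened with the two-sided t-test for a correlation coefficient,
`t = φ√(N−2)/√(1−φ²)` against Student's t on N−2 degrees of freedom at
α = .01, with no multiple-testing correction (a Bonferroni option exists
but is off by default). The t approximation is anticonservative for
sparse 2×2 tables (tiny marginals); see §5 for how the generator's
default conditions keep marginals out of that regime, and note that with
real, large databases (10⁴–10⁵ patients per cell) the issue vanishes.

The SCI cutoff calibrates the SCI network to the φ-significant network.
With `S` significant pairs in a cell:

* Step 1: mark φ-significant pairs; count `S`.
* Step 2: `n_ab_minimum` = the largest co-occurrence threshold `t` such
  that at least `S` pairs have `n_ab ≥ t` (equivalently the S-th largest
  `n_ab`). When significance is monotone in `n_ab` — the typical
  large-sample situation — this equals the minimum `n_ab` among the
  significant pairs.
* Step 3: `q` = number of pairs with `n_ab ≥ n_ab_minimum` (`q ≥ S`,
  exceeding it only through ties in `n_ab`).
* Step 4: the cutoff is the q-th largest SCI; all pairs at or above it
  are kept, ties included (deterministic and order-free).

A cell with no significant pair yields an empty network, which is valid.

## 3. Networks and topology

Stratum networks contain exactly the kept pairs; nodes are their
endpoints (isolated codes are excluded), annotated with the cell
prevalence `n_a/N` and the ICD-10 chapter letter. The 16 stratum networks
of one sex merge into the sex-level network by edge union; a merged
edge's weight is its **maximum** SCI across contributing strata (the
strongest observed comorbidity), with all per-stratum values retained in
edge metadata so a mean rule can be recovered. Merged node prevalence is
the prevalence among that sex's multimorbid patients.

Topology metrics: density `2E/(n(n−1))`; diameter and average path
length on unweighted shortest paths (edge weights are similarities, not
distances), with the diameter taken as the maximum over connected
components and the average path length as the mean over all connected
node pairs; closeness with the Wasserman–Faust component scaling (finite
on disconnected networks); betweenness unnormalized. Metrics need n ≥ 2,
otherwise they are not-available.

The degree distribution is tested against a discrete power law
`p(x) ∝ x^(−α)`, `x ≥ xmin`: α by maximum likelihood under the
Hurwitz-zeta normalization (grid search with parabolic refinement), xmin
by minimizing the KS distance between the empirical and fitted tail
CDFs, and a semiparametric bootstrap p-value (tail from the fitted law,
body resampled, full refit per replicate). The xmin scan only admits
candidates whose tail keeps ≥ 10% of the sample: an unconstrained scan
can escape into a sliver of the extreme tail where any fast-decaying
distribution looks power-law-like. Sampling from the fitted law uses the
exact inverse CDF (tabulated to 10⁵, continuous approximation beyond).
The test's measured power against geometric alternatives at n = 5,000 is
about 85–90% (see the acceptance script's
`exponential_tail_rejection_rate`); p > .05 is read as "consistent with a
power law".

## 4. Roles and communities

*PageRank* runs on the undirected weighted graph, each edge acting as two
arcs with transition probability proportional to SCI, damping 0.85,
iterating until the largest score change is below 0.001 (both
configurable; oracle comparisons use a tolerance of 1e-13). *Connectivity*
is the weighted degree. The top-10-percentile rule used for central
diseases and hubs selects the top `m = n − ⌈0.9·n⌉` values (floored at 1
so every non-empty stratum names at least one disease), with ties at the
cutoff included — nearest-rank behaviour that is deterministic and
order-free.

*Degree trajectories* read each disease's unweighted degree across the 16
stratum networks (0 where absent). A boundary *leap* is a degree increase
≥ 6 between consecutive strata; a disease with ≥ 2 leaps is a *burst*
(both thresholds configurable); the first leap's destination stratum is
reported as the age of onset of network complexity.

*Communities* come from weighted Louvain (networkx implementation,
resolution 1) with seeded restarts (default 10), keeping the partition of
highest weighted Newman–Girvan modularity as recomputed by this package.
Each community's *root* is its member of largest weighted eigenvector
centrality, computed by shifted power iteration ((A+I)x, tolerance 1e-8,
L2 normalization; the shift guarantees convergence on bipartite graphs),
ties broken lexicographically. On disconnected graphs the principal
eigenvector concentrates on the dominant component; roots of communities
in other components then fall back to the lexicographic rule.

*Temporal trends* re-run the entire pipeline — profiles, prevalence
screen, pair statistics, cutoff, networks — within each calendar year
separately (a patient multimorbid only across two different years is
multimorbid in neither year). Communities in consecutive years are
matched greedily by shared-member count (ties by Jaccard, then
lexicographic roots), each community matched at most once. A matched
pair's similarity is the Pearson correlation of the two binary
membership-indicator vectors over the union of nodes present in either
year; its p-value is the **exact** two-sided permutation p given the
community sizes — a hypergeometric tail on the overlap count, which is
the exact null distribution of that correlation. The asymptotic t-based
p-value is badly anticonservative here (sparse binary vectors agree on
absences), to the point of calling a chance overlap of 2 codes between
two 8-code communities over 150 nodes "significant"; the exact p restores
the negative control (per-year code shuffling) to its nominal behaviour.
Matches with p > .05 are dropped.

## 5. The synthetic-data generator

The generator emulates a 5-year regional discharge database: two sexes
(1:1), 16 age strata with a mildly elderly-skewed patient distribution,
ICD-10-like 3-character codes with age-increasing prevalence, admissions
per patient Poisson over the window (patients have an implicit birth year
and age through the window, so stratum boundaries can be crossed — the
ambiguity the cohort module resolves), chronic codes re-coded at most
admissions (recurrence 0.8 by default), non-chronic "acute" filler codes,
and injected symptom-only admissions and sex-conflicting diagnoses
(1% each) to exercise the filters.

Planted structure, all expressed as *excess* odds multipliers so that a
boost of 0 leaves codes exactly independent:

* **Communities** — each patient joins each planted community
  independently with probability `membership_rate` (default 0.1); codes
  of a joined community have inclusion odds × (1 + `within_boost`).
  Same-community codes become positively associated; cross-community
  codes stay near-independent. Per-community membership (rather than a
  single latent affiliation) keeps the within-community φ independent of
  the number of planted communities — a single affiliation dilutes the
  signal as 1/k, which is undetectable at α = .01 for realistic k.
* **Hubs** — hub codes condition on the patient's planted-code burden K
  (count of planted codes drawn, capped at 3): odds
  × (1 + `hub_boost`)^min(K,3). This creates first-order association with
  *every* planted code — i.e. high connectivity across communities —
  which a pure prevalence boost cannot (prevalence alone creates no
  pairwise dependence and hence no network degree).
* **Bursts** — `plant_burst(config, code, leap_strata)` gives a code the
  hub mechanism restricted to an *active* partner set that grows at each
  leap stratum: crossing the i-th leap activates the i-th planted
  community as partners (odds × `burst_gamma`^burden over active
  partners). Each leap therefore raises the code's expected network
  degree by roughly one community size (≥ 6 with the default size 8).
  Planting requires at least as many communities as leaps.

Default prevalences: chronic codes draw an old-age prevalence uniformly
in [0.05, 0.12] (deterministically, from a fixed internal seed) and decay
geometrically by 0.95 per stratum toward youth. The floor matters: it
keeps per-cell marginals large enough that the t-approximation of the φ
test is calibrated. With rarer codes the t-test is anticonservative on
sparse 2×2 tables and whole cells fill with single-co-occurrence
artifacts — a real phenomenon of the method at small samples, but one
that would swamp the planted signal at the ~600-patient cells a
20,000-patient desk-scale study produces. A consequence of the floor is
a high overall multimorbidity share in synthetic cohorts (~90% of
patients; real inpatient databases report 30–60%): the generator trades
marginal realism of that one number for calibrated significance
machinery at desk scale.

What passing tests on synthetic data do **not** show about real data:
real ICD-10 prevalence is heavy-tailed with many sub-1% codes (where the
prevalence screen and the sparse-table caveat bite harder), real
comorbidity has age- and sex-specific structure rather than age-constant
planted communities, and real coding practice is noisier than the
uniform recurrence model. The generator validates the machinery, not the
epidemiology.

## 6. Validation conditions and problem sizes

The test suite validates against independent oracles: indicator-matrix
brute force for counts/RR/φ/SCI (1,000 random strata ≤ 200 patients),
explicit enumeration of the 4-step cutoff, exhaustive set-partition
enumeration for modularity (graphs ≤ 8 nodes), dense linear solves and
eigendecompositions for PageRank and eigenvector centrality (≤ 12 nodes,
agreement 1e-8), and scipy's zipf sampler for the power-law fit.
Study-scale checks run at 20,000 patients: planted-community recovery
(2 communities, within_boost 8 → odds ×9; adjusted Rand index vs ground
truth), hub recovery (hub_boost 2), burst detection (leaps planted at
strata 6 and 8), the independence null (≤ 5% of pairs pass the α = .01
screen; burst false-flag rate ≤ 10%), and temporal stability (7
communities covering the chronic list, within_boost 12, membership 0.2,
2.5 admissions/patient-year, recurrence 0.9: ≥ 80% of size-≥4 communities
find a significant next-year match; per-year code-relabel shuffling
collapses retention below 20% and roughly quarters the year-over-year
edge Jaccard from ~0.5). These problem sizes keep the full suite and the
acceptance script to a few minutes on one CPU while leaving the binomial
standard errors small enough for 3-SE checks.

## 7. Known limitations

* Eligibility steps that need data the package does not model (residency,
  survival through the window) are out of scope.
* The t-based φ screen is anticonservative for rare codes at small N; an
  exact-test option would change which pairs seed the cutoff.
* The temporal community matching is 1-to-1; community splits and merges
  appear as one matched pair plus unmatched remainders.
* The power-law test's power against exponential-tailed alternatives is
  ~85–90% at n = 5,000 — single non-rejections of a clearly exponential
  degree sequence are expected at that rate.
* Sex-level merged networks take the maximum SCI over strata; any
  cross-stratum aggregation is a convention, and downstream statistics
  (hubs on merged networks) inherit it.
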