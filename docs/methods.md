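# Methods

## The experiment the package models

A cache-fate experiment plants seed caches on a stratified design — study
area × elevation zone (subalpine forest vs alpine treeline) × microsite
(near a rock, at a tree base, in the open) — and revisits each cache over
two seasons. Year 1 yields counts of missing seeds (attributed to rodent
pilferage), seed coats (evidence of consumption), and first-year germinants;
year 2 yields surviving seedlings and delayed germinants. The cache, not the
seed, is the sampling unit: seeds within a cache share their fate
environment, and seedling clusters commonly fuse, so cache-level binary
outcomes (≥ 1 seed affected) keep the independence assumption defensible.

## Stage-conditional cohorts

Each life stage is analysed on the caches eligible for it:

| stage            | eligibility                                           | success              |
|------------------|-------------------------------------------------------|----------------------|
| pilferage        | located in year 1                                     | ≥ 1 seed missing     |
| germination (y1) | ≥ 1 intact seed after pilferage, **or** a germinant   | ≥ 1 germinant        |
| survival         | ≥ 1 first-year germinant                              | ≥ 1 seedling in y2   |
| germination (2yr)| germination-eligible **and** relocated in year 2      | germinant in y1 or y2|

Caches never located in year 1 enter no cohort. Null and zero are distinct
throughout: an empty CSV field means "not observed", 0 means "observed,
none". A cache eligible for a year-2 stage but never relocated has an
*unknown* outcome and is dropped from that cohort with a warning — counting
it as a failure would bias proportions downward.

The record invariant `n_missing + n_germinants ≤ n_seeds_cached` treats a
germinated seed as accounted for, not missing; germination eligibility
`(n_seeds − n_missing ≥ 1) or (n_germinants ≥ 1)` is equivalent to requiring
an intact seed or a germinant, so a cache whose every non-germinated seed
was pilfered stays in the germination cohort via its germinant.

## Odds ratios and intervals

Odds are p/(1 − p); the odds ratio of two strata is (a·d)/(b·c) on the
success/failure table. The decision rule is interval-based: a 95 % CI
containing 1.0 is reported as "no difference" (`contains_one`).

CI methods are configurable because no single convention dominates field
reports:

* `wald` (default): exp(ln OR ± z·√(1/a + 1/b + 1/c + 1/d));
* `haldane`: the same after adding 0.5 to every cell;
* `exact`: the conditional (Fisher) interval via
  `scipy.stats.contingency.odds_ratio`.

A zero cell always triggers the +0.5 adjustment for the point estimate and
Wald interval, flagged on the result. Proportions default to exact
Clopper–Pearson intervals (`statsmodels`), with Wilson as an option — the
exact method reproduces the reference study's printed percentage intervals
to printed rounding in the test suite's spot checks. No multiplicity
correction is applied by default, matching common practice for planned
pairwise contrasts; Bonferroni and Benjamini–Hochberg adjusted p-values
(from the two-sided normal test on ln OR) are opt-in output columns.
Reports round odds ratios to 2 decimals and percentages to 1.

Pairwise contrasts use a fixed canonical orientation — rock/tree, rock/open,
tree/open; treeline/subalpine; study areas in order of first appearance — so
that reported ratios are comparable across runs.

## Ripley's K, difference of K, and the random-labeling envelope

K̂(r) = |W|/(n(n−1)) · Σ_{i≠j} w_ij · 1(d_ij ≤ r), on an axis-aligned
rectangular window with Euclidean distances (projected planar meters;
geographic coordinates are rejected). Corrections:

* `none` — w_ij = 1; used for brute-force cross-checks;
* `translation` (default) — w_ij = |W| / ((W_x − |Δx|)(W_y − |Δy|)); exactly
  unbiased for CSR on rectangles; valid for r < min(W_x, W_y);
* `isotropic` — w_ij is the reciprocal fraction of the circle centred at i
  with radius d_ij inside the window, computed in closed form by
  inclusion–exclusion over the four sides with corner-overlap terms; capped
  at r < min(W_x, W_y)/2.

The marked-pattern statistic is D(r) = K̂_success(r) − K̂_failure(r),
requiring ≥ 2 points of each mark. Its null distribution under random
labeling (equal success probability for all caches, the observed success
count fixed) is simulated by permuting marks over the fixed locations;
location geometry and pair weights are computed once per pattern, so each
permutation costs one masked weighted histogram. Both mark classes are
assumed to share a common spatial intensity surface up to a constant —
random labeling is the correct null for fates assigned at fixed cache sites,
as opposed to independent thinning of two processes.

Envelopes are **pointwise**: at each grid distance the bounds are the order
statistics ⌊α(n_sim+1)⌋ and ⌈(1−α)(n_sim+1)⌉ of the simulated curves
(α = (1−level)/2), the exact rank convention at n_sim = 1000 and level 0.95
(ranks 25 and 976). This requires n_sim ≥ 39 at the 95 % level; smaller
values are rejected. Departures are the maximal contiguous grid intervals
outside the bounds, labeled success- or failure-clustered. Pointwise bounds
support the "departure at distances r ∈ [..]" reading but carry the usual
multiple-testing caveat across distances: under the null about 5 % of grid
points exit the envelope by chance (the acceptance script measures this
rate).

Defaults where the analysis leaves a free choice: the observation window is
the bounding box of each group's caches (configurable margin, default 0 m);
the r grid is 128 equally spaced distances from 0 to a quarter of the
shorter window side; grouping is per study area × elevation zone;
1,000 permutations at the 95 % level. Per-group RNG streams are spawned
deterministically from the top-level seed, so results are reproducible and
independent of group order. Groups with fewer than two points of either mark
are skipped with a log message, not an error.

## The synthetic generator

`simulate_study` emulates the reference design: per-stratum cache counts
(734 caches over two areas, the never-located remainder spread round-robin),
uniform placement in one rectangle per area × zone (default 700 m × 700 m,
≈ 49 ha, matching the magnitude of the field areas — only the area scale
matters for K), cache sizes from Poisson(λ = 3) renormalized over 1–7
(sampled exactly from the enumerated 7-point pmf), and per-stratum Bernoulli
stage fates at the reference study's observed proportions. Pilferage removes
all seeds with probability 0.749 (the reference total-loss fraction among
pilfered caches), otherwise a uniform partial count — the partial-loss
distribution is a stand-in, as no empirical distribution is available.
Caches are located in year 1 with probability 717/734 and revisited in year
2 whenever an intact seed or germinant remains.

Spatial clustering of fates uses a two-rate cluster-centre model: per stage,
success probability `inside_prob` within `radius` of any of `n_centers`
uniform centres, `outside_prob` elsewhere. This is deliberately the simplest
mechanism producing difference-of-K departures at a controllable scale; it
is not a mechanistic model of rodent foraging. The power analyses use a
300 m × 300 m window at n = 200 so that two 50 m discs occupy a
non-negligible share (~17 %) of the window — a density comparable to caches
within a single zone — with rates 0.9/0.1 and radius 50 m.

`mirror_study_table` is the deterministic counterpart: a synthetic table
whose per-stratum stage *counts* equal the counts recovered from the
reference study's summary tables (percent × n, rounded half away from zero).
Those recovered counts aggregate exactly to the published area- and
zone-level counts, and the pairwise odds ratios computed from them reproduce
all twelve reproducible published point estimates to two decimals (the
acceptance script's first block). Coordinates are synthetic — the field
coordinates were never published — so the mirror table supports the odds
pipeline, not the spatial one.

What the generator does *not* emulate: inhomogeneous cache intensity,
correlation of fates between neighbouring caches beyond the two-rate model,
microsite-dependent spatial structure, cache-size effects on fate
probabilities, and secondary dispersal (re-caching). Passing tests therefore
demonstrate correctness of the estimators and calibration of the permutation
procedure under the stated design, not robustness to those field
complexities.

## Numerical and degenerate-input choices

* Truncated-Poisson sampling draws directly from the renormalized pmf
  (truncation law, not rejection); a range with essentially zero Poisson
  mass raises an error.
* Pair distances are binned once per pattern (`searchsorted`, left edge:
  d = r counts as within r); K̂ is a cumulative weighted histogram, exactly
  equal to the double loop for `none` correction.
* Translation weights are infinite for pairs spanning nearly the full
  window; such pairs lie beyond any valid r grid and never enter the sums.
* Bounding-box windows use a relative 1e-9 containment tolerance so edge
  points are inside their own box.
* CSV writing uses the shortest exact float representation, making
  write-then-read the identity on records.
* One empirical accident documented rather than patched: one published
  within-area pilferage contrast (tree vs open, subalpine, first site)
  computes to 2.54 from the published table counts while the narrative text
  prints 2.58; the counts-based value is treated as authoritative. The
  published two-year *within-area* ratios are likewise not recoverable from
  the published two-year table under its stated denominators (relocation
  losses are not broken out), so only the between-area two-year contrast is
  used as a reproduction target; the schema records `relocated_y2` so either
  denominator convention can be applied to real data.
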