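# cachescape

Early-recruitment analysis for seed-caching field experiments: do buried seed
caches near rocks, at tree bases, or in the open — in subalpine forest versus
the alpine treeline ecotone — differ in their odds of rodent pilferage,
germination, and seedling survival, and are those fates spatially clustered?

The package is written for ecologists running cache-fate experiments of the
kind used to study bird-dispersed pines (e.g. whitebark pine cached by
Clark's nutcrackers): caches are planted on a stratified design, revisited
over two seasons, and each cache's fate is recorded as counts of missing
seeds, first-year germinants, surviving seedlings, and delayed second-year
germinants.

## What it computes

**Stage-conditional cohorts.** The sampling unit is the cache. Sample sizes
shrink stage by stage: pilferage is assessed on every cache located in year
1; germination on caches with ≥ 1 intact seed after pilferage and/or a
first-year germinant; survival on caches with ≥ 1 first-year germinant;
two-year germination on the germination cohort relocated in year 2.

**Odds-ratio contrasts.** For a stage proportion *p*, the odds are
*p*/(1 − *p*); for two strata with success/failure counts (a, b) and (c, d)
the odds ratio is OR = (a·d)/(b·c), with the default confidence interval on
the log scale, exp(ln OR ± z·√(1/a + 1/b + 1/c + 1/d)). A CI containing 1.0
is read as "no difference". Contrasts are computed for every pair of study
areas, elevation zones within area, and microsites within area × zone.
Proportions carry exact Clopper–Pearson intervals.

**Spatial clustering of fates.** Marked point-pattern analysis via the
difference of Ripley's K functions, D(r) = K̂_success(r) − K̂_failure(r),
with translation (default), isotropic, or no edge correction. Pointwise 95 %
confidence envelopes come from simulating the random-labeling null: marks
are permuted over the fixed cache locations (1,000 permutations by default),
preserving the observed success proportion. Distances where D(r) exceeds the
upper envelope indicate clustering of successes relative to failures at that
scale; below the lower envelope, clustering of failures.

**Synthetic studies.** A generator emulates the full design — stratified
placement in rectangular windows, cache sizes from a truncated Poisson
(λ = 3 on 1–7), per-stratum Bernoulli fates, optional two-rate spatial
clustering of any stage's fates — so every analysis stage is testable
without field data. Defaults are calibrated to a published two-mountain
experiment (734 caches, two areas × {subalpine, treeline} × {rock, tree,
open}).

## Worked example

```python
from cachescape import (mirror_study_table, build_cohort,
                        pairwise_odds_ratios, proportion_ci, Stage)

records = mirror_study_table(seed=0)          # reference-study cache table
germ = build_cohort(records, Stage.GERMINATION_Y1)
print("germination cohort:", germ.n, "caches,", germ.n_success, "germinated")

(ct,) = pairwise_odds_ratios(germ, "study_area")
r = ct.result
print(f"odds ratio {ct.level1}/{ct.level2}: {r.or_estimate:.2f} "
      f"(95% CI {r.ci_low:.2f}-{r.ci_high:.2f}), no-difference: {r.contains_one}")

a = germ.subset(study_area="site_a")
p = proportion_ci(a.n_success, a.n)
print(f"site_a germination: {100*p.p_hat:.1f}% "
      f"(95% CI {100*p.ci_low:.1f}-{100*p.ci_high:.1f})")
```

prints

```
germination cohort: 429 caches, 229 germinated
odds ratio site_a/site_b: 2.42 (95% CI 1.64-3.56), no-difference: False
site_a germination: 64.1% (95% CI 57.3-70.4)
```

— germination odds at the first site are 2.42 times those at the second, an
interval excluding 1.0, so a real between-site difference is concluded;
64.1 % of the first site's germination cohort produced a first-year
seedling.

The spatial side, on a synthetic study with pilferage clustered inside two
50 m discs (success probability 0.9 inside, 0.1 outside):

```python
from cachescape import (SimulationConfig, StratumDesign, StageRates,
                        ClusterSpec, simulate_study, run_spatial_analysis)

cfg = SimulationConfig(
    seed=3,
    design=[StratumDesign("demo", "treeline", "open", 200)],
    windows={("demo", "treeline"): (300.0, 300.0)},
    stage_probabilities={("demo", "treeline", "open"):
                         StageRates(0.5, 0.6, 0.5, 0.1)},
    p_located=1.0,
    clustering={"pilferage": ClusterSpec(n_centers=2, radius=50.0,
                                         inside_prob=0.9, outside_prob=0.1)},
)
(env,) = run_spatial_analysis(simulate_study(cfg), Stage.PILFERAGE,
                              n_sim=999, seed=1)
for lo, hi, direction in env.departures:
    print(f"departure {lo:.0f}-{hi:.0f} m: {direction}")
```

prints

```
departure 12-74 m: success-clustered
```

— the difference-of-K curve exits the upper envelope over 12–74 m,
recovering clustering at roughly the scale the generator injected.

The same pipeline is scriptable from the shell:

```sh
cachescape simulate --seed 7 --out study.csv
cachescape odds  --table study.csv --out-dir results/
cachescape kdiff --table study.csv --seed 7 --out-dir results/
cachescape run   --config run.yaml        # simulate + odds + kdiff + manifest
```

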