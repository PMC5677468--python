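"""Synthetic cache-fate study generator.

Emulates a two-site seed-caching field experiment in the alpine treeline
ecotone: caches are stratified by study area × elevation zone (subalpine
forest vs treeline) × microsite (rock, tree, open), placed uniformly in a
rectangular window per area/zone, sized by a truncated Poisson draw, and
assigned Bernoulli fates per stratum for each life stage (pilferage,
first-year germination, seedling survival, delayed second-year germination).

Two generators are provided:

* :func:`simulate_study` — a stochastic generator driven by
  :class:`SimulationConfig`; its defaults are calibrated to the per-stratum
  sample sizes and observed stage proportions of a published two-mountain
  whitebark pine caching experiment, so a default run has the size and rate
  structure the downstream analysis assumes.
* :func:`mirror_study_table` — a deterministic table whose per-stratum stage
  *counts* reproduce that experiment's summary tables exactly (coordinates
  are synthetic; the raw field coordinates were never published).

Fate clustering is modelled, optionally, by a two-rate cluster-centre
mechanism: within ``radius`` of any centre the stage success probability is
``inside_prob``, elsewhere ``outside_prob``.  This produces difference-of-K
departures at a controllable spatial scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data import CacheRecord, Stage, write_cache_table

__all__ = [
    "StageRates",
    "ClusterSpec",
    "StratumDesign",
    "SimulationConfig",
    "truncated_poisson_pmf",
    "sample_cache_size",
    "sample_cache_sizes",
    "place_caches",
    "assign_outcomes",
    "simulate_study",
    "default_config",
    "mirror_study_table",
    "STUDY_SUMMARY",
]


class ConfigError(ValueError):
    """A simulation configuration value is missing or out of range."""


# ---------------------------------------------------------------------------
# Reference study summary
#
# Per-stratum sample sizes and stage percentages of the reference field
# experiment (two study areas; located-cache counts per stratum; percent of
# caches pilfered; germination cohort size and percent germinated in year 1;
# survival cohort size and percent surviving to year 2; percent with new
# year-2 germinants and percent germinated over both years, both out of the
# germination cohort).  Used as the generator's default calibration and by
# mirror_study_table.

@dataclass(frozen=True)
class StratumSummary:
    study_area: str
    elevation_zone: str
    microsite: str
    n_located: int
    pct_pilfered: float
    n_germ_cohort: int
    pct_germinated: float
    n_surv_cohort: int
    pct_survived: float
    pct_germ_y2: float
    pct_germ_2yr: float


STUDY_SUMMARY: tuple[StratumSummary, ...] = (
    StratumSummary("site_a", "subalpine", "open", 61, 31.1, 49, 59.2, 29, 51.7, 30.6, 79.6),
    StratumSummary("site_a", "subalpine", "rock", 58, 56.9, 38, 73.7, 28, 42.9, 26.3, 92.1),
    StratumSummary("site_a", "subalpine", "tree", 58, 53.4, 33, 48.5, 16, 56.3, 30.3, 69.7),
    StratumSummary("site_a", "treeline", "open", 64, 57.8, 40, 70.0, 28, 60.7, 40.0, 90.0),
    StratumSummary("site_a", "treeline", "rock", 63, 60.3, 31, 77.4, 24, 87.5, 32.3, 90.3),
    StratumSummary("site_a", "treeline", "tree", 62, 62.9, 26, 53.8, 14, 92.9, 65.4, 88.5),
    StratumSummary("site_b", "subalpine", "open", 58, 44.8, 40, 25.0, 10, 30.0, 10.0, 30.0),
    StratumSummary("site_b", "subalpine", "rock", 59, 40.7, 43, 32.6, 14, 21.4, 7.0, 37.2),
    StratumSummary("site_b", "subalpine", "tree", 58, 46.6, 41, 29.3, 12, 8.3, 2.4, 31.7),
    StratumSummary("site_b", "treeline", "open", 51, 58.8, 31, 58.1, 18, 44.4, 6.5, 61.3),
    StratumSummary("site_b", "treeline", "rock", 67, 62.7, 35, 62.9, 22, 27.3, 5.7, 62.9),
    StratumSummary("site_b", "treeline", "tree", 58, 69.0, 22, 63.6, 14, 14.3, 9.1, 72.7),
)

#: caches created but never relocated in year 1, per study area
UNLOCATED_EXTRA = {"site_a": 6, "site_b": 11}


def _round(v: float) -> int:
    """Round half away from zero (the convention used for count recovery)."""
    return int(math.floor(v + 0.5))


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class StageRates:
    """Per-stratum Bernoulli success probabilities for the four stages."""

    p_pilferage: float
    p_germination: float
    p_survival: float
    p_germ_y2: float

    def validate(self, label: str) -> None:
        for name in ("p_pilferage", "p_germination", "p_survival", "p_germ_y2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"stratum {label}: {name}={v} outside [0, 1]")


@dataclass(frozen=True)
class ClusterSpec:
    """Two-rate spatial clustering of one stage's fates.

    ``inside_prob`` applies within ``radius`` meters of any of ``n_centers``
    cluster centres (drawn uniformly in each area/zone window);
    ``outside_prob`` applies elsewhere.  Overrides the stratum probability.
    """

    n_centers: int = 2
    radius: float = 50.0
    inside_prob: float = 0.9
    outside_prob: float = 0.1

    def validate(self, label: str) -> None:
        if self.n_centers < 1:
            raise ConfigError(f"clustering {label}: n_centers must be >= 1")
        if self.radius <= 0:
            raise ConfigError(f"clustering {label}: radius must be > 0")
        for name in ("inside_prob", "outside_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"clustering {label}: {name}={v} outside [0, 1]")


@dataclass(frozen=True)
class StratumDesign:
    study_area: str
    elevation_zone: str
    microsite: str
    n_caches: int

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.study_area, self.elevation_zone, self.microsite)


@dataclass
class SimulationConfig:
    """Full specification of one synthetic study.

    Defaults mirror the reference experiment: the stratum design of the
    located caches plus the never-located remainder, cache sizes truncated
    Poisson(3) on [1, 7], ~700 m × 700 m (≈49 ha) windows per area/zone,
    stage probabilities at the observed per-stratum proportions, 74.9 % of
    pilfered caches losing every seed.
    """

    seed: int = 0
    design: list[StratumDesign] = field(default_factory=list)
    windows: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    cache_size_lambda: float = 3.0
    cache_size_range: tuple[int, int] = (1, 7)
    stage_probabilities: dict[tuple[str, str, str], StageRates] = field(default_factory=dict)
    p_located: float = 717 / 734
    p_total_loss: float = 0.749
    clustering: dict[str, ClusterSpec] = field(default_factory=dict)

    def window_for(self, study_area: str, elevation_zone: str) -> tuple[float, float]:
        return self.windows.get((study_area, elevation_zone), (700.0, 700.0))

    def validate(self) -> None:
        if not self.design:
            raise ConfigError("design is empty")
        lo, hi = self.cache_size_range
        if not (isinstance(lo, int) and isinstance(hi, int) and 1 <= lo <= hi):
            raise ConfigError(f"cache_size_range {self.cache_size_range} invalid")
        if self.cache_size_lambda <= 0:
            raise ConfigError("cache_size_lambda must be > 0")
        for p_name in ("p_located", "p_total_loss"):
            v = getattr(self, p_name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{p_name}={v} outside [0, 1]")
        for d in self.design:
            if d.n_caches < 0:
                raise ConfigError(f"stratum {'/'.join(d.key)}: n_caches < 0")
        for (area, zone), (w, h) in self.windows.items():
            if w <= 0 or h <= 0:
                raise ConfigError(f"window {area}/{zone}: non-positive dimensions")
        for key, rates in self.stage_probabilities.items():
            rates.validate("/".join(key))
        for stage_name, spec in self.clustering.items():
            Stage(stage_name)  # raises ValueError on unknown stage
            spec.validate(stage_name)


def default_config(seed: int = 0) -> SimulationConfig:
    """The reference-study configuration (734 caches across both sites)."""
    design: list[StratumDesign] = []
    extra_left = dict(UNLOCATED_EXTRA)
    per_area = {}
    for s in STUDY_SUMMARY:
        per_area.setdefault(s.study_area, []).append(s)
    for area, strata in per_area.items():
        # spread the never-located caches round-robin over the strata
        extras = [0] * len(strata)
        for i in range(extra_left.get(area, 0)):
            extras[i % len(strata)] += 1
        for s, e in zip(strata, extras):
            design.append(
                StratumDesign(s.study_area, s.elevation_zone, s.microsite, s.n_located + e)
            )
    probs = {
        (s.study_area, s.elevation_zone, s.microsite): StageRates(
            s.pct_pilfered / 100.0,
            s.pct_germinated / 100.0,
            s.pct_survived / 100.0,
            s.pct_germ_y2 / 100.0,
        )
        for s in STUDY_SUMMARY
    }
    return SimulationConfig(seed=seed, design=design, stage_probabilities=probs)


# ---------------------------------------------------------------------------
# Cache-size sampler


def truncated_poisson_pmf(lam: float, lo: int, hi: int) -> np.ndarray:
    """Poisson(``lam``) mass renormalized over the integers ``lo..hi``."""
    if lo < 1 or hi < lo:
        raise ConfigError(f"invalid truncation range [{lo}, {hi}]")
    mass = stats.poisson.pmf(np.arange(lo, hi + 1), lam)
    total = mass.sum()
    if not total > 1e-12:
        raise ConfigError(
            f"Poisson(lambda={lam}) has essentially no mass on [{lo}, {hi}]"
        )
    return mass / total


def sample_cache_sizes(
    rng: np.random.Generator, lam: float, lo: int, hi: int, size: int
) -> np.ndarray:
    """Vectorized truncated-Poisson cache-size draws."""
    pmf = truncated_poisson_pmf(lam, lo, hi)
    return rng.choice(np.arange(lo, hi + 1), size=size, p=pmf)


def sample_cache_size(rng: np.random.Generator, lam: float, lo: int, hi: int) -> int:
    """One truncated-Poisson cache-size draw."""
    return int(sample_cache_sizes(rng, lam, lo, hi, 1)[0])


# ---------------------------------------------------------------------------
# Placement


def place_caches(config: SimulationConfig, rng: np.random.Generator) -> list[CacheRecord]:
    """Place caches uniformly in each stratum's window; fates left unset.

    The design lists each (area, zone, microsite) stratum with its cache
    count, which realises the balanced assignment of microsites to point
    locations.  Returned records have ``located_y1=False`` and null fate
    fields; :func:`assign_outcomes` fills them in.
    """
    config.validate()
    records: list[CacheRecord] = []
    counter: dict[str, int] = {}
    for d in config.design:
        if d.n_caches == 0:
            continue
        w, h = config.window_for(d.study_area, d.elevation_zone)
        xs = rng.uniform(0.0, w, size=d.n_caches)
        ys = rng.uniform(0.0, h, size=d.n_caches)
        sizes = sample_cache_sizes(
            rng, config.cache_size_lambda, *config.cache_size_range, d.n_caches
        )
        for x, y, k in zip(xs, ys, sizes):
            i = counter.get(d.study_area, 0) + 1
            counter[d.study_area] = i
            records.append(
                CacheRecord(
                    cache_id=f"{d.study_area}-{i:04d}",
                    study_area=d.study_area,
                    elevation_zone=d.elevation_zone,
                    microsite=d.microsite,
                    x=float(x),
                    y=float(y),
                    n_seeds_cached=int(k),
                    located_y1=False,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Fates


def _draw_centers(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[tuple[str, str, str], np.ndarray]:
    """Cluster centres per (stage, area, zone), uniform in each window."""
    centers: dict[tuple[str, str, str], np.ndarray] = {}
    zones = sorted({(d.study_area, d.elevation_zone) for d in config.design})
    for stage_name in sorted(config.clustering):
        spec = config.clustering[stage_name]
        for area, zone in zones:
            w, h = config.window_for(area, zone)
            pts = rng.uniform(0.0, 1.0, size=(spec.n_centers, 2)) * np.array([w, h])
            centers[(stage_name, area, zone)] = pts
    return centers


def _stage_prob(
    stage: Stage,
    base_p: float,
    rec: CacheRecord,
    config: SimulationConfig,
    centers: Mapping[tuple[str, str, str], np.ndarray],
) -> float:
    spec = config.clustering.get(stage.value)
    if spec is None:
        return base_p
    pts = centers[(stage.value, rec.study_area, rec.elevation_zone)]
    d2 = np.min((pts[:, 0] - rec.x) ** 2 + (pts[:, 1] - rec.y) ** 2)
    return spec.inside_prob if d2 <= spec.radius**2 else spec.outside_prob


def assign_outcomes(
    records: Sequence[CacheRecord],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[CacheRecord]:
    """Draw per-cache fates for placed records.

    Each located cache is pilfered with its stratum (or clustering-resolved)
    probability; a pilfered cache loses every seed with probability
    ``p_total_loss``, otherwise a uniform partial count.  Germination is
    drawn for caches with intact seeds remaining; survival for caches with a
    first-year germinant; delayed germination for caches with seeds still
    intact after year-1 germination.  Caches with intact seeds or germinants
    are revisited (``relocated_y2``); others have null year-2 fields.
    """
    centers = _draw_centers(config, rng)
    out: list[CacheRecord] = []
    for rec in records:
        key = (rec.study_area, rec.elevation_zone, rec.microsite)
        rates = config.stage_probabilities.get(key)
        if rates is None:
            raise ConfigError(f"no stage probabilities for stratum {'/'.join(key)}")
        if rng.random() >= config.p_located:
            out.append(replace(rec, located_y1=False))
            continue

        n_seeds = rec.n_seeds_cached
        p_pilf = _stage_prob(Stage.PILFERAGE, rates.p_pilferage, rec, config, centers)
        pilfered = rng.random() < p_pilf
        if pilfered:
            if n_seeds == 1 or rng.random() < config.p_total_loss:
                n_missing = n_seeds
            else:
                n_missing = int(rng.integers(1, n_seeds))
        else:
            n_missing = 0
        n_coats = int(rng.integers(0, n_missing + 1)) if n_missing else 0

        remaining = n_seeds - n_missing
        if remaining >= 1:
            p_germ = _stage_prob(
                Stage.GERMINATION_Y1, rates.p_germination, rec, config, centers
            )
            n_germ = int(rng.integers(1, remaining + 1)) if rng.random() < p_germ else 0
        else:
            n_germ = 0

        relocated = remaining >= 1 or n_germ >= 1
        n_live: int | None = None
        n_new: int | None = None
        if relocated:
            if n_germ >= 1:
                p_surv = _stage_prob(Stage.SURVIVAL, rates.p_survival, rec, config, centers)
                n_live = int(rng.integers(1, n_germ + 1)) if rng.random() < p_surv else 0
            else:
                n_live = 0
            left = n_seeds - n_missing - n_germ
            if left >= 1:
                p_g2 = _stage_prob(
                    Stage.GERMINATION_2YR, rates.p_germ_y2, rec, config, centers
                )
                n_new = int(rng.integers(1, left + 1)) if rng.random() < p_g2 else 0
            else:
                n_new = 0

        new_rec = replace(
            rec,
            located_y1=True,
            n_missing_y1=n_missing,
            n_seed_coats_y1=n_coats,
            n_germinants_y1=n_germ,
            relocated_y2=relocated,
            n_live_seedlings_y2=n_live,
            n_new_germinants_y2=n_new,
        )
        new_rec.validate()
        out.append(new_rec)
    return out


def simulate_study(
    config: SimulationConfig | None = None, path: str | Path | None = None
) -> list[CacheRecord]:
    """Place caches and draw fates; optionally write the CSV table."""
    if config is None:
        config = default_config()
    config.validate()
    rng = np.random.default_rng(config.seed)
    records = assign_outcomes(place_caches(config, rng), config, rng)
    if path is not None:
        write_cache_table(records, path)
    return records


# ---------------------------------------------------------------------------
# Deterministic mirror table


def mirror_study_table(seed: int = 0, include_unlocated: bool = False) -> list[CacheRecord]:
    """Deterministic synthetic table reproducing the reference stage counts.

    Per stratum the number of pilfered caches, the germination cohort and its
    successes, the survival cohort and its successes, and the year-2 and
    two-year germination counts all equal the counts recovered from the
    reference study's summary tables (percent × n, rounded half away from
    zero).  Cache coordinates are synthetic (uniform in each window, driven
    by ``seed``); the reference study never published raw coordinates.

    Within each stratum the construction is:

    * ``n_located − n_germ_cohort`` caches pilfered with total seed loss
      (these leave the recruitment pipeline);
    * the germination cohort, of which the first ``pilfered − total_loss``
      are partially pilfered, the first ``n_surv_cohort`` germinated in
      year 1, the first ``pct_survived × n_surv`` of those survived, and
      year-2 germinants are placed to reproduce both the year-2-only and
      both-years counts.
    """
    rng = np.random.default_rng(seed)
    records: list[CacheRecord] = []
    for s in STUDY_SUMMARY:
        n = s.n_located
        pilf = _round(s.pct_pilfered * n / 100.0)
        g_cohort = s.n_germ_cohort
        g13 = s.n_surv_cohort
        surv = _round(s.pct_survived * g13 / 100.0)
        g14 = _round(s.pct_germ_y2 * g_cohort / 100.0)
        g2yr = _round(s.pct_germ_2yr * g_cohort / 100.0)
        full_loss = n - g_cohort
        partial = pilf - full_loss
        both_years = g13 + g14 - g2yr
        y2_only = g2yr - g13
        if not (0 <= partial and 0 <= both_years <= min(g13, g14) and 0 <= y2_only):
            raise ValueError(f"inconsistent summary for stratum {s}")

        w, h = 700.0, 700.0
        xs = rng.uniform(0, w, size=n)
        ys = rng.uniform(0, h, size=n)
        prefix = f"{s.study_area}-{s.elevation_zone}-{s.microsite}"
        idx = 0
        for _ in range(full_loss):
            records.append(
                CacheRecord(
                    cache_id=f"{prefix}-{idx:03d}",
                    study_area=s.study_area,
                    elevation_zone=s.elevation_zone,
                    microsite=s.microsite,
                    x=float(xs[idx]),
                    y=float(ys[idx]),
                    n_seeds_cached=2,
                    located_y1=True,
                    n_missing_y1=2,
                    n_seed_coats_y1=1,
                    n_germinants_y1=0,
                    relocated_y2=False,
                )
            )
            idx += 1
        for i in range(g_cohort):
            n_missing = 1 if i < partial else 0
            n_germ = 1 if i < g13 else 0
            n_live = 1 if i < surv else 0
            n_new = 1 if (i < both_years or g13 <= i < g13 + y2_only) else 0
            rec = CacheRecord(
                cache_id=f"{prefix}-{idx:03d}",
                study_area=s.study_area,
                elevation_zone=s.elevation_zone,
                microsite=s.microsite,
                x=float(xs[idx]),
                y=float(ys[idx]),
                n_seeds_cached=4,
                located_y1=True,
                n_missing_y1=n_missing,
                n_seed_coats_y1=n_missing,
                n_germinants_y1=n_germ,
                relocated_y2=True,
                n_live_seedlings_y2=n_live,
                n_new_germinants_y2=n_new,
            )
            rec.validate()
            records.append(rec)
            idx += 1
    if include_unlocated:
        for area, extra in UNLOCATED_EXTRA.items():
            for j in range(extra):
                records.append(
                    CacheRecord(
                        cache_id=f"{area}-lost-{j:02d}",
                        study_area=area,
                        elevation_zone="treeline",
                        microsite="open",
                        x=float(rng.uniform(0, 700)),
                        y=float(rng.uniform(0, 700)),
                        n_seeds_cached=3,
                        located_y1=False,
                    )
                )
    return records
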