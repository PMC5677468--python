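"""Ripley's K, difference-of-K for marked patterns, and permutation envelopes.

For a stationary point process of intensity λ, λ·K(r) is the expected number
of further points within distance r of a typical point; under complete
spatial randomness (CSR) K(r) = πr².  For a binary-marked pattern (success /
failure at fixed cache locations) the contrast of interest is

    D(r) = K̂_success(r) − K̂_failure(r),

whose null distribution under the *random labeling hypothesis* — marks
permuted over the fixed locations, preserving the marginal success count —
is simulated to build pointwise confidence envelopes.  Distances where the
observed D(r) exceeds the upper envelope indicate clustering of successes
relative to failures at that scale; below the lower envelope, clustering of
failures.

Estimator (border effects handled by per-pair edge-correction weights):

    K̂(r) = |W| / (n(n−1)) · Σ_{i≠j} w_ij · 1(d_ij ≤ r)

with w_ij = 1 (no correction); the translation correction
w_ij = |W| / ((width − |Δx|)(height − |Δy|)); or Ripley's isotropic
correction, the reciprocal fraction of the circle centred at i with radius
d_ij lying inside the window.  All corrections assume an axis-aligned
rectangular window and Euclidean distances on projected planar coordinates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import CacheRecord, Stage, StageCohort, build_cohort

logger = logging.getLogger("cachescape")

__all__ = [
    "Window",
    "PointPattern",
    "KEstimate",
    "EnvelopeResult",
    "default_r_grid",
    "k_estimate",
    "k_difference",
    "random_labeling_envelope",
    "run_spatial_analysis",
    "envelope_frame",
    "departures_summary",
    "plot_envelope",
]

CORRECTIONS = ("none", "translation", "isotropic")

#: minimum simulations for a two-sided pointwise envelope at a given level:
#: the lower order statistic floor(alpha * (n_sim + 1)) must exist.


class SpatialError(ValueError):
    """Precondition violation in a spatial computation."""


@dataclass(frozen=True)
class Window:
    """Axis-aligned rectangular observation window, in meters."""

    x0: float
    y0: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise SpatialError("window must have positive width and height")

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, xy: np.ndarray) -> np.ndarray:
        # tolerance for points sitting exactly on a bounding-box edge
        eps = 1e-9 * max(self.width, self.height, 1.0)
        x, y = xy[:, 0], xy[:, 1]
        return (
            (x >= self.x0 - eps) & (x <= self.x0 + self.width + eps)
            & (y >= self.y0 - eps) & (y <= self.y0 + self.height + eps)
        )

    @classmethod
    def bounding(cls, xy: np.ndarray, margin: float = 0.0) -> "Window":
        """Bounding box of the points, expanded by ``margin`` on each side."""
        x0, y0 = xy.min(axis=0) - margin
        x1, y1 = xy.max(axis=0) + margin
        return cls(float(x0), float(y0), float(x1 - x0), float(y1 - y0))


@dataclass
class PointPattern:
    """Binary-marked planar points in a rectangular window."""

    xy: np.ndarray  # (n, 2)
    marks: np.ndarray  # (n,) bool; True = success
    window: Window

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.marks = np.asarray(self.marks, dtype=bool)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise SpatialError("xy must be an (n, 2) array")
        if self.marks.shape != (len(self.xy),):
            raise SpatialError("marks must be one boolean per point")
        if not self.window.contains(self.xy).all():
            raise SpatialError("all points must lie inside the window")

    @property
    def n(self) -> int:
        return len(self.xy)


@dataclass(frozen=True)
class KEstimate:
    r_grid: np.ndarray
    k_values: np.ndarray
    correction: str
    n_points: int


@dataclass(frozen=True)
class EnvelopeResult:
    """Observed difference-of-K curve with its random-labeling envelope."""

    r_grid: np.ndarray
    observed_diff: np.ndarray
    env_low: np.ndarray
    env_high: np.ndarray
    n_sim: int
    level: float
    departures: tuple[tuple[float, float, str], ...]
    rng_seed: int | None
    correction: str = "translation"
    group: tuple[tuple[str, str], ...] = field(default=())


def default_r_grid(window: Window, n_r: int = 128) -> np.ndarray:
    """128 equally spaced distances from 0 to a quarter of the shorter side."""
    return np.linspace(0.0, min(window.width, window.height) / 4.0, n_r)


def _check_r_grid(r_grid: np.ndarray, window: Window, correction: str) -> np.ndarray:
    r_grid = np.asarray(r_grid, dtype=float)
    if r_grid.ndim != 1 or len(r_grid) < 1:
        raise SpatialError("r_grid must be a 1-D array of distances")
    if np.any(np.diff(r_grid) < 0) or r_grid[0] < 0:
        raise SpatialError("r_grid must be non-negative and increasing")
    short = min(window.width, window.height)
    bounds = {"none": np.inf, "translation": short, "isotropic": short / 2.0}
    bound = bounds[correction]
    if r_grid[-1] >= bound:
        raise SpatialError(
            f"max r = {r_grid[-1]:g} exceeds the validity bound {bound:g} "
            f"of the {correction!r} correction for this window"
        )
    return r_grid


def _isotropic_circle_fraction(xy: np.ndarray, window: Window, r: np.ndarray) -> np.ndarray:
    """Fraction of the circle centred at each point with given radius inside W.

    Inclusion–exclusion over the four sides: each side closer than r removes
    an arc of angle 2·arccos(d/r); arcs of adjacent sides overlap past a
    covered corner by arccos(d1/r) + arccos(d2/r) − π/2.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        dl = xy[:, 0] - window.x0
        dr = window.x0 + window.width - xy[:, 0]
        db = xy[:, 1] - window.y0
        dt = window.y0 + window.height - xy[:, 1]
        r = np.where(r > 0, r, np.nan)  # r == 0: full circle, fraction 1
        beta = {
            s: np.arccos(np.clip(d / r, -1.0, 1.0))
            for s, d in {"l": dl, "r": dr, "b": db, "t": dt}.items()
        }
        exterior = sum(2.0 * b for b in beta.values())
        for s1, s2 in (("l", "b"), ("b", "r"), ("r", "t"), ("t", "l")):
            exterior -= np.maximum(0.0, beta[s1] + beta[s2] - np.pi / 2.0)
        frac = 1.0 - exterior / (2.0 * np.pi)
    return np.where(np.isnan(frac), 1.0, frac)


def _pair_arrays(
    xy: np.ndarray, window: Window, correction: str
) -> tuple[np.ndarray, np.ndarray]:
    """Distances and summed ordered-pair weights for all unordered pairs.

    Returns ``(d, w2)`` over pairs i<j where ``w2`` is w_ij + w_ji (the two
    ordered pairs), so Σ over unordered pairs of w2·1(d ≤ r) equals the
    ordered-pair sum in the estimator.
    """
    n = len(xy)
    iu, ju = np.triu_indices(n, k=1)
    dx = xy[iu, 0] - xy[ju, 0]
    dy = xy[iu, 1] - xy[ju, 1]
    d = np.hypot(dx, dy)
    if correction == "none":
        w2 = np.full(d.shape, 2.0)
    elif correction == "translation":
        # pairs separated by nearly the full window span get infinite weight;
        # such pairs have d >= min(width, height), beyond any valid r grid,
        # so they never enter the counted bins
        denom = (window.width - np.abs(dx)) * (window.height - np.abs(dy))
        with np.errstate(divide="ignore"):
            w2 = 2.0 * window.area / denom
    elif correction == "isotropic":
        fi = _isotropic_circle_fraction(xy[iu], window, d)
        fj = _isotropic_circle_fraction(xy[ju], window, d)
        w2 = 1.0 / fi + 1.0 / fj
    else:
        raise SpatialError(f"unknown correction {correction!r}; choose from {CORRECTIONS}")
    return d, w2


def _k_from_pairs(
    d: np.ndarray, w2: np.ndarray, r_grid: np.ndarray, area: float, n: int
) -> np.ndarray:
    """K̂ on the grid from pair distances/weights via a weighted cumulative histogram."""
    if n < 2:
        raise SpatialError(f"need at least 2 points, got {n}")
    bins = np.searchsorted(r_grid, d, side="left")
    counts = np.bincount(bins, weights=w2, minlength=len(r_grid) + 1)[: len(r_grid)]
    return np.cumsum(counts) * area / (n * (n - 1))


def k_estimate(
    points: np.ndarray,
    window: Window,
    r_grid: np.ndarray,
    correction: str = "translation",
) -> KEstimate:
    """Edge-corrected Ripley's K̂ of one (unmarked) point set."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 2:
        raise SpatialError(f"K estimation needs at least 2 points, got {n}")
    r_grid = _check_r_grid(r_grid, window, correction)
    d, w2 = _pair_arrays(points, window, correction)
    k = _k_from_pairs(d, w2, r_grid, window.area, n)
    return KEstimate(r_grid=r_grid, k_values=k, correction=correction, n_points=n)


def k_difference(
    pattern: PointPattern,
    r_grid: np.ndarray,
    correction: str = "translation",
) -> np.ndarray:
    """K̂_success(r) − K̂_failure(r) on a shared grid and window."""
    ns = int(pattern.marks.sum())
    nf = pattern.n - ns
    if ns < 2 or nf < 2:
        raise SpatialError(
            f"difference of K needs >= 2 points of each mark (got {ns} successes, "
            f"{nf} failures)"
        )
    r_grid = _check_r_grid(r_grid, pattern.window, correction)
    ks = k_estimate(pattern.xy[pattern.marks], pattern.window, r_grid, correction)
    kf = k_estimate(pattern.xy[~pattern.marks], pattern.window, r_grid, correction)
    return ks.k_values - kf.k_values


def _mark_diffs(
    marks_matrix: np.ndarray,
    iu: np.ndarray,
    ju: np.ndarray,
    d: np.ndarray,
    w2: np.ndarray,
    r_grid: np.ndarray,
    area: float,
) -> np.ndarray:
    """Difference-of-K curves for many labelings of one fixed point set.

    ``marks_matrix`` is (n_labelings, n) boolean; pair arrays are shared, so
    each labeling costs one masked weighted histogram per mark class.
    """
    bins = np.searchsorted(r_grid, d, side="left")
    ng = len(r_grid)
    out = np.empty((len(marks_matrix), ng))
    for row, m in enumerate(marks_matrix):
        ms = m[iu] & m[ju]
        mf = ~m[iu] & ~m[ju]
        ns = int(m.sum())
        nf = len(m) - ns
        cs = np.bincount(bins[ms], weights=w2[ms], minlength=ng + 1)[:ng]
        cf = np.bincount(bins[mf], weights=w2[mf], minlength=ng + 1)[:ng]
        ks = np.cumsum(cs) * area / (ns * (ns - 1))
        kf = np.cumsum(cf) * area / (nf * (nf - 1))
        out[row] = ks - kf
    return out


def _envelope_ranks(n_sim: int, level: float) -> tuple[int, int]:
    alpha = (1.0 - level) / 2.0
    lo = int(np.floor(alpha * (n_sim + 1)))
    hi = int(np.ceil((1.0 - alpha) * (n_sim + 1)))
    if lo < 1 or hi > n_sim:
        min_sim = int(np.ceil(1.0 / alpha)) - 1
        raise SpatialError(
            f"n_sim = {n_sim} too small for a level-{level} pointwise envelope; "
            f"need at least {min_sim} simulations"
        )
    return lo, hi


def _departures(
    r_grid: np.ndarray,
    observed: np.ndarray,
    env_low: np.ndarray,
    env_high: np.ndarray,
) -> tuple[tuple[float, float, str], ...]:
    """Maximal contiguous grid intervals where the curve exits the envelope."""
    out: list[tuple[float, float, str]] = []
    for mask, direction in (
        (observed > env_high, "success-clustered"),
        (observed < env_low, "failure-clustered"),
    ):
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in splits:
            out.append((float(r_grid[run[0]]), float(r_grid[run[-1]]), direction))
    return tuple(sorted(out))


def random_labeling_envelope(
    pattern: PointPattern,
    n_sim: int = 1000,
    level: float = 0.95,
    r_grid: np.ndarray | None = None,
    correction: str = "translation",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> EnvelopeResult:
    """Pointwise permutation envelope for the difference-of-K statistic.

    Marks are permuted over the fixed locations ``n_sim`` times, preserving
    the observed success count; envelope bounds at each distance are the
    order statistics ``floor(α(n_sim+1))`` and ``ceil((1−α)(n_sim+1))`` of
    the simulated difference curves (α = (1−level)/2), the exact rank
    convention for n_sim = 1000 at level 0.95.
    """
    ns = int(pattern.marks.sum())
    nf = pattern.n - ns
    if ns < 2 or nf < 2:
        raise SpatialError(
            f"random labeling envelope needs >= 2 points of each mark "
            f"(got {ns} successes, {nf} failures)"
        )
    lo_rank, hi_rank = _envelope_ranks(n_sim, level)
    if r_grid is None:
        r_grid = default_r_grid(pattern.window)
    r_grid = _check_r_grid(r_grid, pattern.window, correction)
    if rng is None:
        rng = np.random.default_rng(seed)

    n = pattern.n
    iu, ju = np.triu_indices(n, k=1)
    d, w2 = _pair_arrays(pattern.xy, pattern.window, correction)

    labelings = np.empty((n_sim + 1, n), dtype=bool)
    labelings[0] = pattern.marks
    for s in range(1, n_sim + 1):
        labelings[s] = rng.permutation(pattern.marks)
    diffs = _mark_diffs(labelings, iu, ju, d, w2, r_grid, pattern.window.area)
    observed, sims = diffs[0], diffs[1:]

    sims_sorted = np.sort(sims, axis=0)
    env_low = sims_sorted[lo_rank - 1]
    env_high = sims_sorted[hi_rank - 1]
    deps = _departures(r_grid, observed, env_low, env_high)
    return EnvelopeResult(
        r_grid=r_grid,
        observed_diff=observed,
        env_low=env_low,
        env_high=env_high,
        n_sim=n_sim,
        level=level,
        departures=deps,
        rng_seed=seed,
        correction=correction,
    )


def run_spatial_analysis(
    records: Sequence[CacheRecord],
    stage: Stage | str,
    n_sim: int = 1000,
    level: float = 0.95,
    correction: str = "translation",
    seed: int | None = None,
    margin: float = 0.0,
    r_grid: np.ndarray | None = None,
    groupby: tuple[str, ...] = ("study_area", "elevation_zone"),
) -> list[EnvelopeResult]:
    """Difference-of-K envelope per group (study area × elevation zone).

    Builds the stage cohort per group (success = pilfered / germinated /
    survived per the stage), forms the marked pattern on the caches' bounding
    box expanded by ``margin``, and runs the envelope.  Groups failing the
    two-points-per-mark precondition are skipped with a log message.  Group
    seeds are split deterministically from ``seed``.
    """
    stage = Stage(stage)
    _envelope_ranks(n_sim, level)  # reject an unusable n_sim/level up front
    cohort = build_cohort(records, stage)
    if cohort.is_empty:
        logger.warning("stage %s: empty cohort; nothing to analyse", stage.value)
        return []
    groups = sorted(cohort.table.groupby(list(groupby)).groups)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(groups))]
    results: list[EnvelopeResult] = []
    for gkey, gseed in zip(groups, child_seeds):
        gkey_t = gkey if isinstance(gkey, tuple) else (gkey,)
        sub = cohort.subset(**dict(zip(groupby, gkey_t)))
        xy = sub.table[["x", "y"]].to_numpy(dtype=float)
        marks = sub.table["success"].to_numpy(dtype=bool)
        label = ", ".join(f"{k}={v}" for k, v in zip(groupby, gkey_t))
        if marks.sum() < 2 or (~marks).sum() < 2:
            logger.warning(
                "stage %s, group (%s): fewer than 2 points of one mark; skipped",
                stage.value, label,
            )
            continue
        window = Window.bounding(xy, margin=margin)
        try:
            env = random_labeling_envelope(
                PointPattern(xy, marks, window),
                n_sim=n_sim, level=level, r_grid=r_grid,
                correction=correction, seed=gseed,
            )
        except SpatialError as e:
            logger.warning("stage %s, group (%s): skipped (%s)", stage.value, label, e)
            continue
        results.append(
            EnvelopeResult(
                **{**env.__dict__, "group": tuple(zip(groupby, map(str, gkey_t)))}
            )
        )
    return results


# ---------------------------------------------------------------------------
# Output


def envelope_frame(result: EnvelopeResult) -> pd.DataFrame:
    return pd.DataFrame({
        "r": result.r_grid,
        "observed_diff": result.observed_diff,
        "env_low": result.env_low,
        "env_high": result.env_high,
    })


def departures_summary(results: Iterable[EnvelopeResult]) -> dict:
    """JSON-ready summary of departure intervals per group."""
    out = []
    for res in results:
        out.append({
            "group": dict(res.group),
            "n_sim": res.n_sim,
            "level": res.level,
            "correction": res.correction,
            "rng_seed": res.rng_seed,
            "departures": [
                {"r_min": lo, "r_max": hi, "direction": direction}
                for lo, hi, direction in res.departures
            ],
        })
    return {"groups": out}


def plot_envelope(result: EnvelopeResult, path: str | Path) -> None:
    """Render the observed curve and envelope to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(
        result.r_grid, result.env_low, result.env_high,
        alpha=0.3, color="gray", label=f"{result.level:.0%} envelope",
    )
    ax.plot(result.r_grid, result.observed_diff, color="C0", label="observed difference")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("distance r (m)")
    ax.set_ylabel(r"$\hat K_{success}(r) - \hat K_{failure}(r)$")
    title = ", ".join(f"{k}={v}" for k, v in result.group) or "difference of K"
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
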