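"""Proportions, odds, and pairwise odds-ratio contrasts for stage cohorts.

The sampling unit is the cache.  For a stage cohort with success proportion
``p`` the odds are ``p / (1 - p)``; the odds ratio between two strata is the
ratio of their odds, equal to ``(a*d) / (b*c)`` on the 2×2 success/failure
table.  A confidence interval containing 1.0 is read as "no difference"
between the two strata — the decision rule used throughout the analysis.

Confidence-interval methods are configurable because the field convention
varies: the default is the Wald interval on the log-odds-ratio scale,
``exp(ln OR ± z·sqrt(1/a + 1/b + 1/c + 1/d))``; a Haldane–Anscombe variant
(+0.5 to every cell) and the exact conditional interval are offered.  Zero
cells always trigger the +0.5 adjustment (flagged on the result).

Proportion intervals default to exact Clopper–Pearson, with Wilson as an
option.  No multiplicity adjustment is applied by default; Bonferroni and
Benjamini–Hochberg adjusted p-values are available as opt-in columns.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .data import ELEVATION_ZONES, MICROSITES, Stage, StageCohort

logger = logging.getLogger("cachescape")

__all__ = [
    "Counts2x2",
    "OddsResult",
    "ProportionResult",
    "PairwiseContrast",
    "odds",
    "odds_ratio",
    "proportion_ci",
    "pairwise_odds_ratios",
    "run_odds_analysis",
    "results_table",
]


def odds(p: float) -> float:
    """Odds ``p / (1 - p)`` of a success proportion.

    ``p == 1`` returns ``inf`` (the infinite-odds signal); values outside
    [0, 1] raise.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion must be in [0, 1], got {p}")
    if p == 1.0:
        return math.inf
    return p / (1.0 - p)


@dataclass(frozen=True)
class Counts2x2:
    """Success/failure counts for two groups: a,b = group 1; c,d = group 2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} negative")
        if self.a + self.b < 1:
            raise ValueError("group 1 is empty (a + b = 0)")
        if self.c + self.d < 1:
            raise ValueError("group 2 is empty (c + d = 0)")

    def swapped(self) -> "Counts2x2":
        return Counts2x2(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class OddsResult:
    odds1: float
    odds2: float
    or_estimate: float
    ci_low: float
    ci_high: float
    level: float
    method: str
    zero_cell_adjusted: bool
    counts: Counts2x2
    p_value: float

    @property
    def contains_one(self) -> bool:
        """True iff the CI includes 1.0, i.e. "no difference" is concluded."""
        return self.ci_low <= 1.0 <= self.ci_high


@dataclass(frozen=True)
class ProportionResult:
    x: int
    n: int
    p_hat: float
    ci_low: float
    ci_high: float
    level: float
    method: str


_OR_METHODS = ("wald", "haldane", "exact")


def odds_ratio(
    counts: Counts2x2, level: float = 0.95, method: str = "wald"
) -> OddsResult:
    """Odds ratio ``(a·d)/(b·c)`` of group 1 relative to group 2, with CI.

    Any zero cell adds 0.5 to all four cells before both the point estimate
    and the interval (flagged via ``zero_cell_adjusted``).  The p-value is
    the two-sided normal test on the log odds ratio.
    """
    if method not in _OR_METHODS:
        raise ValueError(f"unknown CI method {method!r}; choose from {_OR_METHODS}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    adjusted = 0 in (a, b, c, d)
    if adjusted or method == "haldane":
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    est = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = stats.norm.ppf(0.5 + level / 2.0)
    if method == "exact":
        res = _scipy_odds_ratio([[a, b], [c, d]], kind="conditional")
        ci = res.confidence_interval(confidence_level=level)
        ci_low, ci_high = float(ci.low), float(ci.high)
    else:
        ci_low = est * math.exp(-z * se)
        ci_high = est * math.exp(z * se)
    p_value = 2.0 * stats.norm.sf(abs(math.log(est)) / se)
    return OddsResult(
        odds1=aa / bb,
        odds2=cc / dd,
        or_estimate=est,
        ci_low=ci_low,
        ci_high=ci_high,
        level=level,
        method=method,
        zero_cell_adjusted=adjusted,
        counts=counts,
        p_value=p_value,
    )


def proportion_ci(
    x: int, n: int, level: float = 0.95, method: str = "exact"
) -> ProportionResult:
    """Binomial proportion with confidence interval.

    ``method`` is ``"exact"`` (Clopper–Pearson, the default) or
    ``"wilson"``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError(f"x={x} outside [0, {n}]")
    sm_method = {"exact": "beta", "wilson": "wilson"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown proportion CI method {method!r}")
    lo, hi = proportion_confint(x, n, alpha=1.0 - level, method=sm_method)
    return ProportionResult(
        x=x, n=n, p_hat=x / n, ci_low=float(lo), ci_high=float(hi),
        level=level, method=method,
    )


# ---------------------------------------------------------------------------
# Pairwise contrasts

#: canonical orientation of level pairs per stratum factor
_CANONICAL_PAIRS: Mapping[str, tuple[tuple[str, str], ...]] = {
    "microsite": (("rock", "tree"), ("rock", "open"), ("tree", "open")),
    "elevation_zone": (("treeline", "subalpine"),),
}


@dataclass(frozen=True)
class PairwiseContrast:
    """One labeled pairwise odds-ratio contrast, with audit counts."""

    stage: Stage
    factor: str
    level1: str
    level2: str
    within: tuple[tuple[str, str], ...]
    result: OddsResult

    @property
    def label(self) -> str:
        scope = ",".join(f"{k}={v}" for k, v in self.within)
        base = f"{self.factor}:{self.level1}/{self.level2}"
        return f"{base}|{scope}" if scope else base


def _level_pairs(factor: str, present: Sequence[str]) -> list[tuple[str, str]]:
    canon = _CANONICAL_PAIRS.get(factor)
    if canon is not None:
        return [(l1, l2) for l1, l2 in canon if l1 in present and l2 in present]
    # e.g. study areas: keep order of first appearance in the data
    return list(itertools.combinations(present, 2))


def pairwise_odds_ratios(
    cohort: StageCohort,
    factor: str,
    within: Mapping[str, str] | None = None,
    level: float = 0.95,
    method: str = "wald",
) -> list[PairwiseContrast]:
    """All pairwise odds-ratio contrasts between levels of one factor.

    Orientation is canonical: rock/tree, rock/open, tree/open for
    microsites; treeline/subalpine for elevation zones; order of first
    appearance for study areas.  Levels with no eligible caches are skipped
    with a warning.  Returns an empty list (with a warning) if fewer than
    two levels are present.
    """
    within = dict(within or {})
    sub = cohort.subset(**within) if within else cohort
    tab = sub.table
    present = list(dict.fromkeys(tab[factor]))
    if len(present) < 2:
        logger.warning(
            "stage %s, factor %s%s: fewer than 2 levels present; no contrasts",
            cohort.stage.value, factor,
            f" within {within}" if within else "",
        )
        return []
    counts_by_level = {}
    for lev in present:
        mask = tab[factor] == lev
        counts_by_level[lev] = (int(tab.loc[mask, "success"].sum()), int(mask.sum()))
    out: list[PairwiseContrast] = []
    for l1, l2 in _level_pairs(factor, present):
        (x1, n1), (x2, n2) = counts_by_level[l1], counts_by_level[l2]
        if n1 == 0 or n2 == 0:
            logger.warning(
                "stage %s: level %s has no eligible caches; skipping %s/%s",
                cohort.stage.value, l1 if n1 == 0 else l2, l1, l2,
            )
            continue
        counts = Counts2x2(x1, n1 - x1, x2, n2 - x2)
        out.append(
            PairwiseContrast(
                stage=cohort.stage,
                factor=factor,
                level1=l1,
                level2=l2,
                within=tuple(sorted(within.items())),
                result=odds_ratio(counts, level=level, method=method),
            )
        )
    return out


def run_odds_analysis(
    records,
    stages: Iterable[Stage | str] = Stage,
    level: float = 0.95,
    method: str = "wald",
) -> list[PairwiseContrast]:
    """The full contrast battery for each stage cohort.

    Per stage: the study-area contrast; the treeline/subalpine contrast
    within each area; and the microsite contrasts within each area ×
    elevation zone.
    """
    from .data import build_cohort  # local import to avoid cycle at module load

    contrasts: list[PairwiseContrast] = []
    for stage in stages:
        cohort = build_cohort(records, Stage(stage))
        if cohort.is_empty:
            continue
        areas = list(dict.fromkeys(cohort.table["study_area"]))
        contrasts += pairwise_odds_ratios(cohort, "study_area", level=level, method=method)
        for area in areas:
            contrasts += pairwise_odds_ratios(
                cohort, "elevation_zone", within={"study_area": area},
                level=level, method=method,
            )
            for zone in ELEVATION_ZONES:
                if ((cohort.table["study_area"] == area)
                        & (cohort.table["elevation_zone"] == zone)).any():
                    contrasts += pairwise_odds_ratios(
                        cohort, "microsite",
                        within={"study_area": area, "elevation_zone": zone},
                        level=level, method=method,
                    )
    return contrasts


def results_table(
    contrasts: Sequence[PairwiseContrast], adjust: str | None = None
) -> pd.DataFrame:
    """Contrasts as a tidy frame (one row each), with optional adjusted p.

    ``adjust`` is ``None``, ``"bonferroni"`` or ``"bh"`` (Benjamini–
    Hochberg); adjustment adds a ``p_adjusted`` column and never alters the
    estimates.
    """
    rows = []
    for ct in contrasts:
        r = ct.result
        c = r.counts
        rows.append({
            "stage": ct.stage.value,
            "contrast": ct.label,
            "factor": ct.factor,
            "level1": ct.level1,
            "level2": ct.level2,
            "a": c.a, "b": c.b, "c": c.c, "d": c.d,
            "odds_ratio": r.or_estimate,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "level": r.level,
            "method": r.method,
            "zero_cell_adjusted": r.zero_cell_adjusted,
            "contains_one": r.contains_one,
            "p_value": r.p_value,
        })
    df = pd.DataFrame(rows)
    if adjust is not None and not df.empty:
        key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(adjust)
        if key is None:
            raise ValueError(f"unknown adjustment {adjust!r}")
        df["p_adjusted"] = multipletests(df["p_value"].to_numpy(), method=key)[1]
    return df
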