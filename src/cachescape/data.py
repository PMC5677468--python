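"""Cache-fate data model: records, CSV schema, and stage-conditional cohorts.

A *cache* is a small group of seeds buried together at one point location.
Each cache is revisited in two follow-up years; the observed fates (seeds
missing to rodent pilferage, first-year germinants, surviving seedlings,
delayed second-year germinants) define a chain of life stages.  Sample sizes
shrink stage by stage because a cache is only *eligible* for a stage if it
passed through the previous one: germination can only be assessed where at
least one intact seed (or a germinant) remained after pilferage, and seedling
survival only where at least one seed germinated in year 1.

Null vs zero matters throughout: a count field left empty in the CSV means
"not observed" (e.g. the cache was never relocated), while 0 means
"observed, and the count was zero".  Caches never located in year 1
contribute to no cohort at all.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, fields as dc_fields
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("cachescape")

ELEVATION_ZONES = ("subalpine", "treeline")
MICROSITES = ("rock", "tree", "open")

#: canonical spellings accepted for the "no object" microsite
_MICROSITE_ALIASES = {
    "rock": "rock",
    "tree": "tree",
    "open": "open",
    "no object": "open",
    "no_object": "open",
    "none": "open",
}

#: CSV schema, in column order
CACHE_TABLE_COLUMNS = (
    "cache_id",
    "study_area",
    "elevation_zone",
    "microsite",
    "x",
    "y",
    "n_seeds_cached",
    "located_y1",
    "n_missing_y1",
    "n_seed_coats_y1",
    "n_germinants_y1",
    "relocated_y2",
    "n_live_seedlings_y2",
    "n_new_germinants_y2",
)


class CacheDataError(ValueError):
    """Base class for cache-table schema and validation problems."""


class SchemaError(CacheDataError):
    """The CSV header does not match the documented cache-table schema."""


class ValidationError(CacheDataError):
    """One or more rows violate the record invariants."""


class NotLocatedError(CacheDataError):
    """Stage outcomes were requested for a cache never located in year 1."""


class Stage(str, Enum):
    """Life stages analysed at the cache level."""

    PILFERAGE = "pilferage"
    GERMINATION_Y1 = "germination_y1"
    SURVIVAL = "survival"
    GERMINATION_2YR = "germination_2yr"


@dataclass(frozen=True)
class CacheRecord:
    """One cache: design attributes, planar coordinates, and observed fates.

    Coordinates are projected planar meters.  Year-1 observation fields are
    ``None`` when the cache was not located in year 1; year-2 fields are
    ``None`` when the cache was not relocated in year 2.
    """

    cache_id: str
    study_area: str
    elevation_zone: str
    microsite: str
    x: float
    y: float
    n_seeds_cached: int
    located_y1: bool
    n_missing_y1: int | None = None
    n_seed_coats_y1: int | None = None
    n_germinants_y1: int | None = None
    relocated_y2: bool = False
    n_live_seedlings_y2: int | None = None
    n_new_germinants_y2: int | None = None

    def validate(self) -> None:
        """Raise :class:`ValidationError` naming this cache on any violation."""
        errs: list[str] = []
        if self.elevation_zone not in ELEVATION_ZONES:
            errs.append(f"elevation_zone {self.elevation_zone!r} not in {ELEVATION_ZONES}")
        if self.microsite not in MICROSITES:
            errs.append(f"microsite {self.microsite!r} not in {MICROSITES}")
        if self.n_seeds_cached < 1:
            errs.append(f"n_seeds_cached must be >= 1, got {self.n_seeds_cached}")
        if self.located_y1:
            if self.n_missing_y1 is None or self.n_germinants_y1 is None:
                errs.append("located cache must have n_missing_y1 and n_germinants_y1")
            else:
                for name in ("n_missing_y1", "n_seed_coats_y1", "n_germinants_y1"):
                    v = getattr(self, name)
                    if v is not None and v < 0:
                        errs.append(f"{name} negative: {v}")
                if (
                    self.n_missing_y1 is not None
                    and self.n_germinants_y1 is not None
                    and self.n_missing_y1 + self.n_germinants_y1 > self.n_seeds_cached
                ):
                    errs.append(
                        f"n_missing_y1 + n_germinants_y1 = "
                        f"{self.n_missing_y1 + self.n_germinants_y1} exceeds "
                        f"n_seeds_cached = {self.n_seeds_cached}"
                    )
        else:
            for name in (
                "n_missing_y1",
                "n_seed_coats_y1",
                "n_germinants_y1",
                "n_live_seedlings_y2",
                "n_new_germinants_y2",
            ):
                if getattr(self, name) is not None:
                    errs.append(f"{name} must be null for a cache not located in year 1")
        if self.relocated_y2 and self.located_y1:
            if self.n_live_seedlings_y2 is None:
                errs.append("relocated cache must have n_live_seedlings_y2")
        for name in ("n_live_seedlings_y2", "n_new_germinants_y2"):
            v = getattr(self, name)
            if v is not None and v < 0:
                errs.append(f"{name} negative: {v}")
        if (
            self.n_live_seedlings_y2 is not None
            and self.n_germinants_y1 is not None
            and self.n_live_seedlings_y2 > self.n_germinants_y1
        ):
            errs.append(
                f"n_live_seedlings_y2 = {self.n_live_seedlings_y2} exceeds "
                f"n_germinants_y1 = {self.n_germinants_y1}"
            )
        if errs:
            raise ValidationError(f"cache {self.cache_id!r}: " + "; ".join(errs))


@dataclass(frozen=True)
class StageOutcomes:
    """Binary stage outcomes and eligibility flags derived from one record.

    ``survived_y2`` / ``germinated_two_year`` are ``None`` when the cache is
    eligible for the stage but the year-2 outcome was never observed (cache
    not relocated); such caches are dropped from the stage cohort with a
    warning rather than silently counted as failures.
    """

    pilfered: bool
    eligible_germination: bool
    germinated_y1: bool
    eligible_survival: bool
    survived_y2: bool | None
    eligible_two_year: bool
    germinated_two_year: bool | None


def derive_outcomes(record: CacheRecord) -> StageOutcomes:
    """Compute stage eligibility and success flags for a located cache.

    Eligibility rules:

    * pilferage — every located cache;
    * germination — at least one intact seed remained after pilferage,
      *or* a first-year germinant was present (a germinant proves a seed
      survived even if all remaining seeds were later taken);
    * survival — at least one first-year germinant;
    * two-year germination — germination-eligible and relocated in year 2
      (the year-2 denominator excludes caches never revisited).
    """
    if not record.located_y1:
        raise NotLocatedError(
            f"cache {record.cache_id!r} was never located in year 1; "
            "it belongs to no stage cohort"
        )
    assert record.n_missing_y1 is not None and record.n_germinants_y1 is not None
    pilfered = record.n_missing_y1 >= 1
    germinated_y1 = record.n_germinants_y1 >= 1
    seeds_remaining = record.n_seeds_cached - record.n_missing_y1
    eligible_germination = seeds_remaining >= 1 or germinated_y1
    eligible_survival = germinated_y1

    survived_y2: bool | None
    if not eligible_survival:
        survived_y2 = False
    elif record.n_live_seedlings_y2 is None:
        survived_y2 = None
    else:
        survived_y2 = record.n_live_seedlings_y2 >= 1

    eligible_two_year = eligible_germination and record.relocated_y2
    germinated_two_year: bool | None
    if germinated_y1:
        germinated_two_year = True
    elif record.n_new_germinants_y2 is not None:
        germinated_two_year = record.n_new_germinants_y2 >= 1
    else:
        germinated_two_year = None
    return StageOutcomes(
        pilfered=pilfered,
        eligible_germination=eligible_germination,
        germinated_y1=germinated_y1,
        eligible_survival=eligible_survival,
        survived_y2=survived_y2,
        eligible_two_year=eligible_two_year,
        germinated_two_year=germinated_two_year,
    )


#: (eligibility flag, success flag) per stage, read off a StageOutcomes
_STAGE_RULES: Mapping[Stage, tuple[str, str]] = {
    Stage.PILFERAGE: ("_always", "pilfered"),
    Stage.GERMINATION_Y1: ("eligible_germination", "germinated_y1"),
    Stage.SURVIVAL: ("eligible_survival", "survived_y2"),
    Stage.GERMINATION_2YR: ("eligible_two_year", "germinated_two_year"),
}


@dataclass
class StageCohort:
    """The caches eligible for one life stage, with binary success labels.

    ``table`` has one row per eligible cache with columns ``cache_id``,
    ``study_area``, ``elevation_zone``, ``microsite``, ``x``, ``y``,
    ``success``.
    """

    stage: Stage
    table: pd.DataFrame = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def n_success(self) -> int:
        return int(self.table["success"].sum())

    @property
    def is_empty(self) -> bool:
        return self.table.empty

    def subset(self, **strata: str) -> "StageCohort":
        """Restrict to caches matching the given stratum labels."""
        mask = pd.Series(True, index=self.table.index)
        for col, val in strata.items():
            mask &= self.table[col] == val
        return StageCohort(self.stage, self.table[mask].reset_index(drop=True))


def build_cohort(
    records: Sequence[CacheRecord],
    stage: Stage | str,
    where: Callable[[CacheRecord], bool] | None = None,
) -> StageCohort:
    """Assemble the stage-conditional cohort from validated records.

    Caches never located in year 1 are excluded outright.  Caches eligible
    for a year-2 stage whose outcome was not observed (not relocated) are
    dropped with a warning.  An empty cohort is returned as such — callers
    decide whether that is fatal.
    """
    stage = Stage(stage)
    elig_flag, succ_flag = _STAGE_RULES[stage]
    rows = []
    n_unobserved = 0
    for rec in records:
        if not rec.located_y1:
            continue
        if where is not None and not where(rec):
            continue
        out = derive_outcomes(rec)
        eligible = True if elig_flag == "_always" else getattr(out, elig_flag)
        if not eligible:
            continue
        success = getattr(out, succ_flag)
        if success is None:
            n_unobserved += 1
            continue
        rows.append(
            (rec.cache_id, rec.study_area, rec.elevation_zone, rec.microsite,
             rec.x, rec.y, bool(success))
        )
    if n_unobserved:
        logger.warning(
            "stage %s: dropped %d eligible cache(s) with unobserved year-2 outcome",
            stage.value, n_unobserved,
        )
    table = pd.DataFrame(
        rows,
        columns=["cache_id", "study_area", "elevation_zone", "microsite", "x", "y", "success"],
    )
    if table.empty:
        logger.warning("stage %s: empty cohort", stage.value)
    return StageCohort(stage, table)


# ---------------------------------------------------------------------------
# CSV I/O


def _parse_bool(s: str, col: str) -> bool:
    t = s.strip().lower()
    if t in ("true", "1", "yes", "t"):
        return True
    if t in ("false", "0", "no", "f"):
        return False
    raise ValueError(f"column {col!r}: cannot parse boolean from {s!r}")


def _parse_opt_int(s: str, col: str) -> int | None:
    t = s.strip()
    if t == "":
        return None
    try:
        return int(t)
    except ValueError as e:
        raise ValueError(f"column {col!r}: cannot parse integer from {s!r}") from e


def read_cache_table(path: str | Path) -> list[CacheRecord]:
    """Read and validate a cache-fate CSV.

    The header must contain every documented column (case-insensitive,
    order-free).  All rows are parsed before raising, so one error report
    names every offending line.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file") from None
        colmap = {c.strip().lower(): i for i, c in enumerate(header)}
        missing = [c for c in CACHE_TABLE_COLUMNS if c not in colmap]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")

        records: list[CacheRecord] = []
        problems: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(c.strip() == "" for c in row):
                continue
            try:
                get = lambda c: row[colmap[c]]  # noqa: E731
                micro_raw = get("microsite").strip().lower()
                rec = CacheRecord(
                    cache_id=get("cache_id").strip(),
                    study_area=get("study_area").strip(),
                    elevation_zone=get("elevation_zone").strip().lower(),
                    microsite=_MICROSITE_ALIASES.get(micro_raw, micro_raw),
                    x=float(get("x")),
                    y=float(get("y")),
                    n_seeds_cached=int(get("n_seeds_cached")),
                    located_y1=_parse_bool(get("located_y1"), "located_y1"),
                    n_missing_y1=_parse_opt_int(get("n_missing_y1"), "n_missing_y1"),
                    n_seed_coats_y1=_parse_opt_int(get("n_seed_coats_y1"), "n_seed_coats_y1"),
                    n_germinants_y1=_parse_opt_int(get("n_germinants_y1"), "n_germinants_y1"),
                    relocated_y2=_parse_bool(get("relocated_y2"), "relocated_y2"),
                    n_live_seedlings_y2=_parse_opt_int(
                        get("n_live_seedlings_y2"), "n_live_seedlings_y2"
                    ),
                    n_new_germinants_y2=_parse_opt_int(
                        get("n_new_germinants_y2"), "n_new_germinants_y2"
                    ),
                )
                rec.validate()
            except (ValueError, IndexError) as e:
                problems.append(f"line {lineno}: {e}")
                continue
            records.append(rec)
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))
    ids = [r.cache_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"{path}: duplicate cache_id(s): {', '.join(dupes)}")
    return records


def write_cache_table(records: Iterable[CacheRecord], path: str | Path) -> None:
    """Write records to CSV; ``None`` fields become empty cells."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CACHE_TABLE_COLUMNS)
        for rec in records:
            row = []
            for col in CACHE_TABLE_COLUMNS:
                v = getattr(rec, col)
                if v is None:
                    row.append("")
                elif isinstance(v, bool):
                    row.append("true" if v else "false")
                elif isinstance(v, float):
                    row.append(repr(v))  # shortest exact round-trip form
                else:
                    row.append(str(v))
            writer.writerow(row)


def records_to_frame(records: Sequence[CacheRecord]) -> pd.DataFrame:
    """Records as a DataFrame with nullable integer fate columns."""
    df = pd.DataFrame([{f.name: getattr(r, f.name) for f in dc_fields(r)} for r in records])
    for col in df.columns:
        if col.startswith("n_") and col != "n_seeds_cached":
            df[col] = df[col].astype("Int64")
    return df
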