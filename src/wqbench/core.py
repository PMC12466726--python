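"""Core domain types for Welfare Quality (WQ) farm assessments.

The WQ protocol scores a dairy herd on four welfare principles, each on a
0-100 scale:

* ``GF``  -- Good Feeding
* ``GHo`` -- Good Housing
* ``GHe`` -- Good Health
* ``AB``  -- Appropriate Behaviour

A farm is observed over one or more assessment periods; a :class:`FarmPanel`
collects the per-period principle scores of a group of farms (the "norm
group" against which benchmarks are computed).  This module also provides the
WQ rule-based classifier that maps the four principle scores to one of four
ordered welfare categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

#: Canonical order of the four WQ principles.
PRINCIPLES = ("GF", "GHo", "GHe", "AB")


class MissingGroupError(ValueError):
    """A principle group has no criterion scores to aggregate."""


class DegeneratePoolError(ValueError):
    """A record pool is empty or otherwise unusable for extremes."""


class WQCategory(IntEnum):
    """The four ordered WQ welfare categories (worst to best)."""

    NOT_CLASSIFIED = 0
    ACCEPTABLE = 1
    ENHANCED = 2
    EXCELLENT = 3

    @property
    def label(self) -> str:
        return _CATEGORY_LABELS[self]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


_CATEGORY_LABELS = {
    WQCategory.NOT_CLASSIFIED: "Not classified",
    WQCategory.ACCEPTABLE: "Acceptable",
    WQCategory.ENHANCED: "Enhanced",
    WQCategory.EXCELLENT: "Excellent",
}


@dataclass(frozen=True)
class PrincipleScores:
    """The four WQ principle scores of one farm in one period.

    Each score lives on the protocol's 0-100 scale; construction validates
    the range.
    """

    gf: float
    gho: float
    ghe: float
    ab: float

    def __post_init__(self) -> None:
        for name, value in zip(PRINCIPLES, self.as_tuple()):
            if not (0.0 <= float(value) <= 100.0):
                raise ValueError(
                    f"principle {name} score {value!r} outside [0, 100]"
                )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.gf, self.gho, self.ghe, self.ab)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(PRINCIPLES, self.as_tuple()))

    @classmethod
    def from_mapping(cls, values: Mapping[str, float]) -> "PrincipleScores":
        return cls(*(float(values[p]) for p in PRINCIPLES))


@dataclass
class CriterionScores:
    """Criterion-level WQ scores for one farm-period.

    ``entries`` is a list of ``(principle_group, criterion_name, score)``
    tuples; criterion names must be unique within their group.
    """

    farm_id: str
    period_id: str
    entries: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for group, criterion, score in self.entries:
            if group not in PRINCIPLES:
                raise ValueError(f"unknown principle group {group!r}")
            if not (0.0 <= float(score) <= 100.0):
                raise ValueError(
                    f"criterion {criterion!r} score {score!r} outside [0, 100]"
                )
            key = (group, criterion)
            if key in seen:
                raise ValueError(
                    f"duplicate criterion {criterion!r} in group {group}"
                )
            seen.add(key)

    def group(self, principle: str) -> list[float]:
        return [s for g, _, s in self.entries if g == principle]


@dataclass(frozen=True)
class FarmPeriodRecord:
    """One farm's principle scores in one assessment period."""

    farm_id: str
    period_id: str
    scores: PrincipleScores


@dataclass
class FarmPanel:
    """A collection of farm-period records with an explicit period order.

    Period identifiers are opaque; their chronology is defined by
    ``period_order`` (earliest first), defaulting to first-appearance order
    in ``records``.
    """

    records: list[FarmPeriodRecord]
    period_order: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("panel must contain at least one record")
        seen: set[tuple[str, str]] = set()
        appearance: list[str] = []
        for rec in self.records:
            key = (rec.farm_id, rec.period_id)
            if key in seen:
                raise ValueError(f"duplicate record for farm/period {key}")
            seen.add(key)
            if rec.period_id not in appearance:
                appearance.append(rec.period_id)
        if self.period_order is None:
            self.period_order = tuple(appearance)
        else:
            self.period_order = tuple(self.period_order)
            missing = set(appearance) - set(self.period_order)
            if missing:
                raise ValueError(
                    f"period_order does not cover periods {sorted(missing)}"
                )

    @property
    def farm_ids(self) -> tuple[str, ...]:
        out: list[str] = []
        for rec in self.records:
            if rec.farm_id not in out:
                out.append(rec.farm_id)
        return tuple(out)

    def get(self, farm_id: str, period_id: str) -> FarmPeriodRecord:
        for rec in self.records:
            if rec.farm_id == farm_id and rec.period_id == period_id:
                return rec
        raise KeyError(f"no record for farm {farm_id!r}, period {period_id!r}")

    def records_for_period(self, period_id: str) -> list[FarmPeriodRecord]:
        return [r for r in self.records if r.period_id == period_id]

    def previous_period(self, period_id: str) -> str:
        order = list(self.period_order)
        if period_id not in order:
            raise ValueError(f"unknown period {period_id!r}")
        idx = order.index(period_id)
        if idx == 0:
            raise ValueError(f"period {period_id!r} has no predecessor")
        return order[idx - 1]


@dataclass(frozen=True)
class PrincipleExtremes:
    """Per-principle maxima (and optionally minima) over a stated pool.

    These are the normalisation anchors of the benchmark statistics: each
    principle score is expressed relative to the best value attained within
    the pool.
    """

    maxima: PrincipleScores
    minima: PrincipleScores | None = None
    pool: str = ""

    def __post_init__(self) -> None:
        if self.minima is not None:
            for name, lo, hi in zip(
                PRINCIPLES, self.minima.as_tuple(), self.maxima.as_tuple()
            ):
                if lo > hi:
                    raise ValueError(f"principle {name}: min {lo} > max {hi}")


def aggregate_criteria(
    criteria: CriterionScores, mode: str = "mean"
) -> PrincipleScores:
    """Collapse criterion-level scores to the four principle scores.

    ``mode="mean"`` (default) takes the arithmetic mean of each principle
    group, which keeps the result on the 0-100 scale; ``mode="sum"`` adds the
    group and is only valid while the total stays within the scale.

    Raises :class:`MissingGroupError` when a principle has no criteria.
    """
    if mode not in ("mean", "sum"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    values: list[float] = []
    for principle in PRINCIPLES:
        group = criteria.group(principle)
        if not group:
            raise MissingGroupError(
                f"no criterion scores for principle group {principle}"
            )
        total = float(sum(group))
        values.append(total / len(group) if mode == "mean" else total)
    return PrincipleScores(*values)


def classify_wq(scores: PrincipleScores) -> WQCategory:
    """Apply the WQ rule list to four principle scores.

    Rules are evaluated top-down with strict (">") threshold comparisons:

    * Excellent:  all principles above 55 and at least two above 80
    * Enhanced:   all above 20 and at least two above 55
    * Acceptable: all above 10 and at least three above 20
    * otherwise Not classified
    """
    v = scores.as_tuple()

    def n_above(t: float) -> int:
        return sum(1 for x in v if x > t)

    if all(x > 55 for x in v) and n_above(80) >= 2:
        return WQCategory.EXCELLENT
    if all(x > 20 for x in v) and n_above(55) >= 2:
        return WQCategory.ENHANCED
    if all(x > 10 for x in v) and n_above(20) >= 3:
        return WQCategory.ACCEPTABLE
    return WQCategory.NOT_CLASSIFIED


def principle_extremes(
    panel: FarmPanel,
    periods: Iterable[str] | None = None,
    records: Iterable[FarmPeriodRecord] | None = None,
    pool_description: str | None = None,
) -> PrincipleExtremes:
    """Per-principle max and min over a pool of records.

    The pool is either an explicit list of ``records`` or the panel records
    restricted to ``periods`` (all records when both are omitted).
    """
    if records is not None:
        pool = list(records)
        desc = pool_description or f"{len(pool)} explicit records"
    elif periods is not None:
        wanted = set(periods)
        pool = [r for r in panel.records if r.period_id in wanted]
        desc = pool_description or f"periods {sorted(wanted)}"
    else:
        pool = list(panel.records)
        desc = pool_description or "all panel records"
    if not pool:
        raise DegeneratePoolError("extremes pool is empty after filtering")
    columns = list(zip(*(r.scores.as_tuple() for r in pool)))
    maxima = PrincipleScores(*(max(col) for col in columns))
    minima = PrincipleScores(*(min(col) for col in columns))
    return PrincipleExtremes(maxima=maxima, minima=minima, pool=desc)
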