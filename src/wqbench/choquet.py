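"""Non-additive aggregation of benchmark values with the discrete Choquet integral.

A fuzzy measure (capacity) assigns an importance in [0, 1] to every subset of
the evaluation dimensions; non-additivity lets combinations of benchmarks be
worth more (synergy) or less (redundancy) than the sum of their parts.  The
discrete Choquet integral of a profile ``x`` under measure ``mu`` is

    C_mu(x) = sum_i (x_(i) - x_(i-1)) * mu(A_(i)),   x_(0) = 0,

with the values sorted ascending and ``A_(i)`` the set of dimensions whose
value is at least ``x_(i)``.  The result (in [0, 1] for a normalised measure)
is scaled to 0-100 and classified into the four-level welfare scale by
splitting the 100 points into four equal bands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .core import WQCategory

#: Canonical benchmark dimensions, in a fixed display order.
CANONICAL_DIMENSIONS = ("WQ", "Past", "Best", "Competitor")


class MeasureError(ValueError):
    """A fuzzy measure violates a boundary axiom or is incomplete."""


def _subset_key(subset: Iterable[str]) -> str:
    return "|".join(sorted(subset))


@dataclass
class ValidationReport:
    """Outcome of fuzzy-measure validation.

    Boundary violations are errors; monotonicity violations (a superset
    measuring less than one of its subsets) are reported as warnings because
    elicited capacities may legitimately encode such trade-offs.
    """

    errors: list[str] = field(default_factory=list)
    monotonicity_violations: list[tuple[frozenset, frozenset, float, float]] = field(
        default_factory=list
    )

    @property
    def ok(self) -> bool:
        return not self.errors

    @property
    def warnings(self) -> list[str]:
        return [
            f"monotonicity: mu({_subset_key(b)})={mb:g} < mu({_subset_key(a)})={ma:g} "
            f"although {_subset_key(a)} is a subset of {_subset_key(b)}"
            for a, b, ma, mb in self.monotonicity_violations
        ]


class FuzzyMeasure:
    """A set function over subsets of the benchmark dimensions.

    ``mu(empty) = 0`` and ``mu(full) = 1`` are filled in by default when not
    supplied (with provenance ``"defaulted"``); all values must lie in
    [0, 1].  Monotonicity is checked and reported, not enforced.
    """

    def __init__(
        self,
        dimensions: Iterable[str],
        mu: Mapping[frozenset | tuple | str, float],
        provenance: Mapping[frozenset, str] | None = None,
    ) -> None:
        self.dimensions: tuple[str, ...] = tuple(dimensions)
        if len(set(self.dimensions)) != len(self.dimensions):
            raise MeasureError("dimension names must be unique")
        if len(self.dimensions) < 2:
            raise MeasureError("need at least two dimensions")
        universe = frozenset(self.dimensions)
        self._mu: dict[frozenset, float] = {}
        self.provenance: dict[frozenset, str] = {}
        for subset, value in mu.items():
            key = self._normalise(subset)
            if not key <= universe:
                raise MeasureError(
                    f"subset {sorted(key)} outside dimensions {self.dimensions}"
                )
            self._mu[key] = float(value)
            self.provenance[key] = (provenance or {}).get(key, "supplied")
        for boundary, value in ((frozenset(), 0.0), (universe, 1.0)):
            if boundary not in self._mu:
                self._mu[boundary] = value
                self.provenance[boundary] = "defaulted"
        report = self.validate()
        if not report.ok:
            raise MeasureError("; ".join(report.errors))

    def _normalise(self, subset: frozenset | tuple | str) -> frozenset:
        if isinstance(subset, str):
            return frozenset(p for p in subset.split("|") if p)
        return frozenset(subset)

    def __getitem__(self, subset: Iterable[str] | str) -> float:
        key = self._normalise(subset)  # type: ignore[arg-type]
        try:
            return self._mu[key]
        except KeyError:
            raise MeasureError(
                f"fuzzy measure has no value for subset {sorted(key)}"
            ) from None

    def subsets(self) -> list[frozenset]:
        return sorted(self._mu, key=lambda s: (len(s), _subset_key(s)))

    def validate(self) -> ValidationReport:
        report = ValidationReport()
        empty = frozenset()
        if self._mu.get(empty, 0.0) != 0.0:
            report.errors.append(f"mu(empty set) must be 0, got {self._mu[empty]:g}")
        for subset, value in self._mu.items():
            if not (0.0 <= value <= 1.0):
                report.errors.append(
                    f"mu({_subset_key(subset)})={value:g} outside [0, 1]"
                )
        items = self.subsets()
        for a in items:
            for b in items:
                if a < b and self._mu[a] > self._mu[b]:
                    report.monotonicity_violations.append(
                        (a, b, self._mu[a], self._mu[b])
                    )
        return report

    @classmethod
    def additive(
        cls, weights: Mapping[str, float], dimensions: Iterable[str] | None = None
    ) -> "FuzzyMeasure":
        """Additive measure from per-dimension weights (sums over subsets)."""
        dims = tuple(dimensions) if dimensions is not None else tuple(weights)
        mu: dict[frozenset, float] = {}
        from itertools import combinations

        for r in range(len(dims) + 1):
            for combo in combinations(dims, r):
                # clip away floating-point overshoot of normalised weights
                mu[frozenset(combo)] = min(sum(weights[d] for d in combo), 1.0)
        return cls(dims, mu)

    # -- JSON round-trip -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "dimensions": list(self.dimensions),
            "mu": {_subset_key(s): self._mu[s] for s in self.subsets()},
            "provenance": {_subset_key(s): self.provenance[s] for s in self.subsets()},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, data: dict) -> "FuzzyMeasure":
        prov = {
            frozenset(k.split("|")) if k else frozenset(): v
            for k, v in data.get("provenance", {}).items()
        }
        return cls(data["dimensions"], data["mu"], provenance=prov)

    @classmethod
    def from_json(cls, text: str) -> "FuzzyMeasure":
        return cls.from_dict(json.loads(text))


def _default_measure() -> FuzzyMeasure:
    # Expert-elicited capacity over the four benchmark dimensions (centroid
    # defuzzified panel consensus).  The empty and full sets were never
    # elicited and are defaulted to 0 and 1.  The table is deliberately
    # non-monotone in places (e.g. mu{Past,WQ} < mu{WQ}): validation reports
    # this as a warning and aggregation proceeds.
    mu = {
        "Competitor": 0.15,
        "Best": 0.25,
        "Past": 0.25,
        "WQ": 0.35,
        "Best|Competitor": 0.25,
        "Competitor|Past": 0.25,
        "Competitor|WQ": 0.35,
        "Best|Past": 0.25,
        "Best|WQ": 0.35,
        "Past|WQ": 0.25,
        "Best|Competitor|Past": 0.35,
        "Best|Competitor|WQ": 0.45,
        "Competitor|Past|WQ": 0.45,
        "Best|Past|WQ": 0.25,
    }
    prov = {frozenset(k.split("|")): "elicited" for k in mu}
    return FuzzyMeasure(CANONICAL_DIMENSIONS, mu, provenance=prov)


#: The expert-elicited capacity shipped as the package default.
DEFAULT_MEASURE = _default_measure()


def validate_measure(measure: FuzzyMeasure) -> ValidationReport:
    """Boundary (error) and monotonicity (warning) checks on a measure."""
    return measure.validate()


@dataclass(frozen=True)
class ChoquetStep:
    """One increment of the sorted-chain evaluation, kept for reporting."""

    dimension: str
    value: float
    increment: float
    coalition: frozenset
    measure: float


@dataclass(frozen=True)
class AggregateResult:
    """Choquet value, its 0-100 scaling, final category and trace.

    ``category`` is ``None`` when the scaled value falls outside the 0-100
    classification range (possible only for profiles beyond [0, 1]).
    """

    choquet: float
    scaled: float
    category: WQCategory | None
    trace: tuple[ChoquetStep, ...]


def classify_final(scaled: float) -> WQCategory:
    """Four equal bands over the 0-100 aggregate score.

    Bands are half-open at the lower edge: (25, 50] is Acceptable, (50, 75]
    Enhanced, (75, 100] Excellent; [0, 25] is Not classified.
    """
    if not (-1e-9 <= scaled <= 100.0 + 1e-9):
        raise ValueError(f"aggregate score {scaled} outside [0, 100]")
    if scaled <= 25.0:
        return WQCategory.NOT_CLASSIFIED
    if scaled <= 50.0:
        return WQCategory.ACCEPTABLE
    if scaled <= 75.0:
        return WQCategory.ENHANCED
    return WQCategory.EXCELLENT


def choquet_integral(
    profile: Mapping[str, float], measure: FuzzyMeasure
) -> AggregateResult:
    """Discrete Choquet integral of a complete benchmark profile.

    Values are sorted ascending (stable, keyed secondarily by dimension name
    so tied traces are deterministic); ties contribute zero-width increments,
    making the tie order irrelevant to the value.
    """
    missing = [d for d in measure.dimensions if d not in profile]
    if missing:
        raise ValueError(f"profile missing dimensions {missing}")
    extra = [d for d in profile if d not in measure.dimensions]
    if extra:
        raise ValueError(f"profile has unknown dimensions {extra}")
    negative = {d: v for d, v in profile.items() if v < 0.0}
    if negative:
        raise ValueError(f"profile values must be non-negative, got {negative}")
    ordered = sorted(profile.items(), key=lambda kv: (kv[1], kv[0]))
    total = 0.0
    prev = 0.0
    steps: list[ChoquetStep] = []
    for i, (dim, value) in enumerate(ordered):
        coalition = frozenset(d for d, _ in ordered[i:])
        mu = measure[coalition]
        increment = value - prev
        total += increment * mu
        steps.append(
            ChoquetStep(
                dimension=dim,
                value=value,
                increment=increment,
                coalition=coalition,
                measure=mu,
            )
        )
        prev = value
    scaled = total * 100.0
    category = classify_final(scaled) if scaled <= 100.0 + 1e-9 else None
    return AggregateResult(
        choquet=total,
        scaled=scaled,
        category=category,
        trace=tuple(steps),
    )
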