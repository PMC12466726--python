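"""Fuzzy category systems: triangular/shoulder membership and defuzzification.

Each benchmark value (in percent) is evaluated against an ordered system of
five expert-defined fuzzy categories -- critical, not acceptable, acceptable,
good, excellent.  Interior categories are triangles ``(a, b, c)``; the two
extreme categories are shoulders (clamped ramps saturating at 1).  The
winning category (maximum membership, ties broken toward the worse label) is
collapsed to the four-level WQ scale and mapped to a fixed defuzzified
constant in [0, 1] for aggregation.

The three preset systems shipped here carry the thresholds elicited from the
expert panel for the past, best and competitor benchmarks; custom systems can
be loaded from JSON with the same validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Union

from .core import WQCategory

#: Five-level expert labels, worst to best.
FIVE_LEVELS = ("critical", "not_acceptable", "acceptable", "good", "excellent")


class UncoveredDomainError(ValueError):
    """No category has positive membership at the evaluated point."""


@dataclass(frozen=True)
class TriangularMF:
    """Triangle with feet ``a``/``c`` and peak ``b`` (membership 1).

    Membership is ``max(min((x-a)/(b-a), (c-x)/(c-b)), 0)``.  A degenerate
    leg (``a == b`` or ``b == c``) is a vertical edge: membership jumps to 1
    exactly at ``b`` on that side.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c):
            raise ValueError(
                f"triangle parameters must satisfy a <= b <= c, "
                f"got ({self.a}, {self.b}, {self.c})"
            )

    def __call__(self, x: float) -> float:
        if self.a < self.b:
            left = (x - self.a) / (self.b - self.a)
        else:
            left = 1.0 if x >= self.b else 0.0
        if self.b < self.c:
            right = (self.c - x) / (self.c - self.b)
        else:
            right = 1.0 if x <= self.b else 0.0
        return max(min(left, right), 0.0)


@dataclass(frozen=True)
class ShoulderMF:
    """Open (shoulder) fuzzy set: a ramp clamped to [0, 1].

    ``side="left"``: membership 1 for ``x <= plateau_edge``, falling linearly
    to 0 at ``zero_edge``.  ``side="right"``: membership 0 for
    ``x <= zero_edge``, rising linearly to 1 at ``plateau_edge`` and staying
    there.
    """

    side: str
    plateau_edge: float
    zero_edge: float

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"shoulder side must be 'left' or 'right', got {self.side!r}")
        if self.side == "left" and not self.plateau_edge < self.zero_edge:
            raise ValueError("left shoulder requires plateau_edge < zero_edge")
        if self.side == "right" and not self.zero_edge < self.plateau_edge:
            raise ValueError("right shoulder requires zero_edge < plateau_edge")

    def __call__(self, x: float) -> float:
        if self.side == "left":
            ramp = (self.zero_edge - x) / (self.zero_edge - self.plateau_edge)
        else:
            ramp = (x - self.zero_edge) / (self.plateau_edge - self.zero_edge)
        return max(min(ramp, 1.0), 0.0)


MembershipFunction = Union[TriangularMF, ShoulderMF]


@dataclass(frozen=True)
class MembershipVector:
    """Per-label membership degrees of one crisp value."""

    degrees: dict[str, float]
    at: float

    def __getitem__(self, label: str) -> float:
        return self.degrees[label]

    def items(self):
        return self.degrees.items()


@dataclass(frozen=True)
class CategorySystem:
    """An ordered family of labelled fuzzy sets over a percent-valued domain.

    Labels must be a contiguous-order subset of :data:`FIVE_LEVELS` (worst to
    best) and, on a dense grid over the configured span, at least one
    category must be active at every point.
    """

    name: str
    categories: tuple[tuple[str, MembershipFunction], ...]

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.categories]
        order = [FIVE_LEVELS.index(lab) for lab in labels]  # raises on unknown
        if sorted(order) != order or len(set(order)) != len(order):
            raise ValueError(
                f"category labels must be strictly ordered worst to best, got {labels}"
            )
        lo, hi = self.span()
        n = 513
        for i in range(n):
            x = lo + (hi - lo) * i / (n - 1)
            if all(mf(x) == 0.0 for _, mf in self.categories):
                raise ValueError(
                    f"category system {self.name!r} leaves domain point {x:g} uncovered"
                )

    def span(self) -> tuple[float, float]:
        """Smallest interval containing all feet and edges."""
        points: list[float] = []
        for _, mf in self.categories:
            if isinstance(mf, TriangularMF):
                points += [mf.a, mf.c]
            else:
                points += [mf.plateau_edge, mf.zero_edge]
        return (min(points), max(points))

    def evaluate(self, x: float) -> MembershipVector:
        return MembershipVector(
            degrees={label: mf(float(x)) for label, mf in self.categories},
            at=float(x),
        )

    # -- JSON round-trip -------------------------------------------------

    def to_dict(self) -> dict:
        cats = []
        for label, mf in self.categories:
            if isinstance(mf, TriangularMF):
                cats.append(
                    {"label": label, "kind": "triangle", "a": mf.a, "b": mf.b, "c": mf.c}
                )
            else:
                cats.append(
                    {
                        "label": label,
                        "kind": f"{mf.side}_shoulder",
                        "plateau_edge": mf.plateau_edge,
                        "zero_edge": mf.zero_edge,
                    }
                )
        return {"name": self.name, "categories": cats}

    @classmethod
    def from_dict(cls, data: dict) -> "CategorySystem":
        cats: list[tuple[str, MembershipFunction]] = []
        for entry in data["categories"]:
            kind = entry["kind"]
            if kind == "triangle":
                mf: MembershipFunction = TriangularMF(entry["a"], entry["b"], entry["c"])
            elif kind in ("left_shoulder", "right_shoulder"):
                mf = ShoulderMF(
                    side=kind.split("_")[0],
                    plateau_edge=entry["plateau_edge"],
                    zero_edge=entry["zero_edge"],
                )
            else:
                raise ValueError(f"unknown membership kind {kind!r}")
            cats.append((entry["label"], mf))
        return cls(name=data["name"], categories=tuple(cats))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CategorySystem":
        return cls.from_dict(json.loads(text))


def triangular_membership(x: float, mf: TriangularMF) -> float:
    """Functional form of :class:`TriangularMF` evaluation."""
    return mf(x)


# ---------------------------------------------------------------------------
# Preset systems (expert-elicited thresholds, in percent of each benchmark)
# ---------------------------------------------------------------------------

_PRESETS = {
    # past-period ratio, percent: 107 means 7% above the t-1 profile
    "past": CategorySystem(
        name="past",
        categories=(
            ("critical", ShoulderMF("left", 85.0, 95.0)),
            ("not_acceptable", TriangularMF(85.0, 95.0, 102.5)),
            ("acceptable", TriangularMF(95.0, 102.5, 110.0)),
            ("good", TriangularMF(102.5, 110.0, 115.0)),
            ("excellent", ShoulderMF("right", 115.0, 110.0)),
        ),
    ),
    # best-in-sample profile, percent of the ceiling 4
    "best": CategorySystem(
        name="best",
        categories=(
            ("critical", ShoulderMF("left", 20.0, 40.0)),
            ("not_acceptable", TriangularMF(20.0, 40.0, 50.0)),
            ("acceptable", TriangularMF(40.0, 50.0, 70.0)),
            ("good", TriangularMF(50.0, 70.0, 90.0)),
            ("excellent", ShoulderMF("right", 80.0, 70.0)),
        ),
    ),
    # competitor sigma, percent: negative = worse than the competitor
    "competitor": CategorySystem(
        name="competitor",
        categories=(
            ("critical", ShoulderMF("left", -50.0, -30.0)),
            ("not_acceptable", TriangularMF(-50.0, -30.0, -10.0)),
            ("acceptable", TriangularMF(-30.0, -10.0, 10.0)),
            ("good", TriangularMF(-10.0, 10.0, 30.0)),
            ("excellent", ShoulderMF("right", 30.0, 10.0)),
        ),
    ),
}


def build_preset_system(which: str) -> CategorySystem:
    """Return one of the shipped category systems: past, best, competitor."""
    try:
        return _PRESETS[which]
    except KeyError:
        raise ValueError(
            f"unknown preset {which!r}; expected one of {sorted(_PRESETS)}"
        ) from None


def evaluate_memberships(system: CategorySystem, x: float) -> MembershipVector:
    """Membership degree of ``x`` in every category of ``system``."""
    return system.evaluate(x)


def assign_category(mv: MembershipVector) -> str:
    """Winning five-level label: maximum membership, ties to the worse label.

    The conservative tie-break suits certification use: an ambiguous value is
    never promoted.  Raises :class:`UncoveredDomainError` on an all-zero
    vector.
    """
    best_label: str | None = None
    best_degree = 0.0
    for label in FIVE_LEVELS:
        if label not in mv.degrees:
            continue
        degree = mv.degrees[label]
        if degree > best_degree:  # strict: first (worst) max wins
            best_label, best_degree = label, degree
    if best_label is None:
        raise UncoveredDomainError(
            f"value {mv.at:g} has zero membership in every category"
        )
    return best_label


_COLLAPSE = {
    "critical": WQCategory.NOT_CLASSIFIED,
    "not_acceptable": WQCategory.NOT_CLASSIFIED,
    "acceptable": WQCategory.ACCEPTABLE,
    "good": WQCategory.ENHANCED,
    "excellent": WQCategory.EXCELLENT,
}

#: Fixed defuzzified constant for each four-level category.
DEFUZZIFIED_VALUES = {
    WQCategory.NOT_CLASSIFIED: 0.25,
    WQCategory.ACCEPTABLE: 0.50,
    WQCategory.ENHANCED: 0.75,
    WQCategory.EXCELLENT: 1.00,
}


def collapse_to_four(label: str) -> WQCategory:
    """Merge the two worst five-level labels into "Not classified"."""
    try:
        return _COLLAPSE[label]
    except KeyError:
        raise ValueError(f"unknown five-level label {label!r}") from None


def defuzzify_category(category: WQCategory) -> float:
    """Category-to-constant map used before aggregation."""
    return DEFUZZIFIED_VALUES[WQCategory(category)]


@dataclass(frozen=True)
class FuzzyResult:
    """Full fuzzification trace of one benchmark value."""

    memberships: MembershipVector
    five_level: str
    four_level: WQCategory
    defuzzified: float


def fuzzify(system: CategorySystem, x: float) -> FuzzyResult:
    """Evaluate, assign, collapse and defuzzify a crisp percent value."""
    mv = system.evaluate(x)
    label = assign_category(mv)
    four = collapse_to_four(label)
    return FuzzyResult(
        memberships=mv,
        five_level=label,
        four_level=four,
        defuzzified=defuzzify_category(four),
    )
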