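"""Expert-panel machinery: linguistic scales, consensus triangles, measures.

Experts express category thresholds as "-from"/"-to" percent pairs ``(a, c)``
and importance judgements on a five-point linguistic scale whose labels map
to triangular fuzzy numbers on [0, 0.5].  Panel consensus is formed by
parameter-wise averaging of triangles; crisp values are recovered with the
centroid of a triangle, ``(a + b + c) / 3``.  Assembling the per-subset
centroids over all dimension combinations yields a fuzzy measure for the
Choquet aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .choquet import FuzzyMeasure
from .fuzzy import TriangularMF


class MissingSubsetError(ValueError):
    """A dimension combination has no importance responses."""


#: Five-point importance scale.  Only the lower three triangles were stated
#: by the panel protocol; the upper two continue the evident arithmetic
#: progression on [0, 0.5] and can be overridden.
DEFAULT_IMPORTANCE_SCALE: dict[str, TriangularMF] = {
    "not_at_all_important": TriangularMF(0.00, 0.05, 0.10),
    "slightly_important": TriangularMF(0.10, 0.15, 0.20),
    "moderately_important": TriangularMF(0.20, 0.25, 0.30),
    "important": TriangularMF(0.30, 0.35, 0.40),
    "extremely_important": TriangularMF(0.40, 0.45, 0.50),
}

#: Ordinal codes used when the scale is treated as 1-5 ratings.
IMPORTANCE_CODES = {label: i + 1 for i, label in enumerate(DEFAULT_IMPORTANCE_SCALE)}


@dataclass(frozen=True)
class ExpertThresholdResponse:
    """One expert's (a, c) percent interval for one category."""

    expert_id: str
    category: str
    a: float
    c: float

    def __post_init__(self) -> None:
        if self.a > self.c:
            raise ValueError(
                f"expert {self.expert_id}: a={self.a} exceeds c={self.c}"
            )


@dataclass(frozen=True)
class ExpertImportanceResponse:
    """One expert's linguistic importance rating for a dimension subset."""

    expert_id: str
    subset: frozenset
    label: str

    def __post_init__(self) -> None:
        if not self.subset:
            raise ValueError("importance response subset must be non-empty")


@dataclass
class ExpertPanel:
    """Roster of experts with their threshold and/or importance responses."""

    experts: list[str]
    threshold_responses: list[ExpertThresholdResponse] = field(default_factory=list)
    importance_responses: list[ExpertImportanceResponse] = field(default_factory=list)

    def __post_init__(self) -> None:
        roster = set(self.experts)
        for resp in [*self.threshold_responses, *self.importance_responses]:
            if resp.expert_id not in roster:
                raise ValueError(f"response from unknown expert {resp.expert_id!r}")

    def importance_for(self, subset: Iterable[str]) -> list[ExpertImportanceResponse]:
        key = frozenset(subset)
        return [r for r in self.importance_responses if r.subset == key]


def average_triangles(triangles: Sequence[TriangularMF]) -> TriangularMF:
    """Parameter-wise arithmetic mean of triangular fuzzy numbers."""
    if not triangles:
        raise ValueError("cannot average an empty list of triangles")
    n = len(triangles)
    return TriangularMF(
        a=sum(t.a for t in triangles) / n,
        b=sum(t.b for t in triangles) / n,
        c=sum(t.c for t in triangles) / n,
    )


def centroid_defuzzify(mf: TriangularMF) -> float:
    """Centroid (centre of gravity) of a triangular fuzzy number.

    For a triangle this is simply ``(a + b + c) / 3``.
    """
    return (mf.a + mf.b + mf.c) / 3.0


def build_threshold_category(
    responses: Sequence[ExpertThresholdResponse],
) -> TriangularMF:
    """Consensus triangle for one category from expert (a, c) intervals.

    Feet are the arithmetic means of the experts' a's and c's; the peak is
    their midpoint.  Averaging before taking the midpoint is equivalent to
    the reverse order (both maps are affine) but is adopted as the canonical
    form.  A zero-width consensus yields a degenerate spike, accepted with a
    warning.
    """
    if not responses:
        raise ValueError("no threshold responses for category")
    a = sum(r.a for r in responses) / len(responses)
    c = sum(r.c for r in responses) / len(responses)
    if a > c:
        raise ValueError(f"mean a={a} exceeds mean c={c}")
    if a == c:
        warnings.warn(
            f"zero-width consensus at {a}: degenerate spike membership",
            stacklevel=2,
        )
    return TriangularMF(a=a, b=(a + c) / 2.0, c=c)


def build_fuzzy_measure(
    panel: ExpertPanel,
    dims: Sequence[str],
    scale: Mapping[str, TriangularMF] | None = None,
) -> FuzzyMeasure:
    """Assemble a fuzzy measure from panel importance responses.

    Every non-empty proper subset of ``dims`` must have at least one
    response; each subset's responses are mapped to scale triangles,
    averaged, and centroid-defuzzified.  The empty and full sets are
    defaulted (0 and 1) with provenance ``"defaulted"``.
    """
    scale = dict(scale) if scale is not None else DEFAULT_IMPORTANCE_SCALE
    from itertools import combinations

    mu: dict[frozenset, float] = {}
    provenance: dict[frozenset, str] = {}
    for r in range(1, len(dims)):
        for combo in combinations(dims, r):
            subset = frozenset(combo)
            responses = panel.importance_for(subset)
            if not responses:
                raise MissingSubsetError(
                    f"no importance responses for subset {sorted(subset)}"
                )
            triangles = []
            for resp in responses:
                if resp.label not in scale:
                    raise ValueError(
                        f"label {resp.label!r} not on the importance scale"
                    )
                triangles.append(scale[resp.label])
            mu[subset] = centroid_defuzzify(average_triangles(triangles))
            provenance[subset] = "elicited"
    return FuzzyMeasure(dims, mu, provenance=provenance)
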