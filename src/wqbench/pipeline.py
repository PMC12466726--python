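"""End-to-end evaluation: panel in, aggregated welfare index out.

Composes the stages: WQ rule classification at period t; past, best and
competitor benchmark statistics; fuzzification against the category systems;
collapse and defuzzification; Choquet aggregation and final classification.
The full trace of every stage is retained in an :class:`EvaluationReport`.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import benchmarks as bm
from .choquet import (
    DEFAULT_MEASURE,
    AggregateResult,
    FuzzyMeasure,
    choquet_integral,
)
from .core import (
    FarmPanel,
    PrincipleExtremes,
    PrincipleScores,
    WQCategory,
    classify_wq,
    principle_extremes,
)
from .fuzzy import CategorySystem, build_preset_system, defuzzify_category, fuzzify


class PipelineError(RuntimeError):
    """An evaluation stage failed; ``stage`` names the benchmark dimension."""

    def __init__(self, stage: str, message: str) -> None:
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class DimensionEvaluation:
    """One benchmark dimension's journey from raw value to defuzzified input.

    ``raw_value`` is the benchmark statistic on its natural scale (ratio,
    profile sum or sigma; ``None`` for the WQ rule dimension), ``percent``
    the value fed to the fuzzy system.
    """

    dimension: str
    raw_value: float | None
    percent: float | None
    memberships: dict[str, float] | None
    five_level: str | None
    four_level: WQCategory
    defuzzified: float


@dataclass(frozen=True)
class EvaluationReport:
    """Complete, internally consistent record of one farm evaluation."""

    farm_id: str
    period_t: str
    period_tm1: str
    competitor_id: str | None
    dimensions: dict[str, DimensionEvaluation]
    profile: dict[str, float]
    aggregate: AggregateResult
    provenance: dict[str, str]


def _fuzzy_dimension(
    name: str, raw: float, percent: float, system: CategorySystem
) -> DimensionEvaluation:
    try:
        res = fuzzify(system, percent)
    except ValueError as exc:  # pragma: no cover - defensive
        raise PipelineError(name, str(exc)) from exc
    return DimensionEvaluation(
        dimension=name,
        raw_value=raw,
        percent=percent,
        memberships=dict(res.memberships.degrees),
        five_level=res.five_level,
        four_level=res.four_level,
        defuzzified=res.defuzzified,
    )


def run_full_pipeline(
    panel: FarmPanel,
    farm_id: str,
    period_t: str,
    period_tm1: str | None = None,
    competitor_id: str | None = None,
    *,
    measure: FuzzyMeasure | None = None,
    systems: dict[str, CategorySystem] | None = None,
    maxima_t: PrincipleExtremes | None = None,
    maxima_tm1: PrincipleExtremes | None = None,
    competitor_scores: PrincipleScores | None = None,
    pool_min_scores: PrincipleScores | None = None,
) -> EvaluationReport:
    """Evaluate one farm against all four benchmark dimensions.

    Defaults derive everything from the panel: per-period maxima over that
    period's records, the competitor's scores from its period-t record, and
    the competitor pool range from the period-t per-principle extremes.  Each
    default can be overridden explicitly (e.g. when the min/max pool should
    span several periods or include records outside the panel).
    """
    measure = measure if measure is not None else DEFAULT_MEASURE
    if systems is None:
        systems = {k: build_preset_system(k) for k in ("past", "best", "competitor")}

    try:
        record_t = panel.get(farm_id, period_t)
    except KeyError as exc:
        raise PipelineError("WQ", str(exc)) from exc

    # WQ rule dimension
    wq_category = classify_wq(record_t.scores)
    wq_dim = DimensionEvaluation(
        dimension="WQ",
        raw_value=None,
        percent=None,
        memberships=None,
        five_level=None,
        four_level=wq_category,
        defuzzified=defuzzify_category(wq_category),
    )

    # Past dimension
    if period_tm1 is None:
        try:
            period_tm1 = panel.previous_period(period_t)
        except ValueError as exc:
            raise PipelineError("Past", str(exc)) from exc
    try:
        record_tm1 = panel.get(farm_id, period_tm1)
    except KeyError as exc:
        raise PipelineError("Past", str(exc)) from exc
    if maxima_t is None:
        maxima_t = principle_extremes(panel, periods=[period_t])
    if maxima_tm1 is None:
        maxima_tm1 = principle_extremes(panel, periods=[period_tm1])
    try:
        ratio = bm.past_ratio(record_t, record_tm1, maxima_t, maxima_tm1)
    except (ValueError, ZeroDivisionError) as exc:
        raise PipelineError("Past", str(exc)) from exc
    past_dim = _fuzzy_dimension("Past", ratio.value, ratio.percent, systems["past"])

    # Best dimension
    try:
        profile_t = bm.normalized_profile(record_t, maxima_t)
        best_percent = bm.best_ratio_percent(profile_t)
    except (ValueError, ZeroDivisionError) as exc:
        raise PipelineError("Best", str(exc)) from exc
    best_dim = _fuzzy_dimension("Best", profile_t.value, best_percent, systems["best"])

    # Competitor dimension
    if competitor_scores is None:
        if competitor_id is None:
            raise PipelineError(
                "Competitor", "competitor_id or competitor_scores required"
            )
        try:
            competitor_scores = panel.get(competitor_id, period_t).scores
        except KeyError as exc:
            raise PipelineError("Competitor", str(exc)) from exc
    if pool_min_scores is None:
        if maxima_t.minima is None:
            raise PipelineError("Competitor", "maxima_t lacks pool minima")
        pool_min_scores = maxima_t.minima
    try:
        pool_max_profile = bm.normalized_profile(maxima_t.maxima, maxima_t)
        pool_min_profile = bm.normalized_profile(pool_min_scores, maxima_t)
        sigma = bm.competitor_sigma(
            record_t.scores,
            competitor_scores,
            maxima_t,
            pool_max_profile,
            pool_min_profile,
        )
    except (ValueError, ZeroDivisionError) as exc:
        raise PipelineError("Competitor", str(exc)) from exc
    comp_dim = _fuzzy_dimension(
        "Competitor", sigma.value, sigma.percent, systems["competitor"]
    )

    dimensions = {
        "WQ": wq_dim,
        "Past": past_dim,
        "Best": best_dim,
        "Competitor": comp_dim,
    }
    profile = {name: d.defuzzified for name, d in dimensions.items()}
    aggregate = choquet_integral(profile, measure)

    provenance = {
        "maxima_t": f"{maxima_t.pool} -> {maxima_t.maxima.as_dict()}",
        "maxima_tm1": f"{maxima_tm1.pool} -> {maxima_tm1.maxima.as_dict()}",
        "competitor": competitor_id or "explicit scores",
        "pool_min": str(pool_min_scores.as_dict()),
    }
    return EvaluationReport(
        farm_id=farm_id,
        period_t=period_t,
        period_tm1=period_tm1,
        competitor_id=competitor_id,
        dimensions=dimensions,
        profile=profile,
        aggregate=aggregate,
        provenance=provenance,
    )
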