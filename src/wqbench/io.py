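"""Readers and writers: panels, expert response tables, evaluation reports.

Panels travel as UTF-8 CSV with a dot decimal separator, in two dialects:

* wide -- ``farm_id,period,GF,GHo,GHe,AB``, one row per farm-period;
* long -- ``farm_id,period,principle,criterion,score``, one row per
  criterion, aggregated to principle scores (mean) on read.

Decimal commas are rejected rather than coerced: silently re-parsing
``"51,53"`` would corrupt scores.  Reports serialise deterministically
(stable key order; display rounding of ratios to 4 d.p., percents and scores
to 2 d.p. in the human-readable formats; full precision in JSON so a report
round-trips exactly).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd

from .choquet import AggregateResult, ChoquetStep
from .core import (
    CriterionScores,
    FarmPanel,
    FarmPeriodRecord,
    PrincipleScores,
    WQCategory,
    aggregate_criteria,
)
from .elicitation import (
    ExpertImportanceResponse,
    ExpertPanel,
    ExpertThresholdResponse,
)
from .pipeline import DimensionEvaluation, EvaluationReport

WIDE_COLUMNS = ["farm_id", "period", "GF", "GHo", "GHe", "AB"]
LONG_COLUMNS = ["farm_id", "period", "principle", "criterion", "score"]


class PanelFormatError(ValueError):
    """A panel file violates the documented schema."""


def _parse_score(raw, where: str) -> float:
    text = str(raw).strip()
    if "," in text:
        raise PanelFormatError(
            f"{where}: decimal comma in {text!r}; use a dot decimal separator"
        )
    try:
        return float(text)
    except ValueError:
        raise PanelFormatError(f"{where}: cannot parse score {text!r}") from None


def read_panel(path, dialect: str = "wide") -> FarmPanel:
    """Load a farm panel from CSV; period order follows first appearance."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise PanelFormatError(f"{path}: empty or headerless file") from None
    if dialect == "wide":
        return _panel_from_wide(frame, path)
    if dialect == "long":
        return _panel_from_long(frame, path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'wide' or 'long'")


def _require_columns(frame: pd.DataFrame, columns: list[str], path: Path) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise PanelFormatError(f"{path}: missing columns {missing}")


def _panel_from_wide(frame: pd.DataFrame, path: Path) -> FarmPanel:
    _require_columns(frame, WIDE_COLUMNS, path)
    records: list[FarmPeriodRecord] = []
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        farm, period = str(row["farm_id"]), str(row["period"])
        values = []
        for principle in ("GF", "GHo", "GHe", "AB"):
            where = f"{path}:{line} (farm {farm}, period {period}, {principle})"
            value = _parse_score(row[principle], where)
            if not (0.0 <= value <= 100.0):
                raise PanelFormatError(f"{where}: score {value} outside [0, 100]")
            values.append(value)
        records.append(
            FarmPeriodRecord(farm, period, PrincipleScores(*values))
        )
    try:
        return FarmPanel(records)
    except ValueError as exc:
        raise PanelFormatError(f"{path}: {exc}") from exc


def _panel_from_long(frame: pd.DataFrame, path: Path) -> FarmPanel:
    _require_columns(frame, LONG_COLUMNS, path)
    grouped: dict[tuple[str, str], list[tuple[str, str, float]]] = {}
    order: list[tuple[str, str]] = []
    for idx, row in frame.iterrows():
        line = idx + 2
        farm, period = str(row["farm_id"]), str(row["period"])
        principle, criterion = str(row["principle"]), str(row["criterion"])
        where = f"{path}:{line} (farm {farm}, period {period}, {principle})"
        score = _parse_score(row["score"], where)
        if not (0.0 <= score <= 100.0):
            raise PanelFormatError(f"{where}: score {score} outside [0, 100]")
        key = (farm, period)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append((principle, criterion, score))
    records = []
    for farm, period in order:
        try:
            criteria = CriterionScores(farm, period, grouped[(farm, period)])
            scores = aggregate_criteria(criteria, mode="mean")
        except ValueError as exc:
            raise PanelFormatError(
                f"{path} (farm {farm}, period {period}): {exc}"
            ) from exc
        records.append(FarmPeriodRecord(farm, period, scores))
    try:
        return FarmPanel(records)
    except ValueError as exc:
        raise PanelFormatError(f"{path}: {exc}") from exc


def write_panel(panel: FarmPanel, path) -> None:
    """Write a panel as wide CSV with full-precision (repr) scores."""
    path = Path(path)
    lines = [",".join(WIDE_COLUMNS)]
    for rec in panel.records:
        gf, gho, ghe, ab = rec.scores.as_tuple()
        lines.append(
            f"{rec.farm_id},{rec.period_id},{gf!r},{gho!r},{ghe!r},{ab!r}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Expert response tables
# ---------------------------------------------------------------------------


def read_importance_csv(path, experts: Iterable[str] | None = None) -> ExpertPanel:
    """Importance responses: columns ``expert_id,subset,label``.

    ``subset`` is a ``|``-joined list of dimension names.
    """
    frame = pd.read_csv(Path(path), dtype=str)
    responses = [
        ExpertImportanceResponse(
            expert_id=str(row["expert_id"]),
            subset=frozenset(str(row["subset"]).split("|")),
            label=str(row["label"]),
        )
        for _, row in frame.iterrows()
    ]
    roster = sorted({r.expert_id for r in responses} | set(experts or []))
    return ExpertPanel(experts=roster, importance_responses=responses)


def read_threshold_csv(path, experts: Iterable[str] | None = None) -> ExpertPanel:
    """Threshold responses: columns ``expert_id,benchmark,category,a,c``."""
    frame = pd.read_csv(Path(path), dtype=str)
    responses = []
    for idx, row in frame.iterrows():
        where = f"{path}:{idx + 2}"
        responses.append(
            ExpertThresholdResponse(
                expert_id=str(row["expert_id"]),
                category=f"{row['benchmark']}:{row['category']}",
                a=_parse_score(row["a"], where),
                c=_parse_score(row["c"], where),
            )
        )
    roster = sorted({r.expert_id for r in responses} | set(experts or []))
    return ExpertPanel(experts=roster, threshold_responses=responses)


# ---------------------------------------------------------------------------
# Evaluation reports
# ---------------------------------------------------------------------------


def _dimension_to_dict(d: DimensionEvaluation) -> dict:
    return {
        "dimension": d.dimension,
        "raw_value": d.raw_value,
        "percent": d.percent,
        "memberships": d.memberships,
        "five_level": d.five_level,
        "four_level": d.four_level.name,
        "defuzzified": d.defuzzified,
    }


def report_to_dict(report: EvaluationReport) -> dict:
    agg = report.aggregate
    return {
        "farm_id": report.farm_id,
        "period_t": report.period_t,
        "period_tm1": report.period_tm1,
        "competitor_id": report.competitor_id,
        "dimensions": {
            name: _dimension_to_dict(d) for name, d in report.dimensions.items()
        },
        "profile": dict(report.profile),
        "aggregate": {
            "choquet": agg.choquet,
            "scaled": agg.scaled,
            "category": agg.category.name if agg.category is not None else None,
            "trace": [
                {
                    "dimension": s.dimension,
                    "value": s.value,
                    "increment": s.increment,
                    "coalition": sorted(s.coalition),
                    "measure": s.measure,
                }
                for s in agg.trace
            ],
        },
        "provenance": dict(report.provenance),
    }


def report_from_dict(data: dict) -> EvaluationReport:
    dimensions = {}
    for name, d in data["dimensions"].items():
        dimensions[name] = DimensionEvaluation(
            dimension=d["dimension"],
            raw_value=d["raw_value"],
            percent=d["percent"],
            memberships=d["memberships"],
            five_level=d["five_level"],
            four_level=WQCategory[d["four_level"]],
            defuzzified=d["defuzzified"],
        )
    agg = data["aggregate"]
    aggregate = AggregateResult(
        choquet=agg["choquet"],
        scaled=agg["scaled"],
        category=WQCategory[agg["category"]] if agg["category"] is not None else None,
        trace=tuple(
            ChoquetStep(
                dimension=s["dimension"],
                value=s["value"],
                increment=s["increment"],
                coalition=frozenset(s["coalition"]),
                measure=s["measure"],
            )
            for s in agg["trace"]
        ),
    )
    return EvaluationReport(
        farm_id=data["farm_id"],
        period_t=data["period_t"],
        period_tm1=data["period_tm1"],
        competitor_id=data["competitor_id"],
        dimensions=dimensions,
        profile=dict(data["profile"]),
        aggregate=aggregate,
        provenance=dict(data["provenance"]),
    )


def _fmt(value: float | None, places: int) -> str:
    return "" if value is None else f"{value:.{places}f}"


def render_report(report: EvaluationReport, format: str = "json") -> str:
    """Serialise a report as ``json`` (full precision), ``markdown`` or ``csv``."""
    if format == "json":
        return json.dumps(report_to_dict(report), indent=2, sort_keys=True)
    if format == "markdown":
        lines = [
            f"# Welfare evaluation: {report.farm_id} "
            f"({report.period_tm1} -> {report.period_t})",
            "",
            "| Dimension | Raw value | Percent | Five-level | Four-level | Defuzzified |",
            "|---|---|---|---|---|---|",
        ]
        for name, d in report.dimensions.items():
            lines.append(
                f"| {name} | {_fmt(d.raw_value, 4)} | {_fmt(d.percent, 2)} "
                f"| {d.five_level or ''} | {d.four_level.label} "
                f"| {d.defuzzified:.2f} |"
            )
        agg = report.aggregate
        category = agg.category.label if agg.category is not None else "out of range"
        lines += [
            "",
            f"**Aggregate score: {agg.scaled:.2f}** -> **{category}**",
            "",
        ]
        return "\n".join(lines)
    if format == "csv":
        lines = ["row,dimension,raw_value,percent,five_level,four_level,defuzzified,score"]
        for name, d in report.dimensions.items():
            lines.append(
                f"dimension,{name},{_fmt(d.raw_value, 4)},{_fmt(d.percent, 2)},"
                f"{d.five_level or ''},{d.four_level.name},{d.defuzzified:.2f},"
            )
        agg = report.aggregate
        category = agg.category.name if agg.category is not None else ""
        lines.append(f"summary,,,,,{category},,{agg.scaled:.2f}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {format!r}")


def write_report(report: EvaluationReport, path, format: str = "json") -> None:
    """Render a report and write it to ``path``."""
    Path(path).write_text(render_report(report, format=format), encoding="utf-8")
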