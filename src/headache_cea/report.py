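"""Full evaluation runs and results-table rendering.

``run_full_evaluation`` composes effectiveness -> costing -> ICER for all
three headache types, both horizons and both perspectives of one country,
producing an :class:`EvaluationReport` shaped like the published results
tables (with "(cost saved)"/"n/a" semantics for dominant cells).
Renderers emit CSV and JSON losslessly and a markdown table mirroring the
printed layout.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from typing import Iterable

import pandas as pd

from . import __about__
from .cea import break_even_cost_factor, classify_who, compute_icer
from .costing import provider_cost_delta, societal_cost_delta
from .effectiveness import hlys_gained
from .model import (
    CountryParameters,
    GapClosurePolicy,
    ProductivityPolicy,
    WHOThresholds,
)

__all__ = ["ReportCell", "EvaluationReport", "run_full_evaluation", "render_tables"]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

#: Literal row labels used in the published tables, reused by the markdown
#: renderer.
ROW_LABELS = {
    "n_patients": "Numbers of patients",
    "additional_cost": "Additional costs (euros)",
    "hlys_gained": "HLYs gained",
    "icer": "ICER (euros spent for each HLY gained)",
}


@dataclass(frozen=True)
class ReportCell:
    """One (country, headache type, horizon, perspective) result cell."""

    country_id: str
    headache_type: str
    horizon_years: int
    perspective: str
    n_patients: int
    additional_cost: float
    hlys_gained: float
    icer: int | None  # display-rounded; None when cost saving / no gain
    icer_full_precision: float | None
    dominance: str
    who_category: str
    break_even_cost_factor: float


@dataclass(frozen=True)
class EvaluationReport:
    """All requested cells of one evaluation run plus run metadata."""

    cells: tuple[ReportCell, ...]
    metadata: dict

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(c) for c in self.cells])


def run_full_evaluation(
    params: CountryParameters,
    thresholds: WHOThresholds,
    policy: GapClosurePolicy | None = None,
    rho: ProductivityPolicy | None = None,
    horizons: Iterable[int] = (1, 5),
    discount_rate: float = 0.0,
) -> EvaluationReport:
    """Evaluate one country across all types, horizons and perspectives.

    The pipeline is deterministic: identical inputs give identical reports.
    Stage errors propagate with the offending cell attached. A warning is
    logged when a defined ICER reaches the 3 x GDP threshold, since such a
    cell would not be considered cost-effective by WHO criteria.
    """
    policy = policy or GapClosurePolicy()
    rho = rho or ProductivityPolicy()
    cells: list[ReportCell] = []
    for headache_type in params.params_by_type:
        for horizon in horizons:
            try:
                eff = hlys_gained(
                    params, headache_type, policy, horizon, discount_rate
                )
                provider = provider_cost_delta(
                    params, headache_type, policy, horizon, discount_rate
                )
                societal = societal_cost_delta(
                    provider, params, headache_type, eff, rho, discount_rate
                )
            except Exception as exc:
                raise RuntimeError(
                    f"evaluation failed for cell ({params.country_id}, "
                    f"{headache_type}, {horizon}y): {exc}"
                ) from exc
            logger.debug(
                "cell (%s, %s, %dy): HLYs=%.2f provider=%.2f societal=%.2f",
                params.country_id,
                headache_type,
                horizon,
                eff.hlys_gained,
                provider.additional_cost,
                societal.additional_cost,
            )
            for delta in (provider, societal):
                outcome = compute_icer(delta.additional_cost, eff.hlys_gained)
                category = classify_who(outcome, thresholds)
                if category == "not_cost_effective" and outcome.icer is not None:
                    logger.warning(
                        "ICER %.0f euros/HLY for (%s, %s, %dy, %s) is at or above "
                        "3 x GDP per capita (%.0f)",
                        outcome.icer,
                        params.country_id,
                        headache_type,
                        horizon,
                        delta.perspective,
                        thresholds.ce_multiple * thresholds.gdp_per_capita,
                    )
                cells.append(
                    ReportCell(
                        country_id=params.country_id,
                        headache_type=headache_type,
                        horizon_years=int(horizon),
                        perspective=delta.perspective,
                        n_patients=params.n_patients(headache_type),
                        additional_cost=delta.additional_cost,
                        hlys_gained=eff.hlys_gained,
                        icer=outcome.rounded,
                        icer_full_precision=outcome.icer,
                        dominance=outcome.dominance,
                        who_category=category,
                        break_even_cost_factor=break_even_cost_factor(
                            outcome, thresholds
                        ),
                    )
                )
    metadata = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __about__.__version__,
        "currency_year": "2020 euros",
        "country_id": params.country_id,
        "gdp_per_capita": thresholds.gdp_per_capita,
        "coverage_closure": policy.coverage_closure,
        "adherence_closure": policy.adherence_closure,
        "rho": rho.recovery_fraction,
        "discount_rate": discount_rate,
        "horizons": [int(h) for h in horizons],
    }
    return EvaluationReport(cells=tuple(cells), metadata=metadata)


def render_tables(report: EvaluationReport, format: str) -> str:
    """Serialize a report as ``csv``, ``json`` or ``markdown``.

    CSV and JSON are lossless; markdown mirrors the published tables'
    layout, one block per horizon and perspective, with "(cost saved)"
    annotating negative additional costs and "n/a" for undefined ICERs.
    """
    if format == "csv":
        return report.to_dataframe().to_csv(index=False)
    if format == "json":
        return json.dumps(
            {
                "metadata": report.metadata,
                "cells": [asdict(c) for c in report.cells],
            },
            indent=2,
        )
    if format == "markdown":
        return _render_markdown(report)
    raise ValueError(f"unknown format {format!r}; choose csv, json or markdown")


def _fmt_cost(value: float) -> str:
    if value < 0:
        return f"({value:,.0f}) (cost saved)"
    return f"{value:,.0f}"


def _render_markdown(report: EvaluationReport) -> str:
    df = report.to_dataframe()
    lines = [f"# {report.metadata.get('country_id', 'evaluation')}", ""]
    if df.empty:
        lines.append("(no cells)")
        return "\n".join(lines) + "\n"
    types = list(dict.fromkeys(df["headache_type"]))
    header = "| | " + " | ".join(t.upper() if t != "migraine" else t.capitalize() for t in types) + " |"
    rule = "|---" * (len(types) + 1) + "|"
    for horizon in sorted(df["horizon_years"].unique()):
        for perspective in ("provider", "societal"):
            sub = df[
                (df["horizon_years"] == horizon)
                & (df["perspective"] == perspective)
            ]
            if sub.empty:
                continue
            by_type = {row.headache_type: row for row in sub.itertuples()}
            lines.append(f"## {horizon}-year time frame, {perspective} perspective")
            lines.append("")
            lines.append(header)
            lines.append(rule)
            lines.append(
                f"| {ROW_LABELS['n_patients']} | "
                + " | ".join(f"{by_type[t].n_patients:,}" for t in types)
                + " |"
            )
            lines.append(
                f"| {ROW_LABELS['additional_cost']} | "
                + " | ".join(_fmt_cost(by_type[t].additional_cost) for t in types)
                + " |"
            )
            lines.append(
                f"| {ROW_LABELS['hlys_gained']} | "
                + " | ".join(f"{by_type[t].hlys_gained:,.0f}" for t in types)
                + " |"
            )
            lines.append(
                f"| {ROW_LABELS['icer']} | "
                + " | ".join(
                    "n/a" if pd.isna(by_type[t].icer) else f"{int(by_type[t].icer):,}"
                    for t in types
                )
                + " |"
            )
            lines.append("")
    return "\n".join(lines)
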