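"""ICER computation, WHO threshold classification and sensitivity analysis.

The incremental cost-effectiveness ratio (ICER) is the additional cost per
healthy life year gained, defined only when both are positive. Following
the convention of published cost-effectiveness tables, a cell with positive
health gain and non-positive additional cost is reported as *cost saving*
(dominant) rather than with a negative ICER, and a cell with no health gain
carries no ICER at all.

Classification uses the WHO GDP-per-capita thresholds: an intervention
costing < 1 x GDP per capita per HLY gained is highly cost-effective, and
< 3 x GDP per capita is cost-effective (strict inequalities).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .model import CostDelta, EffectivenessResult, WHOThresholds

__all__ = [
    "IcerOutcome",
    "compute_icer",
    "round_icer",
    "classify_who",
    "break_even_cost_factor",
    "SensitivityResult",
    "sensitivity_sweep",
    "per_1000_cohort",
]


@dataclass(frozen=True)
class IcerOutcome:
    """ICER (euros/HLY, full precision) together with its dominance flag.

    ``dominance`` is ``icer_defined`` when a positive cost buys a positive
    gain, ``cost_saving`` when a positive gain comes at non-positive cost,
    and ``no_gain`` when there is no health gain to ratio against.
    """

    dominance: str
    icer: float | None = None

    @property
    def rounded(self) -> int | None:
        """ICER rounded to the nearest integer euro (half away from zero)."""
        return None if self.icer is None else round_icer(self.icer)


def round_icer(value: float) -> int:
    """Round to the nearest integer euro, halves away from zero."""
    return int(math.floor(value + 0.5)) if value >= 0 else int(math.ceil(value - 0.5))


def compute_icer(additional_cost: float, hlys_gained: float) -> IcerOutcome:
    """ICER or dominance flag for one (cost, effect) pair.

    The full-precision quotient is retained internally; use
    :attr:`IcerOutcome.rounded` for the display value.
    """
    if not (math.isfinite(additional_cost) and math.isfinite(hlys_gained)):
        raise ValueError(
            f"non-finite inputs: additional_cost={additional_cost!r}, "
            f"hlys_gained={hlys_gained!r}"
        )
    if hlys_gained <= 0:
        return IcerOutcome(dominance="no_gain")
    if additional_cost <= 0:
        return IcerOutcome(dominance="cost_saving")
    return IcerOutcome(dominance="icer_defined", icer=additional_cost / hlys_gained)


def classify_who(
    icer_or_outcome: float | IcerOutcome, thresholds: WHOThresholds
) -> str:
    """WHO category of an ICER (or of a dominance flag).

    Cost-saving outcomes are *dominant*; a cell with no health gain cannot
    be cost-effective at any threshold. Threshold comparisons are strict.
    """
    if isinstance(icer_or_outcome, IcerOutcome):
        if icer_or_outcome.dominance == "cost_saving":
            return "dominant"
        if icer_or_outcome.dominance == "no_gain":
            return "not_cost_effective"
        icer = icer_or_outcome.icer
    else:
        icer = float(icer_or_outcome)
    gdp = thresholds.gdp_per_capita
    if icer < thresholds.highly_ce_multiple * gdp:
        return "highly_cost_effective"
    if icer < thresholds.ce_multiple * gdp:
        return "cost_effective"
    return "not_cost_effective"


def break_even_cost_factor(
    outcome: IcerOutcome, thresholds: WHOThresholds
) -> float:
    """Largest cost-inflation factor keeping the cell at least cost-effective.

    Closed form: (ce_multiple x GDP per capita) / ICER for cells with a
    defined ICER. Dominant (cost-saving) cells tolerate any inflation of
    *health-care* costs smaller than the saving, conventionally reported as
    infinity; cells with no gain break even at factor 0.
    """
    if outcome.dominance == "cost_saving":
        return math.inf
    if outcome.dominance == "no_gain":
        return 0.0
    return thresholds.ce_multiple * thresholds.gdp_per_capita / outcome.icer


@dataclass(frozen=True)
class SensitivityResult:
    """One-way sensitivity sweep output.

    ``table`` has one row per (kind, factor): kind ``cost`` inflates
    health-care costs by the factor, kind ``hly`` deflates health gains by
    it. ``break_even_cost_factor`` is the closed-form threshold multiplier.
    """

    table: pd.DataFrame
    break_even_cost_factor: float


def sensitivity_sweep(
    additional_cost: float,
    hlys_gained: float,
    cost_factors: list[float],
    hly_deflators: list[float],
    thresholds: WHOThresholds,
) -> SensitivityResult:
    """Re-classify a cell under inflated costs and deflated health gains.

    For each factor F the ICER is recomputed with cost x F (kind ``cost``)
    or HLYs / F (kind ``hly``) and classified against the unchanged WHO
    thresholds. Both distortions move the ICER identically (cost x F and
    HLY / F give the same quotient), so the two halves of the table agree
    factor by factor.
    """
    for f in list(cost_factors) + list(hly_deflators):
        if not (f > 0 and math.isfinite(f)):
            raise ValueError(f"sensitivity factors must be positive, got {f!r}")
    rows = []
    for kind, factors in (("cost", cost_factors), ("hly", hly_deflators)):
        for f in factors:
            if kind == "cost":
                outcome = compute_icer(additional_cost * f, hlys_gained)
            else:
                outcome = compute_icer(additional_cost, hlys_gained / f)
            rows.append(
                {
                    "kind": kind,
                    "factor": f,
                    "icer": outcome.icer,
                    "dominance": outcome.dominance,
                    "who_category": classify_who(outcome, thresholds),
                }
            )
    base = compute_icer(additional_cost, hlys_gained)
    return SensitivityResult(
        table=pd.DataFrame(rows),
        break_even_cost_factor=break_even_cost_factor(base, thresholds),
    )


def per_1000_cohort(
    population_result: tuple[CostDelta, EffectivenessResult], n_patients: int
) -> tuple[CostDelta, EffectivenessResult]:
    """Rescale population-level results to a cohort of 1000 patients.

    Every extensive quantity (costs and their components, HLYs) is
    multiplied by 1000 / ``n_patients``; intensive quantities (effective
    fractions, and hence the ICER) are unchanged.
    """
    if n_patients <= 0:
        raise ValueError(f"n_patients must be > 0, got {n_patients!r}")
    cost, eff = population_result
    factor = 1000.0 / n_patients
    scaled_eff = EffectivenessResult(
        country_id=eff.country_id,
        headache_type=eff.headache_type,
        horizon_years=eff.horizon_years,
        hlys_gained=eff.hlys_gained * factor,
        effective_fraction_current=eff.effective_fraction_current,
        effective_fraction_achieved=eff.effective_fraction_achieved,
    )
    return cost.scaled(factor), scaled_eff
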