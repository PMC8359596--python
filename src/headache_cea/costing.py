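"""Additional cost of target vs current care, provider and societal views.

Provider-perspective costs count health-system resources only: medicines,
GP visits, specialist visits and examinations, plus a one-time per-patient
implementation charge (provider training and consumer education) in year 1.
Patients who are not effectively treated consume the same background
resources in both arms, so those costs net out of the difference; the
recurrent annual delta per patient is

    f_achieved * c_target - f_current * c_current

where ``c`` is the annual per-patient cost of each scenario's resource use.

The societal perspective additionally values lost productivity by the
human-capital approach (recovered workdays x wage). Recovered workdays per
year are N * (f_achieved - f_current) * treatment_effect *
workdays_lost_per_patient_year, of which only a fraction rho (1.0 baseline,
0.2 conservative) is assumed actually recoverable.
"""
from __future__ import annotations

from .model import (
    CareScenario,
    CostDelta,
    CountryParameters,
    EffectivenessResult,
    GapClosurePolicy,
    ProductivityPolicy,
    canonical_headache_type,
)
from .effectiveness import achieved_fractions, horizon_factor

__all__ = [
    "scenario_annual_cost_per_patient",
    "scenario_cost_components",
    "provider_cost_delta",
    "societal_cost_delta",
]


def scenario_cost_components(s: CareScenario) -> dict[str, float]:
    """Annual per-patient cost of a scenario, split by resource category."""
    return {
        "medicines": s.annual_medication_cost,
        "gp_visits": s.gp_visits * s.unit_cost_gp,
        "specialist_visits": s.specialist_visits * s.unit_cost_specialist,
        "examinations": s.examinations * s.unit_cost_examination,
    }


def scenario_annual_cost_per_patient(s: CareScenario) -> float:
    """Total annual health-care cost per effectively treated patient (euros)."""
    return sum(scenario_cost_components(s).values())


def provider_cost_delta(
    params: CountryParameters,
    headache_type: str,
    policy: GapClosurePolicy | None = None,
    horizon_years: int = 1,
    discount_rate: float = 0.0,
) -> CostDelta:
    """Additional health-care cost of target vs current care (euros).

    The recurrent component accrues every year of the horizon; the
    implementation cost is charged once, in year 1. The sign is
    unrestricted: when target care reduces medication overuse and visits
    (typically TTH and MOH) the delta is negative, i.e. a cost saving.
    """
    headache_type = canonical_headache_type(headache_type)
    if policy is None:
        policy = GapClosurePolicy()
    p = params.type_params(headache_type)
    n = params.n_patients(headache_type)
    f_current, f_achieved = achieved_fractions(params, headache_type, policy)
    years = horizon_factor(horizon_years, discount_rate)

    cur = scenario_cost_components(p.current)
    tgt = scenario_cost_components(p.target)
    components = {
        key: n * (f_achieved * tgt[key] - f_current * cur[key]) * years
        for key in cur
    }
    components["implementation"] = n * p.implementation_cost_per_patient
    components["productivity"] = 0.0
    return CostDelta(
        country_id=params.country_id,
        headache_type=headache_type,
        horizon_years=horizon_years,
        perspective="provider",
        additional_cost=sum(components.values()),
        components=components,
    )


def societal_cost_delta(
    provider: CostDelta,
    params: CountryParameters,
    headache_type: str,
    hlys: EffectivenessResult,
    rho: ProductivityPolicy | None = None,
    discount_rate: float = 0.0,
) -> CostDelta:
    """Extend a provider-perspective delta with recovered lost productivity.

    ``provider`` and ``hlys`` must refer to the same (country, headache
    type, horizon) cell. The productivity component is recorded as a
    (usually negative) euro amount; with rho = 0 the societal delta equals
    the provider delta exactly.
    """
    headache_type = canonical_headache_type(headache_type)
    if rho is None:
        rho = ProductivityPolicy()
    key = (params.country_id, headache_type, provider.horizon_years)
    if (provider.country_id, provider.headache_type, provider.horizon_years) != key:
        raise ValueError(
            f"provider delta keys {(provider.country_id, provider.headache_type, provider.horizon_years)} "
            f"do not match {key}"
        )
    if (hlys.country_id, hlys.headache_type, hlys.horizon_years) != key:
        raise ValueError(
            f"effectiveness keys {(hlys.country_id, hlys.headache_type, hlys.horizon_years)} "
            f"do not match {key}"
        )
    p = params.type_params(headache_type)
    n = params.n_patients(headache_type)
    years = horizon_factor(int(provider.horizon_years), discount_rate)
    workdays_recovered_per_year = (
        n
        * (hlys.effective_fraction_achieved - hlys.effective_fraction_current)
        * p.treatment_effect
        * p.workdays_lost_per_patient_year
    )
    productivity = (
        -rho.recovery_fraction
        * params.wage_per_workday
        * workdays_recovered_per_year
        * years
    )
    components = dict(provider.components)
    components["productivity"] = productivity
    return CostDelta(
        country_id=provider.country_id,
        headache_type=headache_type,
        horizon_years=provider.horizon_years,
        perspective="societal",
        additional_cost=provider.additional_cost + productivity,
        components=components,
    )
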