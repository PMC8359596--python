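"""Synthetic country parameter sets for testing and demonstration.

The study's real inputs (country prevalences, efficacies, unit costs,
wages) come from population-based surveys and a companion costing exercise
and are not redistributable here. This module generates complete,
internally consistent stand-ins with the same statistical *structure*:
three country archetypes spanning the relevant range of size and wage
level,

* ``small-high-wage``     -- a small, very high-wage economy,
* ``large-high-income``   -- a large high-income economy,
* ``large-middle-income`` -- a large middle-income economy,

with wage ordering small-high-wage > large-high-income >
large-middle-income guaranteed by disjoint wage bands. Every draw is
uniform within the documented band (see ``ARCHETYPE_RANGES``,
``SHARED_RANGES`` and ``TYPE_RANGES``); no generated number claims to be a
published national statistic.

Two design choices matter for downstream comparisons:

* **Common random numbers.** The random stream depends on the seed only,
  not on the archetype, and draws occur in a fixed order. Archetypes
  therefore share uniform quantiles and differ only through their bands,
  so cross-archetype contrasts (e.g. how societal savings scale with
  wages) are not confounded by sampling noise -- the standard
  variance-reduction device for scenario comparison.
* **Price index.** All unit costs, medication costs and implementation
  costs are drawn at a reference price level and scaled by
  ``wage_per_workday / REFERENCE_WAGE``, reflecting that health-care
  prices track wage levels across economies.

Structural constraints encode the qualitative economics of each headache
type: target care for migraine *adds* resources on top of current care
(prophylaxis, more structured follow-up), while target care for TTH
(consumer education displacing medical consultations) and MOH (withdrawal
of overused medication) *reduces* per-patient resource use.
"""
from __future__ import annotations

import numpy as np

from .model import CareScenario, CountryParameters, HeadacheTypeParameters

__all__ = [
    "ARCHETYPES",
    "ARCHETYPE_RANGES",
    "SHARED_RANGES",
    "TYPE_RANGES",
    "REFERENCE_WAGE",
    "generate_country",
]

#: Valid archetype labels, in decreasing wage order.
ARCHETYPES: tuple[str, ...] = (
    "small-high-wage",
    "large-high-income",
    "large-middle-income",
)

#: Reference daily wage (euros) at which cost bands are expressed; all
#: monetary draws are scaled by wage_per_workday / REFERENCE_WAGE.
REFERENCE_WAGE: float = 110.0

#: Archetype-specific uniform bands. Wage bands are disjoint, which forces
#: the documented wage ordering for every pair of seeds.
ARCHETYPE_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "small-high-wage": {
        "population": (500_000, 800_000),
        "wage_per_workday": (200.0, 300.0),
    },
    "large-high-income": {
        "population": (40_000_000, 60_000_000),
        "wage_per_workday": (90.0, 150.0),
    },
    "large-middle-income": {
        "population": (100_000_000, 150_000_000),
        "wage_per_workday": (15.0, 40.0),
    },
}

#: Bands shared by all archetypes (drawn with common quantiles).
SHARED_RANGES: dict[str, tuple[float, float]] = {
    # GDP per capita as a multiple of the daily wage (roughly the number of
    # annual workdays times the labour share of output).
    "gdp_to_wage_ratio": (250.0, 400.0),
}

#: Per-headache-type uniform bands. Monetary bands ("ref euros") are at the
#: reference price level, before wage-index scaling. ``target_*`` entries
#: describe how the target scenario is derived from the current one:
#: ``*_addon`` bands are added (migraine gains prophylaxis and follow-up),
#: ``*_multiplier`` bands scale current resource use down (TTH consumer
#: education, MOH medication withdrawal), ``*_abs`` bands are absolute.
TYPE_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "migraine": {
        "prevalence": (0.10, 0.15),
        "disability_time_fraction": (0.055, 0.105),
        "treatment_effect": (0.45, 0.65),
        "coverage_current": (0.25, 0.40),
        "coverage_target": (0.75, 0.90),
        "adherence_current": (0.30, 0.50),
        "adherence_target": (0.75, 0.90),
        "workdays_lost_per_patient_year": (10.0, 18.0),
        "implementation_cost_per_patient": (4.0, 10.0),
        "unit_cost_gp": (25.0, 40.0),
        "unit_cost_specialist": (70.0, 110.0),
        "unit_cost_examination": (40.0, 70.0),
        "current_medication_cost": (15.0, 35.0),
        "current_gp_visits": (0.8, 1.5),
        "current_specialist_visits": (0.05, 0.15),
        "current_examinations": (0.05, 0.20),
        "target_medication_addon": (15.0, 35.0),
        "target_gp_visits_addon": (0.3, 0.8),
        "target_specialist_visits_addon": (0.0, 0.10),
        "target_examinations_addon": (0.0, 0.10),
    },
    "tth": {
        "prevalence": (0.15, 0.25),
        "disability_time_fraction": (0.010, 0.030),
        "treatment_effect": (0.30, 0.50),
        "coverage_current": (0.30, 0.50),
        "coverage_target": (0.75, 0.85),
        "adherence_current": (0.40, 0.60),
        "adherence_target": (0.75, 0.85),
        "workdays_lost_per_patient_year": (1.0, 3.0),
        "implementation_cost_per_patient": (0.5, 1.5),
        "unit_cost_gp": (25.0, 40.0),
        "unit_cost_specialist": (70.0, 110.0),
        "unit_cost_examination": (40.0, 70.0),
        "current_medication_cost": (20.0, 40.0),
        "current_gp_visits": (0.5, 1.5),
        "current_specialist_visits": (0.02, 0.10),
        "current_examinations": (0.05, 0.15),
        "target_resource_multiplier": (0.08, 0.18),
    },
    "moh": {
        "prevalence": (0.010, 0.020),
        "disability_time_fraction": (0.15, 0.25),
        "treatment_effect": (0.50, 0.70),
        "coverage_current": (0.20, 0.40),
        "coverage_target": (0.75, 0.90),
        "adherence_current": (0.35, 0.55),
        "adherence_target": (0.75, 0.90),
        "workdays_lost_per_patient_year": (15.0, 30.0),
        "implementation_cost_per_patient": (5.0, 12.0),
        "unit_cost_gp": (25.0, 40.0),
        "unit_cost_specialist": (70.0, 110.0),
        "unit_cost_examination": (40.0, 70.0),
        "current_medication_cost": (80.0, 150.0),
        "current_gp_visits": (1.0, 2.0),
        "current_specialist_visits": (0.10, 0.30),
        "current_examinations": (0.10, 0.30),
        "target_medication_multiplier": (0.15, 0.35),
        "target_gp_visits_multiplier": (0.8, 1.2),
        "target_specialist_visits_abs": (0.30, 0.60),
        "target_examinations_abs": (0.10, 0.30),
    },
}


class _BandSampler:
    """Uniform draws within bands, consuming the stream in call order."""

    def __init__(self, seed: int):
        # Wrap arbitrary integers into the generator's accepted range.
        self._rng = np.random.default_rng(int(seed) % 2**63)

    def u(self, band: tuple[float, float]) -> float:
        lo, hi = band
        return lo + self._rng.random() * (hi - lo)


def _type_parameters(
    headache_type: str, draw: _BandSampler, price_index: float
) -> tuple[float, HeadacheTypeParameters]:
    """Draw one headache type's parameters; returns (prevalence, params).

    The draw order is fixed and identical for every archetype so that
    archetypes share quantiles (common random numbers).
    """
    b = TYPE_RANGES[headache_type]
    prevalence = draw.u(b["prevalence"])
    dtf = draw.u(b["disability_time_fraction"])
    effect = draw.u(b["treatment_effect"])
    cov_cur = draw.u(b["coverage_current"])
    cov_tgt = draw.u(b["coverage_target"])
    adh_cur = draw.u(b["adherence_current"])
    adh_tgt = draw.u(b["adherence_target"])
    days = draw.u(b["workdays_lost_per_patient_year"])
    impl = draw.u(b["implementation_cost_per_patient"]) * price_index
    unit_gp = draw.u(b["unit_cost_gp"]) * price_index
    unit_spec = draw.u(b["unit_cost_specialist"]) * price_index
    unit_exam = draw.u(b["unit_cost_examination"]) * price_index
    cur_med = draw.u(b["current_medication_cost"]) * price_index
    cur_gp = draw.u(b["current_gp_visits"])
    cur_spec = draw.u(b["current_specialist_visits"])
    cur_exam = draw.u(b["current_examinations"])

    if headache_type == "migraine":
        tgt_med = cur_med + draw.u(b["target_medication_addon"]) * price_index
        tgt_gp = cur_gp + draw.u(b["target_gp_visits_addon"])
        tgt_spec = cur_spec + draw.u(b["target_specialist_visits_addon"])
        tgt_exam = cur_exam + draw.u(b["target_examinations_addon"])
    elif headache_type == "tth":
        mult = draw.u(b["target_resource_multiplier"])
        tgt_med = cur_med * mult
        tgt_gp = cur_gp * mult
        tgt_spec = cur_spec * mult
        tgt_exam = cur_exam * mult
    else:  # moh
        tgt_med = cur_med * draw.u(b["target_medication_multiplier"])
        tgt_gp = cur_gp * draw.u(b["target_gp_visits_multiplier"])
        tgt_spec = draw.u(b["target_specialist_visits_abs"])
        tgt_exam = draw.u(b["target_examinations_abs"])

    current = CareScenario(
        coverage=cov_cur,
        adherence=adh_cur,
        annual_medication_cost=cur_med,
        gp_visits=cur_gp,
        specialist_visits=cur_spec,
        examinations=cur_exam,
        unit_cost_gp=unit_gp,
        unit_cost_specialist=unit_spec,
        unit_cost_examination=unit_exam,
    )
    target = CareScenario(
        coverage=cov_tgt,
        adherence=adh_tgt,
        annual_medication_cost=tgt_med,
        gp_visits=tgt_gp,
        specialist_visits=tgt_spec,
        examinations=tgt_exam,
        unit_cost_gp=unit_gp,
        unit_cost_specialist=unit_spec,
        unit_cost_examination=unit_exam,
    )
    params = HeadacheTypeParameters(
        headache_type=headache_type,
        disability_time_fraction=dtf,
        treatment_effect=effect,
        current=current,
        target=target,
        workdays_lost_per_patient_year=days,
        implementation_cost_per_patient=impl,
    )
    return prevalence, params


def generate_country(archetype: str, seed: int) -> CountryParameters:
    """Generate one synthetic country parameter set.

    A pure function of ``(archetype, seed)``: identical calls return
    identical objects. Unknown archetypes raise ``ValueError`` naming the
    valid labels.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(
            f"unknown archetype {archetype!r}; valid archetypes: "
            + ", ".join(ARCHETYPES)
        )
    draw = _BandSampler(seed)
    bands = ARCHETYPE_RANGES[archetype]
    population = int(round(draw.u(bands["population"])))
    wage = draw.u(bands["wage_per_workday"])
    gdp_per_capita = wage * draw.u(SHARED_RANGES["gdp_to_wage_ratio"])
    price_index = wage / REFERENCE_WAGE

    patients: dict[str, int] = {}
    params_by_type: dict[str, HeadacheTypeParameters] = {}
    for headache_type in ("migraine", "tth", "moh"):
        prevalence, params = _type_parameters(headache_type, draw, price_index)
        patients[headache_type] = int(round(population * prevalence))
        params_by_type[headache_type] = params

    return CountryParameters(
        country_id=f"{archetype}-{seed}",
        population=population,
        patients=patients,
        gdp_per_capita=gdp_per_capita,
        wage_per_workday=wage,
        params_by_type=params_by_type,
    )
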