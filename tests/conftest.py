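import pytest

from headache_cea import CareScenario, CountryParameters, HeadacheTypeParameters


def make_scenario(
    coverage=0.3,
    adherence=0.4,
    medication=0.0,
    gp_visits=0.0,
    specialist_visits=0.0,
    examinations=0.0,
    unit_gp=30.0,
    unit_specialist=80.0,
    unit_exam=100.0,
) -> CareScenario:
    return CareScenario(
        coverage=coverage,
        adherence=adherence,
        annual_medication_cost=medication,
        gp_visits=gp_visits,
        specialist_visits=specialist_visits,
        examinations=examinations,
        unit_cost_gp=unit_gp,
        unit_cost_specialist=unit_specialist,
        unit_cost_examination=unit_exam,
    )


def make_country(
    n=1000,
    current=None,
    target=None,
    disability_time_fraction=0.10,
    treatment_effect=0.5,
    workdays_lost=5.0,
    implementation_cost=0.0,
    wage=20.0,
    gdp=10_000.0,
    headache_type="migraine",
) -> CountryParameters:
    """Single-type toy country used by hand-arithmetic unit tests."""
    current = current or make_scenario(coverage=0.3, adherence=0.4)
    target = target or make_scenario(coverage=0.9, adherence=0.8)
    params = HeadacheTypeParameters(
        headache_type=headache_type,
        disability_time_fraction=disability_time_fraction,
        treatment_effect=treatment_effect,
        current=current,
        target=target,
        workdays_lost_per_patient_year=workdays_lost,
        implementation_cost_per_patient=implementation_cost,
    )
    return CountryParameters(
        country_id="toyland",
        population=max(n, 1) * 10,
        patients={headache_type: n},
        gdp_per_capita=gdp,
        wage_per_workday=wage,
        params_by_type={headache_type: params},
    )


@pytest.fixture
def toy_country():
    """The worked example: N=1000, coverage 0.3->0.9, adherence 0.4->0.8,
    disability fraction 0.10, treatment effect 0.5."""
    return make_country()
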