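import pytest

from headache_cea import (
    GapClosurePolicy,
    ProductivityPolicy,
    generate_country,
    hlys_gained,
    provider_cost_delta,
    scenario_annual_cost_per_patient,
    societal_cost_delta,
)

from conftest import make_country, make_scenario


class TestScenarioAnnualCost:
    def test_worked_example(self):
        s = make_scenario(
            medication=50,
            gp_visits=2,
            specialist_visits=0.5,
            examinations=0.2,
            unit_gp=30,
            unit_specialist=80,
            unit_exam=100,
        )
        # 50 + 2*30 + 0.5*80 + 0.2*100 = 170
        assert scenario_annual_cost_per_patient(s) == pytest.approx(170.0)

    def test_all_zero_resource_use(self):
        assert scenario_annual_cost_per_patient(make_scenario()) == 0.0

    def test_zero_unit_costs_leave_medication_only(self):
        s = make_scenario(
            medication=42, gp_visits=9, specialist_visits=3, examinations=7,
            unit_gp=0, unit_specialist=0, unit_exam=0,
        )
        assert scenario_annual_cost_per_patient(s) == pytest.approx(42.0)


class TestProviderCostDelta:
    def test_one_time_plus_recurrent_decomposition(self):
        # N=1; both scenarios fully effective; recurrent delta 10/patient-year
        # (medication 20 -> 30); implementation 50 once. 5 years: 50 + 5*10.
        country = make_country(
            n=1,
            current=make_scenario(coverage=1.0, adherence=1.0, medication=20),
            target=make_scenario(coverage=1.0, adherence=1.0, medication=30),
            implementation_cost=50.0,
        )
        delta5 = provider_cost_delta(country, "migraine", horizon_years=5)
        assert delta5.additional_cost == pytest.approx(100.0)
        assert delta5.components["implementation"] == pytest.approx(50.0)
        delta1 = provider_cost_delta(country, "migraine", horizon_years=1)
        assert delta1.additional_cost == pytest.approx(60.0)

    def test_no_change_no_cost(self):
        same = make_scenario(coverage=0.5, adherence=0.5, medication=80, gp_visits=2)
        country = make_country(current=same, target=same, implementation_cost=0.0)
        assert provider_cost_delta(country, "migraine").additional_cost == 0.0

    def test_cheaper_target_yields_saving(self):
        # MOH-like: withdrawal replaces overused acute medication
        country = make_country(
            n=100,
            current=make_scenario(coverage=0.5, adherence=0.5, medication=200),
            target=make_scenario(coverage=0.8, adherence=0.8, medication=10),
            implementation_cost=0.0,
            headache_type="moh",
        )
        delta = provider_cost_delta(country, "moh")
        assert delta.additional_cost < 0

    def test_component_sum_identity(self):
        country = generate_country("large-middle-income", 9)
        for headache_type in country.params_by_type:
            delta = provider_cost_delta(country, headache_type, horizon_years=5)
            assert sum(delta.components.values()) == pytest.approx(
                delta.additional_cost, rel=1e-12
            )
            assert delta.components["productivity"] == 0.0


def _societal_setup(rho):
    """N=1, provider delta 100, 10 recovered workdays/year, wage 20."""
    country = make_country(
        n=1,
        current=make_scenario(coverage=0.2, adherence=1.0, medication=0),
        target=make_scenario(coverage=1.0, adherence=1.0, medication=100),
        treatment_effect=0.5,
        workdays_lost=25.0,
        wage=20.0,
    )
    policy = GapClosurePolicy(coverage_closure=1.0, adherence_closure=1.0)
    eff = hlys_gained(country, "migraine", policy, horizon_years=1)
    provider = provider_cost_delta(country, "migraine", policy, horizon_years=1)
    assert provider.additional_cost == pytest.approx(100.0)
    societal = societal_cost_delta(
        provider, country, "migraine", eff, ProductivityPolicy(rho)
    )
    return provider, societal


class TestSocietalCostDelta:
    def test_full_recovery_turns_cost_into_saving(self):
        # 100 - 1.0 * 20 euros/day * 10 days = -100
        _, societal = _societal_setup(rho=1.0)
        assert societal.additional_cost == pytest.approx(-100.0)
        assert societal.components["productivity"] == pytest.approx(-200.0)

    def test_zero_recovery_collapses_to_provider_perspective(self):
        provider, societal = _societal_setup(rho=0.0)
        assert societal.additional_cost == pytest.approx(provider.additional_cost)

    def test_conservative_twenty_percent_recovery(self):
        # 100 - 0.2 * 200 = 60
        _, societal = _societal_setup(rho=0.2)
        assert societal.additional_cost == pytest.approx(60.0)

    def test_mismatched_cell_keys_are_rejected(self):
        country = make_country()
        eff1 = hlys_gained(country, "migraine", horizon_years=1)
        provider5 = provider_cost_delta(country, "migraine", horizon_years=5)
        with pytest.raises(ValueError, match="do not match"):
            societal_cost_delta(provider5, country, "migraine", eff1)

    def test_societal_never_exceeds_provider_cost(self):
        for seed in range(5):
            country = generate_country("small-high-wage", seed)
            for headache_type in country.params_by_type:
                eff = hlys_gained(country, headache_type, horizon_years=5)
                provider = provider_cost_delta(country, headache_type, horizon_years=5)
                societal = societal_cost_delta(provider, country, headache_type, eff)
                assert societal.additional_cost <= provider.additional_cost

    def test_saving_monotone_in_wage(self):
        import dataclasses

        country = make_country(wage=10.0)
        savings = []
        for wage in (10.0, 20.0, 40.0):
            c = dataclasses.replace(country, wage_per_workday=wage)
            eff = hlys_gained(c, "migraine")
            provider = provider_cost_delta(c, "migraine")
            societal = societal_cost_delta(provider, c, "migraine", eff)
            savings.append(-societal.additional_cost)
        assert savings == sorted(savings)
        assert savings[0] < savings[-1]


class TestLinearityAndRecurrence:
    def test_doubling_patients_doubles_every_component(self):
        small = make_country(n=500, implementation_cost=7.0)
        large = make_country(n=1000, implementation_cost=7.0)
        d_small = provider_cost_delta(small, "migraine", horizon_years=5)
        d_large = provider_cost_delta(large, "migraine", horizon_years=5)
        for key, value in d_small.components.items():
            assert d_large.components[key] == pytest.approx(2 * value, rel=1e-12)

    def test_five_year_recurrent_identity(self):
        for seed in range(5):
            country = generate_country("large-high-income", seed)
            for headache_type in country.params_by_type:
                d1 = provider_cost_delta(country, headache_type, horizon_years=1)
                d5 = provider_cost_delta(country, headache_type, horizon_years=5)
                impl = d1.components["implementation"]
                assert d5.components["implementation"] == pytest.approx(impl)
                assert d5.additional_cost - impl == pytest.approx(
                    5 * (d1.additional_cost - impl), rel=1e-12
                )

    def test_discounting_reduces_recurrent_but_not_implementation(self):
        country = make_country(
            current=make_scenario(coverage=0.3, adherence=0.4, medication=20),
            target=make_scenario(coverage=0.9, adherence=0.8, medication=60),
            implementation_cost=5.0,
        )
        plain = provider_cost_delta(country, "migraine", horizon_years=5)
        discounted = provider_cost_delta(
            country, "migraine", horizon_years=5, discount_rate=0.05
        )
        assert discounted.components["implementation"] == pytest.approx(
            plain.components["implementation"]
        )
        assert abs(discounted.additional_cost - discounted.components["implementation"]) < abs(
            plain.additional_cost - plain.components["implementation"]
        )
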