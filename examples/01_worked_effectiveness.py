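"""HLYs gained for a toy cohort, step by step.

A cohort of 1000 migraine patients moves from current care (coverage 0.30,
adherence 0.40) toward target care (0.90, 0.80), with each gap half-closed.
Untreated patients spend 10% of the year in ill health; effective treatment
averts half of that.
"""
from headache_cea import (
    CareScenario,
    CountryParameters,
    GapClosurePolicy,
    HeadacheTypeParameters,
    hlys_gained,
)


def scenario(coverage, adherence):
    return CareScenario(
        coverage=coverage, adherence=adherence,
        annual_medication_cost=0, gp_visits=0, specialist_visits=0,
        examinations=0, unit_cost_gp=0, unit_cost_specialist=0,
        unit_cost_examination=0,
    )


country = CountryParameters(
    country_id="example",
    population=10_000,
    patients={"migraine": 1000},
    gdp_per_capita=30_000,
    wage_per_workday=100,
    params_by_type={
        "migraine": HeadacheTypeParameters(
            headache_type="migraine",
            disability_time_fraction=0.10,
            treatment_effect=0.5,
            current=scenario(0.30, 0.40),
            target=scenario(0.90, 0.80),
            workdays_lost_per_patient_year=5,
            implementation_cost_per_patient=0,
        )
    },
)

for horizon in (1, 5):
    res = hlys_gained(country, "migraine", GapClosurePolicy(), horizon)
    print(
        f"{horizon}-year horizon: effectively treated fraction "
        f"{res.effective_fraction_current:.2f} -> {res.effective_fraction_achieved:.2f}, "
        f"HLYs gained = {res.hlys_gained:.1f}"
    )

print(
    "\nThe effectively treated fraction rises from 0.30*0.40 = 0.12 to "
    "0.60*0.60 = 0.36 (each gap half-closed); the cohort recovers "
    "1000 * 0.24 * 0.10 * 0.5 = 12 healthy life years per year."
)
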