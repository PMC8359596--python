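"""Full evaluation of one synthetic country, rendered like a results table.

Generates a large high-income archetype, evaluates all three headache
types over 1- and 5-year horizons from both perspectives, and prints the
markdown table. Migraine requires investment (a defined ICER, lower at 5
years because the one-time implementation cost is spread over more health
gain); TTH and MOH are cost saving; societally everything is dominant.
"""
from headache_cea import WHOThresholds, generate_country, render_tables, run_full_evaluation

country = generate_country("large-high-income", seed=1)
report = run_full_evaluation(
    country, WHOThresholds(gdp_per_capita=country.gdp_per_capita)
)
print(f"wage {country.wage_per_workday:.0f} euros/day, "
      f"GDP per capita {country.gdp_per_capita:,.0f} euros\n")
print(render_tables(report, "markdown"))
print("Cells with 'n/a' ICERs are cost saving (dominant): more health for "
      "less money. Defined ICERs are euros invested per healthy life year "
      "gained, judged against 1x and 3x GDP per capita.")
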