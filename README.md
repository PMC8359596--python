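# headache-cea

Decision-analytic cost-effectiveness modelling of **structured headache
services** — primary-care-based headache care supported by provider
training and consumer education — for migraine, tension-type headache
(TTH) and medication-overuse headache (MOH).

The package is for health economists and public-health analysts who want
to compare *current* (suboptimal) care with *target* care (structured
services implemented) in a country, from the health-care **provider** and
the **societal** perspective, over 1- and 5-year horizons.

## The model

For each headache type with `N` patients, effectiveness is measured in
healthy life years (HLYs) gained:

```
f            = coverage × adherence              (effectively treated fraction)
f_achieved   : each gap closed part-way, by default 50%:
               coverage'  = c + 0.5 (c_target − c)
               adherence' = a + 0.5 (a_target − a)
ΔHLY         = N · (f_achieved − f_current) · d · e · Y
```

where `d` is the fraction of a year an untreated patient spends in ill
health, `e` the proportion of that time averted by effective treatment,
and `Y` the horizon in years.

Provider-perspective additional cost counts medicines, GP visits,
specialist visits and examinations, plus a one-time per-patient
implementation charge `I` in year 1:

```
ΔC_provider = N · (f_achieved · c_target − f_current · c_current) · Y + N·I
```

with `c_·` the annual per-patient cost of each scenario's resource use.
The societal perspective additionally values recovered lost productivity
by the human-capital approach:

```
ΔC_societal = ΔC_provider − ρ · w · N · (f_achieved − f_current) · e · L · Y
```

with wage `w` (euros/workday), `L` lost workdays per patient-year, and
`ρ` the recoverable fraction of lost productivity (1.0 baseline, 0.2
conservative).

Cost-effectiveness is the incremental cost-effectiveness ratio
`ICER = ΔC / ΔHLY` (euros per HLY gained), classified against WHO
GDP-per-capita thresholds: `ICER < 1×GDP` highly cost-effective,
`< 3×GDP` cost-effective (strict). Cells with positive health gain at
non-positive cost are *cost saving* (dominant) and report no ICER.

Because the original study's country inputs are not published, the
package ships (a) a fixture of the published provider-perspective results
for Luxembourg, Russia and Spain (18 cells), used as an
internal-consistency oracle, and (b) a synthetic parameter generator with
three documented country archetypes (`small-high-wage`,
`large-high-income`, `large-middle-income`) for exercising the forward
model end to end.

## Worked example

```python
from headache_cea import WHOThresholds, generate_country, run_full_evaluation

country = generate_country("large-high-income", seed=1)
report = run_full_evaluation(country, WHOThresholds(gdp_per_capita=country.gdp_per_capita))
print(report.to_dataframe()[["headache_type", "horizon_years", "perspective",
                             "additional_cost", "hlys_gained", "icer", "who_category"]])
```

prints (abridged):

```
headache_type  horizon_years perspective  additional_cost  hlys_gained    icer           who_category
     migraine              1    provider     3.489671e+08     53569.45  6514.0  highly_cost_effective
     migraine              1    societal    -1.439356e+09     53569.45     NaN               dominant
     migraine              5    provider     1.458584e+09    267847.24  5446.0  highly_cost_effective
          tth              1    provider    -1.543884e+08     32878.57     NaN               dominant
          moh              1    provider     5.304476e+07     29598.36  1792.0  highly_cost_effective
```

Migraine needs investment (ICER well below 1×GDP, and lower at 5 years
because the one-time implementation cost is spread over more health
gain); TTH is cost saving even for the provider; societally every cell is
dominant. The `examples/` directory holds one short script per
capability — the worked effectiveness arithmetic, a full evaluation
rendered as a results table, the printed-tables consistency check, a
sensitivity sweep with break-even factor, and per-1000-patient
normalization with the wage ordering of societal savings.

A thin CLI wraps the same calls:

```bash
headache-cea check-tables                 # verify the published tables' ICER arithmetic
headache-cea run --archetype small-high-wage --seed 5 --gdp 90000
headache-cea sensitivity --cost 215273678 --hlys 163709 --gdp 45000
```

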