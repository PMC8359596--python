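# Methods

## Model structure

The package implements a deterministic cohort decision model comparing
two static care arrangements — *current* (suboptimal) care and *target*
care (structured headache services, implemented through provider training
and consumer education) — for three headache types: migraine,
tension-type headache (TTH) and medication-overuse headache (MOH). There
is no individual-level simulation and no state-transition dynamics: each
cell of the analysis (country × headache type × horizon × perspective) is
a closed-form product of its inputs.

### Effectiveness

The *effectively treated fraction* of a patient population is
`f = coverage × adherence`: adherence is conditional on being reached by
care, so the two channels compose multiplicatively. Implementation does
not fully close the treatment gaps. Provider training moves coverage, and
consumer education moves adherence, each a fraction of the way from the
current to the target value (default 0.5 for both, independently
settable via `GapClosurePolicy` — they are separate mechanisms).

Health gain over horizon `Y` years for `N` patients is

    ΔHLY = N · (f_achieved − f_current) · d · e · Y

with `d` the disability time fraction (share of a year an untreated
patient spends in ill health, 0–1) and `e` the treatment effect (share of
that time averted in an effectively treated patient, 0–1, as established
in randomised trials). This is a DALY-averted-style product: the minimal
model consistent with measuring effectiveness as healthy life years
gained in a WHO-CHOICE-lineage framework. It implies the gain cannot
exceed `N · Y · d` (one cannot restore more healthy time than is lost)
and is exactly zero when the gap or the effect is zero.

The multi-year gain is a static per-year rate times years. The published
5-year figures are *not* linear multiples of the 1-year figures, which
indicates type-specific dynamics (e.g. relapse and re-accumulation in
MOH) encoded in analytical models whose details are not recoverable from
the source text; this package deliberately carries all type-specific
structure in the parameter values instead, and the nonlinearity of the
1- vs 5-year ICERs through front-loaded implementation cost (below).

### Costs

Provider perspective: medicines, GP visits, specialist visits and
examinations. Each care scenario specifies annual per-patient resource
use for an *effectively treated* patient plus unit costs. Patients who
are not effectively treated consume the same background resources under
either arm, so those costs net out of the difference; the recurrent
annual delta per patient is `f_achieved·c_target − f_current·c_current`
(the source description of partial gap closure admits more than one
cost-mixing reading; this is the one under which the stated incremental
formula holds, and it is what the package implements). The one-time
per-patient implementation cost (training + education allocation) is
charged in year 1 only. This front-loading is the only mechanism in the
model that makes 5-year ICERs lower than 1-year ICERs, matching the
published pattern.

Societal perspective adds lost productivity, valued by the human-capital
approach with no friction period: recovered workdays per year are
`N · (f_achieved − f_current) · e · L` (with `L` lost workdays per
patient-year), valued at the daily wage `w`, of which only a fraction
`ρ ∈ [0,1]` is assumed recoverable. Baseline `ρ = 1.0` (all
headache-attributed lost productivity recovered commensurately with
disability); conservative scenario `ρ = 0.2`. With `ρ = 0` the societal
delta equals the provider delta exactly; productivity can only reduce net
cost.

No discounting is applied by default (the evaluation framework does not
discount), but every cost/effectiveness entry point accepts an annual
`discount_rate` that weights year *t* by `1/(1+r)^(t−1)` identically for
recurrent costs and health gains; the one-time implementation cost (year
1) is never discounted.

### Cost-effectiveness

`ICER = ΔC / ΔHLY`, euros per HLY gained, defined only when both are
positive. Positive gain at non-positive cost is *cost saving* (dominant);
no ICER is reported for such cells — the raw quotient is uninterpretable
and suppressed, with the dominance flag carried programmatically. ICERs
are displayed rounded to the nearest integer euro, half away from zero;
full precision is retained internally. All eighteen published
provider-perspective cells are internally consistent under exactly this
rounding rule.

WHO GDP-per-capita thresholds: `ICER < 1×GDP` highly cost-effective,
`< 3×GDP` cost-effective, with **strict** inequalities (boundary equality
is not cost-effective). GDP per capita is always a user input, never
bundled as fact. One-way sensitivity analysis inflates health-care costs
(×F) or deflates health gains (÷F); the two distortions move the ICER
identically, which the suite checks as an algebraic property. The
break-even cost factor has the closed form `3×GDP / ICER` (infinite for
dominant cells, zero for cells with no gain) and is cross-checked against
a bisection search.

Per-1000-patient normalization multiplies every extensive quantity
(costs, components, HLYs, workdays) by `1000/N`; the ICER is invariant,
which makes countries of very different size comparable.

## Synthetic parameter generator

The study's actual country inputs (prevalences, efficacies, unit costs,
wages, resource-use patterns) live in survey data and a companion costing
exercise and are not published; no generated number claims to be a real
national statistic. The generator instead targets the *structure* of
those inputs with three archetypes ordered by wage and size —
`small-high-wage`, `large-high-income`, `large-middle-income` — with all
draws uniform within published band tables (`ARCHETYPE_RANGES`,
`SHARED_RANGES`, `TYPE_RANGES` in `headache_cea.synthetic`).

Design choices, made once:

* **Disjoint wage bands** (200–300, 90–150, 15–40 euros/workday) force
  the archetype wage ordering for any pair of seeds.
* **Wage-proportional price index.** All monetary draws are expressed at
  a reference wage (110 euros/day) and scaled by
  `wage / reference wage`: health-care prices track wage levels across
  economies. GDP per capita is drawn as a wage multiple (250–400,
  roughly annual workdays times labour share).
* **Common random numbers.** The RNG stream is a pure function of the
  seed, with a fixed draw order; the archetype selects only the bands.
  Archetypes at the same seed therefore share uniform quantiles, the
  standard variance-reduction device for scenario comparison — the
  cross-archetype contrast in societal savings is then exactly the wage
  scaling, not sampling noise.
* **Type-specific economics.** Migraine target care *adds* resources to
  current care (prophylaxis, structured follow-up: additive band
  add-ons), so its provider delta is structurally positive. TTH target
  care multiplies current resource use by a small factor (0.08–0.18:
  consumer education displaces consultations and medication), and MOH
  target care withdraws overused medication (0.15–0.35 multiplier on
  medication with modest specialist input) — both typically cost saving,
  as in the published pattern. Disability and productivity bands make
  indirect costs dominate direct costs (as cost-of-illness studies of
  headache consistently find): migraine 10–18 lost workdays/patient-year,
  MOH 15–30, TTH 1–3.

Patient counts are population × type prevalence (migraine 10–15%, TTH
15–25%, MOH 1–2%), rounded.

What the generator does **not** emulate: correlation between a country's
coverage gap and its income level, headache-type comorbidity/overlap
within patients, non-uniform (e.g. skewed) parameter distributions, and
any real country's actual values. Passing forward-model tests therefore
demonstrates internal correctness and the claimed qualitative orderings
under plausible conditions, not agreement with any real-world dataset.

## Published-results fixture

`headache_cea/data/tables123.csv` encodes the published
provider-perspective results for Luxembourg, Russia and Spain (three
types × two horizons; patient numbers, additional costs, HLYs gained,
printed ICER, with cost-saving cells stored as a negative cost plus a
`cost_saving` sentinel). The loader validates the full 3×3×2 grid and
every row invariant, and round-trips byte-exactly. The fixture is the
oracle for the ICER arithmetic: printed cost ÷ printed HLYs, rounded to
the nearest euro, reproduces all six printed migraine ICERs (2192, 1548,
1315, 1394, 2225, 1514), and all twelve TTH/MOH cells classify as cost
saving.

## Numerical choices and degenerate inputs

* Tolerances: oracle-equivalence checks compare at relative 1e-9;
  identities that are algebraically exact but accumulate one extra
  floating-point rounding (term-wise vs sum-wise scaling by 5) are
  checked at relative 1e-12.
* `ICER` display rounding is half-away-from-zero (`floor(x+0.5)` for
  positive x), not banker's rounding.
* Zero-gap or zero-effect inputs give exactly 0 HLYs and a `no_gain`
  flag, which maps to `not_cost_effective` (nothing is bought, so nothing
  can be cost-effective).
* Zero additional cost with positive gain counts as cost saving
  (dominance boundary).
* Seeds: any Python integer is accepted; values are wrapped into the
  RNG's accepted range deterministically.
* Problem sizes in the test and acceptance runs — ~100 generated
  parameter sets for the equivalence property, 25 seeds for the wage
  ordering, 20–30 seeds elsewhere — were chosen as the smallest sizes at
  which the checked properties are exercised across all archetypes and
  types; every computation is closed-form, so runs complete in seconds.

## Known limitations

* Single-formula effectiveness model: no type-specific decision-tree
  dynamics, no headache-type interconversion (e.g. MOH reverting to
  migraine after withdrawal), no epidemiological turnover over the
  5-year horizon.
* Human-capital productivity costing only: no friction-cost method, no
  absenteeism/presenteeism split, no informal-care costs.
* Deterministic sensitivity analysis only (one-way inflation/deflation
  and break-even factors); no probabilistic sensitivity analysis or
  acceptability curves, and no country-specific opportunity-cost
  thresholds beyond the WHO GDP multiples.
* The forward model cannot be validated against the published absolute
  numbers, because the inputs behind them are unpublished; validation is
  by internal consistency of the published tables plus property-based
  acceptance of the forward model.
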