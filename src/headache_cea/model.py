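"""Core domain types for headache-service cost-effectiveness modelling.

The model compares *current* (suboptimal) care with *target* care
(structured headache services implemented through provider training and
consumer education) for three headache types -- migraine, tension-type
headache (TTH) and medication-overuse headache (MOH) -- in one country.

All monetary quantities are denominated in a single currency-year
(by convention 2020 euros).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "HEADACHE_TYPES",
    "CareScenario",
    "HeadacheTypeParameters",
    "CountryParameters",
    "GapClosurePolicy",
    "ProductivityPolicy",
    "WHOThresholds",
    "EffectivenessResult",
    "CostDelta",
    "CEAResult",
    "UnknownHeadacheTypeError",
]

#: Canonical (lower-case) labels of the modelled headache types.
HEADACHE_TYPES: tuple[str, ...] = ("migraine", "tth", "moh")

#: Cost component labels used in every :class:`CostDelta`.
COST_COMPONENTS: tuple[str, ...] = (
    "medicines",
    "gp_visits",
    "specialist_visits",
    "examinations",
    "implementation",
    "productivity",
)


class UnknownHeadacheTypeError(KeyError):
    """Raised when an operation is asked about a headache type it does not know."""

    def __init__(self, headache_type: str, known: tuple[str, ...] = HEADACHE_TYPES):
        self.headache_type = headache_type
        self.known = known
        super().__init__(
            f"unknown headache type {headache_type!r}; known types: {', '.join(known)}"
        )

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


def canonical_headache_type(label: str) -> str:
    """Map a label such as ``'TTH'`` or ``'Migraine'`` to its canonical form."""
    low = str(label).strip().lower()
    if low not in HEADACHE_TYPES:
        raise UnknownHeadacheTypeError(label)
    return low


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValueError(message)


def _check_proportion(value: float, name: str) -> None:
    _require(0.0 <= value <= 1.0, f"{name} must lie in [0, 1], got {value!r}")


def _check_nonneg(value: float, name: str) -> None:
    _require(value >= 0.0, f"{name} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class CareScenario:
    """Coverage, adherence and per-patient resource use of one care arrangement.

    ``coverage`` is the proportion of patients reached by appropriate care and
    ``adherence`` the proportion of reached patients who use it effectively.
    Resource-use fields describe the annual consumption of an *effectively
    treated* patient; unit costs are in euros.
    """

    coverage: float
    adherence: float
    annual_medication_cost: float
    gp_visits: float
    specialist_visits: float
    examinations: float
    unit_cost_gp: float
    unit_cost_specialist: float
    unit_cost_examination: float

    def __post_init__(self) -> None:
        _check_proportion(self.coverage, "coverage")
        _check_proportion(self.adherence, "adherence")
        for name in (
            "annual_medication_cost",
            "gp_visits",
            "specialist_visits",
            "examinations",
            "unit_cost_gp",
            "unit_cost_specialist",
            "unit_cost_examination",
        ):
            _check_nonneg(getattr(self, name), name)


@dataclass(frozen=True)
class HeadacheTypeParameters:
    """Epidemiological, clinical and cost inputs for one headache type.

    Parameters
    ----------
    disability_time_fraction
        Proportion of one year an untreated patient spends in ill health
        (dimensionless, 0-1).
    treatment_effect
        Proportion of that ill-health time averted in an effectively treated
        patient (0-1); efficacy as established in randomised controlled trials.
    current, target
        The two care arrangements being compared.
    workdays_lost_per_patient_year
        Headache-attributed lost workdays (absenteeism plus presenteeism
        equivalents) per untreated patient per year.
    implementation_cost_per_patient
        One-time per-patient cost of setting up structured services
        (provider-training and consumer-education allocation), euros.
    """

    headache_type: str
    disability_time_fraction: float
    treatment_effect: float
    current: CareScenario
    target: CareScenario
    workdays_lost_per_patient_year: float
    implementation_cost_per_patient: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "headache_type", canonical_headache_type(self.headache_type)
        )
        _check_proportion(self.disability_time_fraction, "disability_time_fraction")
        _check_proportion(self.treatment_effect, "treatment_effect")
        _check_nonneg(
            self.workdays_lost_per_patient_year, "workdays_lost_per_patient_year"
        )
        _check_nonneg(
            self.implementation_cost_per_patient, "implementation_cost_per_patient"
        )
        _require(
            self.target.coverage >= self.current.coverage,
            f"target coverage ({self.target.coverage}) must be >= current "
            f"coverage ({self.current.coverage}) for {self.headache_type}",
        )
        _require(
            self.target.adherence >= self.current.adherence,
            f"target adherence ({self.target.adherence}) must be >= current "
            f"adherence ({self.current.adherence}) for {self.headache_type}",
        )


@dataclass(frozen=True)
class CountryParameters:
    """Complete parameter set for one country.

    ``patients`` maps each headache type to its patient count (types may
    overlap within the population, but no single type can exceed the
    population and the total cannot exceed three times the population).
    """

    country_id: str
    population: int
    patients: Mapping[str, int]
    gdp_per_capita: float
    wage_per_workday: float
    params_by_type: Mapping[str, HeadacheTypeParameters]

    def __post_init__(self) -> None:
        _require(self.population > 0, f"population must be > 0, got {self.population}")
        _require(
            self.gdp_per_capita > 0,
            f"gdp_per_capita must be > 0, got {self.gdp_per_capita}",
        )
        _require(
            self.wage_per_workday > 0,
            f"wage_per_workday must be > 0, got {self.wage_per_workday}",
        )
        patients = {canonical_headache_type(k): int(v) for k, v in self.patients.items()}
        object.__setattr__(self, "patients", patients)
        for h, n in patients.items():
            _check_nonneg(n, f"patients[{h}]")
            _require(
                n <= self.population,
                f"patients[{h}] = {n} exceeds population {self.population}",
            )
        _require(
            sum(patients.values()) <= 3 * self.population,
            "total patient count exceeds 3 x population",
        )
        by_type = {
            canonical_headache_type(k): v for k, v in self.params_by_type.items()
        }
        object.__setattr__(self, "params_by_type", by_type)
        _require(
            set(by_type) == set(patients),
            "patients and params_by_type must cover the same headache types",
        )
        for h, p in by_type.items():
            _require(
                p.headache_type == h,
                f"params_by_type[{h}] holds parameters for {p.headache_type}",
            )

    def type_params(self, headache_type: str) -> HeadacheTypeParameters:
        return self.params_by_type[canonical_headache_type(headache_type)]

    def n_patients(self, headache_type: str) -> int:
        return self.patients[canonical_headache_type(headache_type)]

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        def scenario(s: CareScenario) -> dict[str, float]:
            return {f: getattr(s, f) for f in s.__dataclass_fields__}

        return {
            "schema": "headache-cea/country-parameters/v1",
            "currency_year": "2020 euros",
            "country_id": self.country_id,
            "population": self.population,
            "gdp_per_capita": self.gdp_per_capita,
            "wage_per_workday": self.wage_per_workday,
            "patients": dict(self.patients),
            "params_by_type": {
                h: {
                    "disability_time_fraction": p.disability_time_fraction,
                    "treatment_effect": p.treatment_effect,
                    "workdays_lost_per_patient_year": p.workdays_lost_per_patient_year,
                    "implementation_cost_per_patient": p.implementation_cost_per_patient,
                    "current": scenario(p.current),
                    "target": scenario(p.target),
                }
                for h, p in self.params_by_type.items()
            },
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "CountryParameters":
        params_by_type = {
            h: HeadacheTypeParameters(
                headache_type=h,
                disability_time_fraction=d["disability_time_fraction"],
                treatment_effect=d["treatment_effect"],
                workdays_lost_per_patient_year=d["workdays_lost_per_patient_year"],
                implementation_cost_per_patient=d["implementation_cost_per_patient"],
                current=CareScenario(**d["current"]),
                target=CareScenario(**d["target"]),
            )
            for h, d in data["params_by_type"].items()
        }
        return cls(
            country_id=data["country_id"],
            population=int(data["population"]),
            patients={h: int(n) for h, n in data["patients"].items()},
            gdp_per_capita=float(data["gdp_per_capita"]),
            wage_per_workday=float(data["wage_per_workday"]),
            params_by_type=params_by_type,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CountryParameters":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CountryParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class GapClosurePolicy:
    """How far target care closes the coverage and adherence gaps.

    The intervention conservatively closes each gap halfway: provider
    training moves coverage, and consumer education moves adherence, each by
    50% of the distance between current and target care.
    """

    coverage_closure: float = 0.5
    adherence_closure: float = 0.5

    def __post_init__(self) -> None:
        _check_proportion(self.coverage_closure, "coverage_closure")
        _check_proportion(self.adherence_closure, "adherence_closure")


@dataclass(frozen=True)
class ProductivityPolicy:
    """Fraction of headache-attributed lost workdays recoverable by treatment.

    ``recovery_fraction`` (rho) is 1.0 at baseline (all lost productivity is
    explained by headache-attributed disability and recovered commensurately)
    and 0.2 in the conservative scenario (disability explains only 20% of
    lost productivity, so only that share can be recovered).
    """

    recovery_fraction: float = 1.0

    def __post_init__(self) -> None:
        _check_proportion(self.recovery_fraction, "recovery_fraction")


@dataclass(frozen=True)
class WHOThresholds:
    """WHO GDP-per-capita cost-effectiveness thresholds.

    An ICER below ``highly_ce_multiple`` x GDP per capita per HLY gained is
    highly cost-effective; below ``ce_multiple`` x GDP, cost-effective
    (strict inequalities).
    """

    gdp_per_capita: float
    highly_ce_multiple: float = 1.0
    ce_multiple: float = 3.0

    def __post_init__(self) -> None:
        _require(
            self.gdp_per_capita > 0,
            f"gdp_per_capita must be > 0, got {self.gdp_per_capita}",
        )
        _require(
            0 < self.highly_ce_multiple < self.ce_multiple,
            "thresholds must satisfy 0 < highly_ce_multiple < ce_multiple",
        )


@dataclass(frozen=True)
class EffectivenessResult:
    """Healthy life years gained in one (country, headache type, horizon) cell."""

    country_id: str
    headache_type: str
    horizon_years: float
    hlys_gained: float
    effective_fraction_current: float
    effective_fraction_achieved: float

    def __post_init__(self) -> None:
        _check_proportion(
            self.effective_fraction_current, "effective_fraction_current"
        )
        _check_proportion(
            self.effective_fraction_achieved, "effective_fraction_achieved"
        )
        if self.effective_fraction_achieved >= self.effective_fraction_current:
            _require(
                self.hlys_gained >= -1e-12,
                "hlys_gained must be >= 0 when the achieved effective fraction "
                "is at least the current one",
            )


@dataclass(frozen=True)
class CostDelta:
    """Additional cost of target vs current care for one cell.

    ``additional_cost`` is in euros; a negative value is a cost saving.
    ``components`` decomposes it into medicines, GP visits, specialist
    visits, examinations, one-time implementation and (societal perspective
    only) productivity; the components always sum to the total.
    """

    country_id: str
    headache_type: str
    horizon_years: float
    perspective: str
    additional_cost: float
    components: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require(
            self.perspective in ("provider", "societal"),
            f"perspective must be 'provider' or 'societal', got {self.perspective!r}",
        )
        comps = dict(self.components)
        unknown = set(comps) - set(COST_COMPONENTS)
        _require(not unknown, f"unknown cost components: {sorted(unknown)}")
        if comps:
            total = sum(comps.values())
            scale = max(1.0, abs(self.additional_cost))
            _require(
                abs(total - self.additional_cost) <= 1e-6 * scale,
                f"components sum to {total}, not additional_cost="
                f"{self.additional_cost}",
            )
            if self.perspective == "provider":
                _require(
                    comps.get("productivity", 0.0) == 0.0,
                    "productivity component must be 0 under the provider perspective",
                )
        object.__setattr__(self, "components", comps)

    def scaled(self, factor: float) -> "CostDelta":
        """Return a copy with every extensive quantity multiplied by ``factor``."""
        return replace(
            self,
            additional_cost=self.additional_cost * factor,
            components={k: v * factor for k, v in self.components.items()},
        )


@dataclass(frozen=True)
class CEAResult:
    """Cost-effectiveness verdict for one cell.

    ``icer`` (euros per HLY gained) is defined only when additional cost and
    HLYs gained are both positive; otherwise ``dominance`` records whether
    the intervention is cost saving (dominant) or yields no health gain.
    ``break_even_cost_factor`` is the largest multiplier by which health-care
    costs could be inflated while the intervention stays at least
    cost-effective under the WHO thresholds (infinite for dominant cells).
    """

    country_id: str
    headache_type: str
    horizon_years: float
    perspective: str
    dominance: str
    who_category: str
    icer: float | None = None
    break_even_cost_factor: float | None = None

    def __post_init__(self) -> None:
        _require(
            self.dominance in ("icer_defined", "cost_saving", "no_gain"),
            f"invalid dominance flag {self.dominance!r}",
        )
        _require(
            self.who_category
            in ("highly_cost_effective", "cost_effective", "not_cost_effective", "dominant"),
            f"invalid WHO category {self.who_category!r}",
        )
        if self.dominance != "icer_defined":
            _require(self.icer is None, "icer must be absent unless icer_defined")
        _require(
            (self.who_category == "dominant") == (self.dominance == "cost_saving"),
            "who_category is 'dominant' exactly when dominance is 'cost_saving'",
        )
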