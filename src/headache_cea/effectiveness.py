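"""Effectiveness of moving a population from current to target care.

Health gain is measured in healthy life years (HLYs). For a headache type
with N patients, the model is a DALY-averted-style product:

    HLYs gained = N * (f_achieved - f_current) * d * e * Y

where ``f`` is the *effectively treated fraction* (coverage x adherence),
``d`` the fraction of a year an untreated patient spends in ill health,
``e`` the proportion of that ill-health time averted by effective treatment,
and ``Y`` the horizon in years. Target care does not fully close the
treatment gaps: coverage (via provider training) and adherence (via consumer
education) each move only part-way from current to target, by default 50% of
each gap.
"""
from __future__ import annotations

from .model import (
    CountryParameters,
    EffectivenessResult,
    GapClosurePolicy,
    canonical_headache_type,
)

__all__ = [
    "apply_gap_closure",
    "effective_fraction",
    "achieved_fractions",
    "horizon_factor",
    "hlys_gained",
]


def apply_gap_closure(current_value: float, target_value: float, closure: float) -> float:
    """Move ``closure`` of the way from ``current_value`` to ``target_value``.

    All arguments are proportions in [0, 1]; ``target_value`` must be at
    least ``current_value``. The result lies in
    ``[current_value, target_value]``.
    """
    for name, v in (
        ("current_value", current_value),
        ("target_value", target_value),
        ("closure", closure),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
    if target_value < current_value:
        raise ValueError(
            f"scenario ordering violated: target_value ({target_value}) < "
            f"current_value ({current_value})"
        )
    return current_value + closure * (target_value - current_value)


def effective_fraction(coverage: float, adherence: float) -> float:
    """Fraction of patients effectively treated: coverage x adherence.

    Adherence is conditional on being reached by care, so the two channels
    combine multiplicatively.
    """
    for name, v in (("coverage", coverage), ("adherence", adherence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
    return coverage * adherence


def achieved_fractions(
    params: CountryParameters, headache_type: str, policy: GapClosurePolicy
) -> tuple[float, float]:
    """Effectively treated fractions (current, achieved) for one headache type.

    The achieved fraction is the effective fraction after partially closing
    both the coverage and the adherence gap per ``policy``.
    """
    p = params.type_params(headache_type)
    f_current = effective_fraction(p.current.coverage, p.current.adherence)
    coverage = apply_gap_closure(
        p.current.coverage, p.target.coverage, policy.coverage_closure
    )
    adherence = apply_gap_closure(
        p.current.adherence, p.target.adherence, policy.adherence_closure
    )
    return f_current, effective_fraction(coverage, adherence)


def horizon_factor(horizon_years: int, discount_rate: float = 0.0) -> float:
    """Sum of per-year weights over the horizon.

    With the default zero discount rate this is simply ``horizon_years``
    (a static per-year rate times years). A positive ``discount_rate`` r
    weights year t (t = 1..Y) by 1/(1+r)^(t-1); it applies identically to
    recurrent costs and to health gains.
    """
    if not (isinstance(horizon_years, (int,)) and horizon_years >= 1):
        raise ValueError(f"horizon_years must be an integer >= 1, got {horizon_years!r}")
    if discount_rate < 0:
        raise ValueError(f"discount_rate must be >= 0, got {discount_rate!r}")
    if discount_rate == 0.0:
        return float(horizon_years)
    return sum((1.0 + discount_rate) ** -t for t in range(horizon_years))


def hlys_gained(
    params: CountryParameters,
    headache_type: str,
    policy: GapClosurePolicy | None = None,
    horizon_years: int = 1,
    discount_rate: float = 0.0,
) -> EffectivenessResult:
    """HLYs gained by the change from current to target care.

    Parameters
    ----------
    params
        Country parameter set.
    headache_type
        One of ``migraine``, ``tth``, ``moh`` (case-insensitive).
    policy
        Gap-closure policy; defaults to 50% closure on both channels.
    horizon_years
        Time frame (the study uses 1 and 5 years).
    discount_rate
        Optional annual discount rate applied to health gains in later years
        (default 0: no discounting).
    """
    headache_type = canonical_headache_type(headache_type)
    if policy is None:
        policy = GapClosurePolicy()
    p = params.type_params(headache_type)
    n = params.n_patients(headache_type)
    f_current, f_achieved = achieved_fractions(params, headache_type, policy)
    years = horizon_factor(horizon_years, discount_rate)
    gained = (
        n
        * (f_achieved - f_current)
        * p.disability_time_fraction
        * p.treatment_effect
        * years
    )
    return EffectivenessResult(
        country_id=params.country_id,
        headache_type=headache_type,
        horizon_years=horizon_years,
        hlys_gained=gained,
        effective_fraction_current=f_current,
        effective_fraction_achieved=f_achieved,
    )
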