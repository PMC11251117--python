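"""Adverse-event and mortality probabilities per model cycle.

Stroke risk combines the cohort's CHA2DS2-VASc score distribution with
annual stroke probabilities per score and a health-state relative risk.
Heart-failure onset uses general-population age-banded incidence rates with
a health-state relative risk.  All-cause death composes (on the annual rate
scale) general mortality — already net of stroke/HF deaths — with the
case-fatality share of the stroke and HF event rates, then converts to a
3-month probability under a constant within-cycle hazard.
"""

from __future__ import annotations

import math

from .params import EventInputs, ValidationError


def rate_to_probability(rate: float, period_years: float) -> float:
    """Probability of at least one event in ``period_years`` at constant hazard."""
    if rate < 0:
        raise ValidationError(f"rate must be >= 0: got {rate}")
    if period_years <= 0:
        raise ValidationError(f"period_years must be > 0: got {period_years}")
    return 1.0 - math.exp(-rate * period_years)


def probability_to_rate(prob: float, period_years: float) -> float:
    """Inverse of :func:`rate_to_probability`."""
    if not 0 <= prob < 1:
        raise ValidationError(f"probability must be in [0, 1): got {prob}")
    return -math.log(1.0 - prob) / period_years


def _age_points(age: float) -> int:
    # CHA2DS2-VASc age component: +1 at 65-74, +2 at >= 75
    if age >= 75:
        return 2
    if age >= 65:
        return 1
    return 0


def cha2ds2vasc_at_age(distribution: list[float], start_age: float, age: float) -> list[float]:
    """Shift the score distribution for ageing past 65 and 75.

    The baseline distribution describes the cohort at its starting age; the
    age component of the score is advanced as the cohort crosses the 65 and
    75 year thresholds (scores clipped at 9).
    """
    shift = _age_points(age) - _age_points(start_age)
    if shift <= 0:
        return list(distribution)
    out = [0.0] * 10
    for score, mass in enumerate(distribution):
        out[min(9, score + shift)] += mass
    return out


def annual_stroke_probability(
    age: float, state: str, ev: EventInputs, start_age: float
) -> float:
    """Score-averaged annual stroke probability times the state relative risk."""
    dist = cha2ds2vasc_at_age(ev.cha2ds2vasc_distribution, start_age, age)
    if abs(sum(dist) - 1.0) > 1e-9:
        raise ValidationError("cha2ds2vasc_distribution does not sum to 1")
    base = sum(p * q for p, q in zip(dist, ev.stroke_risk_by_score))
    return min(1.0, base * ev.stroke_rr_by_state.get(state, 1.0))


def stroke_probability(
    age: float, state: str, ev: EventInputs, start_age: float, period_years: float = 0.25
) -> float:
    """Per-cycle stroke probability for an alive health state."""
    q = annual_stroke_probability(age, state, ev, start_age)
    return 1.0 - (1.0 - q) ** period_years


def annual_hf_rate(age: float, state: str, ev: EventInputs) -> float:
    """Age-banded annual heart-failure incidence rate times the state RR.

    Ages beyond the last band are clamped to it.
    """
    if not ev.hf_incidence_by_age:
        return 0.0
    rate = ev.hf_incidence_by_age[0][1]
    for age_lo, r in ev.hf_incidence_by_age:
        if age >= age_lo:
            rate = r
    return rate * ev.hf_rr_by_state.get(state, 1.0)


def hf_probability(
    age: float, state: str, ev: EventInputs, period_years: float = 0.25
) -> float:
    """Per-cycle probability of incident heart failure."""
    return rate_to_probability(annual_hf_rate(age, state, ev), period_years)


def general_mortality_rate(age: float, fraction_female: float, ev: EventInputs) -> float:
    """Sex-weighted annual background mortality rate (net of stroke/HF deaths)."""
    if not ev.general_mortality:
        raise ValidationError("general_mortality table is empty")
    row = ev.general_mortality[0]
    for cand in ev.general_mortality:
        if age >= cand[0]:
            row = cand
    return fraction_female * row[1] + (1 - fraction_female) * row[2]


def compose_mortality(
    age: float,
    fraction_female: float,
    state: str,
    ev: EventInputs,
    start_age: float | None = None,
    period_years: float = 0.25,
) -> float:
    """Per-cycle all-cause death probability for one health state.

    Annual all-cause rate = general rate + stroke rate x stroke case
    fatality + HF rate x HF case fatality, where the event probabilities are
    first expressed as annual rates.  The composed rate is converted to a
    cycle probability under a constant hazard.
    """
    start_age = age if start_age is None else start_age
    general = general_mortality_rate(age, fraction_female, ev)
    stroke_q = annual_stroke_probability(age, state, ev, start_age)
    stroke_rate = -math.log(1.0 - stroke_q) if stroke_q < 1 else float("inf")
    hf_rate = annual_hf_rate(age, state, ev)
    total = general + stroke_rate * ev.stroke_case_fatality + hf_rate * ev.hf_case_fatality
    return rate_to_probability(total, period_years)
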