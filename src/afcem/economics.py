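"""Discounted cost and QALY accounting plus comparative outcomes.

Costs fall into five categories — initial procedure, re-ablations,
healthcare contacts, pharmaceuticals, and AF-related adverse events — and
are accrued per cycle at start-of-cycle occupancy (no half-cycle
correction), each weighted by ``(1 + r)^(-t)`` at the cycle's start time.
Pharmaceutical per-cycle costs apply to all alive states in both arms,
which is the attribution implied by the published cost breakdown (the
drug-arm-to-ablation-arm ratio of the pharmaceutical totals equals the
ratio of the per-cycle prices times the discounted survival).

Prevalent post-stroke and heart-failure fractions are carried forward from
the incident-event tallies: survivors of an incident event (one minus the
case fatality) join a tracking fraction that decays with the cohort's
overall per-cycle survival and accrues ongoing costs and long-term
disutilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort_model import CohortTrace, DEATH, state_occupancy_years
from .params import (
    CONTACT_TYPES,
    NYHA_CLASSES,
    STROKE_SEVERITIES,
    ParameterSet,
    ValidationError,
)

DOMINANT = "Dominant"
DOMINATED = "Dominated"


def discount_factor(time_years: float, annual_rate: float) -> float:
    """Present-value factor ``(1 + r)^(-t)`` (continuous times allowed)."""
    if annual_rate < 0:
        raise ValidationError(f"annual_rate must be >= 0: got {annual_rate}")
    return (1.0 + annual_rate) ** (-time_years)


@dataclass
class EconResult:
    arm: str
    cost_initial_procedure: float = 0.0
    cost_reablations: float = 0.0
    cost_healthcare_contacts: float = 0.0
    cost_pharma: float = 0.0
    cost_ae: float = 0.0
    qalys_total: float = 0.0
    life_years_discounted: float = 0.0
    life_years: float = 0.0
    state_years: dict[str, float] = field(default_factory=dict)
    strokes_lifetime: float = 0.0
    hf_lifetime: float = 0.0
    reablations_12m: float = 0.0
    reablations_lifetime: float = 0.0
    undiscounted_cost_total: float = 0.0

    @property
    def cost_total(self) -> float:
        return (
            self.cost_initial_procedure
            + self.cost_reablations
            + self.cost_healthcare_contacts
            + self.cost_pharma
            + self.cost_ae
        )


@dataclass
class ComparativeResult:
    delta_cost: float
    delta_qalys: float
    icer: float | None
    dominance: str | None
    nmb: float
    threshold: float

    @property
    def icer_label(self) -> str:
        if self.dominance is not None:
            return self.dominance
        if self.icer is None:
            return "undefined"
        return f"{self.icer:,.0f}"


def _prevalence_series(incident: np.ndarray, survivors_frac: float,
                       split: np.ndarray, cohort_survival: np.ndarray) -> np.ndarray:
    """Prevalent fractions (cycles x classes) carried forward from incidence."""
    n = len(incident)
    prev = np.zeros((n, len(split)))
    running = np.zeros(len(split))
    for t in range(n):
        prev[t] = running
        running = running * cohort_survival[t] + incident[t] * survivors_frac * split
    return prev


def accumulate_economics(trace: CohortTrace, p: ParameterSet, arm: str | None = None) -> EconResult:
    """Fold a cohort trace into discounted costs by category and QALYs."""
    arm = arm or trace.arm
    s = p.settings
    c = p.costs
    ev = p.events
    u = p.utilities
    n = trace.n_cycles
    cy = trace.cycle_years
    occ = trace.occupancy
    if len(trace.events) != n:
        raise ValidationError("trace events and occupancy are inconsistent")

    t_years = np.arange(n) * cy
    df_c = (1.0 + s.discount_rate_costs) ** (-t_years)
    df_q = (1.0 + s.discount_rate_qalys) ** (-t_years)

    alive = 1.0 - occ[:, DEATH]
    # per-cycle survival of the alive cohort, for decaying prevalent fractions
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.where(alive[:-1] > 0, alive[1:] / alive[:-1], 0.0)

    events = trace.events
    strokes = events["strokes"].to_numpy()
    hf = events["hf_onsets"].to_numpy()
    reabl = events["reablations"].to_numpy()

    sev_split = np.asarray(ev.stroke_severity_split)
    nyha_split = np.asarray(ev.hf_nyha_split)
    post_stroke = _prevalence_series(strokes, 1 - ev.stroke_case_fatality, sev_split, surv)
    hf_prev = _prevalence_series(hf, 1 - ev.hf_case_fatality, nyha_split, surv)

    res = EconResult(arm=arm)
    res.cost_initial_procedure = c.index_procedure if arm == "cryo" else 0.0
    res.cost_reablations = float(np.sum(reabl * c.reablation_procedure * df_c))

    contact_cost = np.zeros(n)
    for t in CONTACT_TYPES:
        contact_cost += events[t].to_numpy() * c.contact_unit_cost(t)
    res.cost_healthcare_contacts = float(np.sum(contact_cost * df_c))

    res.cost_pharma = float(np.sum(alive[:-1] * c.pharma_per_cycle[arm] * df_c))

    stroke_event_cost = float(np.dot(sev_split, [c.stroke_event[s_] for s_ in STROKE_SEVERITIES]))
    hf_cycle_cost = np.array([c.hf_per_cycle[k] for k in NYHA_CLASSES])
    ae_cost = (
        strokes * stroke_event_cost
        + post_stroke.sum(axis=1) * c.stroke_followup_per_cycle
        + hf_prev @ hf_cycle_cost
    )
    res.cost_ae = float(np.sum(ae_cost * df_c))

    # QALYs: state utility minus prevalent and incident adverse-event decrements
    base_u = np.array([
        u.baseline(p.demographics.start_age + t * cy, p.demographics.fraction_female)
        for t in range(n)
    ])
    ho = trace.health_occupancy().iloc[:-1]
    state_util = np.zeros(n)
    for h in ("NSR", "ST_EPISODIC", "LT_PERSISTENT", "PERMANENT"):
        state_util += ho[h].to_numpy() * (base_u - u.state_decrements.get(h, 0.0))
    st_dec = np.array([u.stroke_short_term[s_] for s_ in STROKE_SEVERITIES])
    lt_dec = np.array([u.stroke_long_term[s_] for s_ in STROKE_SEVERITIES])
    hf_dec = np.array([u.hf_decrements[k] for k in NYHA_CLASSES])
    decrements = (
        strokes * float(np.dot(sev_split, st_dec))
        + post_stroke @ lt_dec
        + hf_prev @ hf_dec
    )
    res.qalys_total = float(np.sum((state_util - decrements) * cy * df_q))
    res.life_years_discounted = float(np.sum(alive[:-1] * cy * df_q))
    res.life_years = float(np.sum(alive[:-1] * cy))
    res.state_years = state_occupancy_years(trace, discounted=False)

    res.strokes_lifetime = float(np.sum(strokes))
    res.hf_lifetime = float(np.sum(hf))
    tc = s.tree_cycles
    res.reablations_12m = float(np.sum(reabl[:tc]))
    res.reablations_lifetime = float(np.sum(reabl))

    und_contact = float(np.sum(contact_cost))
    res.undiscounted_cost_total = (
        res.cost_initial_procedure
        + float(np.sum(reabl)) * c.reablation_procedure
        + und_contact
        + float(np.sum(alive[:-1])) * c.pharma_per_cycle[arm]
        + float(np.sum(ae_cost))
    )
    return res


def compare_arms(
    intervention: EconResult, comparator: EconResult, threshold: float
) -> ComparativeResult:
    """Incremental outcomes oriented intervention minus comparator."""
    dc = intervention.cost_total - comparator.cost_total
    dq = intervention.qalys_total - comparator.qalys_total
    dominance = None
    icer = None
    if dc < 0 and dq > 0:
        dominance = DOMINANT
    elif dc > 0 and dq < 0:
        dominance = DOMINATED
    elif dq != 0:
        icer = dc / dq
    nmb = dq * threshold - dc
    return ComparativeResult(
        delta_cost=dc, delta_qalys=dq, icer=icer, dominance=dominance,
        nmb=nmb, threshold=threshold,
    )


def events_avoided_metrics(
    intervention: EconResult, comparator: EconResult, event: str
) -> tuple[float, float]:
    """Number needed to treat and cost per event avoided.

    ``NNT = 1 / (rate_comparator - rate_intervention)``: positive when the
    intervention avoids events.  Cost per event avoided is ``-delta_cost x
    NNT`` so that a cost-saving, event-avoiding intervention reports a
    positive figure (the published presentation).
    """
    attr = {"stroke": "strokes_lifetime", "heart_failure": "hf_lifetime",
            "reablation": "reablations_lifetime"}[event]
    diff = getattr(comparator, attr) - getattr(intervention, attr)
    if diff == 0:
        return math.inf, math.inf
    nnt = 1.0 / diff
    delta_cost = intervention.cost_total - comparator.cost_total
    return nnt, -delta_cost * nnt
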