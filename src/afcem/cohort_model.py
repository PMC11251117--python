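"""Hybrid decision-tree / Markov cohort engine.

Structure: a one-year decision-tree phase (four 3-month cycles with
year-one transition inputs) allocates the cohort across normal sinus
rhythm (NSR) and ST-episodic AF with ablation-count sub-states, followed
by a Markov phase to the 40-year horizon over the full state space

    NSR-{0..3}, ST_EPISODIC-{0..3}, LT_PERSISTENT-{0..3}, PERMANENT, DEATH

The sub-state records ablations beyond the index procedure in the
cryoablation arm and total ablations in the drug arm; with a cap of three
total ablations the cryoablation arm can never occupy the count-3
sub-states.  DEATH is absorbing and PERMANENT admits no return to rhythm
control.  Age-dependent mortality makes the transition matrix cycle
varying.  No half-cycle correction is applied (see ``ModelSettings``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import events_mortality as em
from .params import ParameterSet, ValidationError, CONTACT_TYPES

# state indexing: NSR-k -> k, ST-k -> 4+k, LT-k -> 8+k, PERM -> 12, DEATH -> 13
N_STATES = 14
NSR0, ST0, LT0, PERM, DEATH = 0, 4, 8, 12, 13

STATE_LABELS = (
    [f"NSR:{k}" for k in range(4)]
    + [f"ST_EPISODIC:{k}" for k in range(4)]
    + [f"LT_PERSISTENT:{k}" for k in range(4)]
    + ["PERMANENT", "DEATH"]
)

_HEALTH_OF_STATE = (
    ["NSR"] * 4 + ["ST_EPISODIC"] * 4 + ["LT_PERSISTENT"] * 4 + ["PERMANENT", "DEATH"]
)

EVENT_COLUMNS = ("reablations", "strokes", "hf_onsets") + CONTACT_TYPES


def state_index(health: str, count: int | None = None) -> int:
    if health == "DEATH":
        return DEATH
    if health == "PERMANENT":
        return PERM
    base = {"NSR": NSR0, "ST_EPISODIC": ST0, "LT_PERSISTENT": LT0}[health]
    if count is None or not 0 <= count <= 3:
        raise ValidationError(f"invalid ablation count {count!r} for {health}")
    return base + count


def health_of(index: int) -> str:
    return _HEALTH_OF_STATE[index]


def max_substate(arm: str, max_total_ablations: int) -> int:
    """Highest reachable ablation-count sub-state for an arm.

    The cryoablation index procedure counts toward the total, so its
    sub-states (which exclude the index ablation) cap one lower.
    """
    if arm == "cryo":
        return min(3, max_total_ablations - 1)
    return min(3, max_total_ablations)


@dataclass
class StateSpace:
    arm: str
    max_total_ablations: int = 3

    @property
    def cap(self) -> int:
        return max_substate(self.arm, self.max_total_ablations)

    @property
    def forbidden(self) -> list[int]:
        out = []
        for base in (NSR0, ST0, LT0):
            out.extend(base + k for k in range(self.cap + 1, 4))
        return out

    @property
    def labels(self) -> list[str]:
        return list(STATE_LABELS)


@dataclass
class CohortTrace:
    """Occupancy per cycle boundary plus per-cycle expected event tallies."""

    arm: str
    occupancy: np.ndarray  # (n_cycles + 1, N_STATES), rows sum to 1
    events: pd.DataFrame  # one row per cycle, EVENT_COLUMNS
    state_space: StateSpace = field(repr=False, default=None)
    cycle_years: float = 0.25

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def alive(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, DEATH]

    def health_occupancy(self) -> pd.DataFrame:
        """Occupancy aggregated over sub-states, one column per health state."""
        occ = self.occupancy
        return pd.DataFrame(
            {
                "NSR": occ[:, NSR0:NSR0 + 4].sum(axis=1),
                "ST_EPISODIC": occ[:, ST0:ST0 + 4].sum(axis=1),
                "LT_PERSISTENT": occ[:, LT0:LT0 + 4].sum(axis=1),
                "PERMANENT": occ[:, PERM],
                "DEATH": occ[:, DEATH],
            }
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (cycle, state)."""
        rows = []
        for t in range(self.occupancy.shape[0]):
            for s, label in enumerate(STATE_LABELS):
                health, _, count = label.partition(":")
                rows.append(
                    {
                        "cycle": t,
                        "state": health,
                        "substate": int(count) if count else None,
                        "occupancy": self.occupancy[t, s],
                    }
                )
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# cycle assembly


def _cycle_inputs(p: ParameterSet, arm: str, cycle: int):
    cl = p.clinical.per_arm[arm]
    in_tree = cycle < p.settings.tree_cycles
    if in_tree:
        y1 = cl.year1
        return dict(
            recurrence=y1.recurrence,
            resolution=y1.resolution,
            prog_st_lt=y1.progression_st_lt,
            prog_lt_perm=cl.progression_lt_perm,
            uptake_st=y1.reablation_uptake,
            uptake_lt=y1.reablation_uptake,
            success=y1.reablation_success,
        )
    return dict(
        recurrence=cl.recurrence,
        resolution=cl.resolution,
        prog_st_lt=cl.progression_st_lt,
        prog_lt_perm=cl.progression_lt_perm,
        uptake_st=cl.reablation_uptake_st,
        uptake_lt=cl.reablation_uptake_lt,
        success=cl.reablation_success,
    )


def build_cycle(p: ParameterSet, arm: str, cycle: int):
    """Transition matrix plus per-state event-probability tallies for one cycle.

    Within-cycle ordering: death competes first; among survivors a
    re-ablation (from ST-episodic or LT-persistent, below the arm's cap)
    resolves to NSR on success or stays with the sub-state incremented on
    failure; non-ablated mass follows recurrence / resolution / progression.
    """
    s = p.settings
    cy = s.cycle_years
    age = p.demographics.start_age + cycle * cy
    ffem = p.demographics.fraction_female
    ev = p.events
    ci = _cycle_inputs(p, arm, cycle)
    rr_rec = p.clinical.rr_recurrence_by_count
    rr_res = p.clinical.rr_resolution_by_count
    rr_suc = p.clinical.rr_success_by_count
    cap = max_substate(arm, s.max_total_ablations)

    death_q = {}
    stroke_q = {}
    hf_q = {}
    for h in ("NSR", "ST_EPISODIC", "LT_PERSISTENT", "PERMANENT"):
        death_q[h] = em.compose_mortality(
            age, ffem, h, ev, start_age=p.demographics.start_age, period_years=cy
        )
        stroke_q[h] = em.stroke_probability(
            age, h, ev, p.demographics.start_age, period_years=cy
        )
        hf_q[h] = em.hf_probability(age, h, ev, period_years=cy)

    M = np.zeros((N_STATES, N_STATES))
    reablation_p = np.zeros(N_STATES)
    stroke_p = np.zeros(N_STATES)
    hf_p = np.zeros(N_STATES)

    def clip01(x: float) -> float:
        return min(1.0, max(0.0, x))

    for k in range(4):
        # NSR-k
        i = NSR0 + k
        d = death_q["NSR"]
        rec = clip01(ci["recurrence"] * rr_rec[k])
        M[i, ST0 + k] = (1 - d) * rec
        M[i, i] = (1 - d) * (1 - rec)
        M[i, DEATH] = d
        stroke_p[i] = stroke_q["NSR"]
        hf_p[i] = hf_q["NSR"]

        # ST-k
        i = ST0 + k
        d = death_q["ST_EPISODIC"]
        u = ci["uptake_st"] if k < cap else 0.0
        suc = clip01(ci["success"] * rr_suc[k])
        res = clip01(ci["resolution"] * rr_res[k])
        prog = ci["prog_st_lt"]
        if res + prog > 1:
            raise ValidationError(
                f"resolution + progression exceed 1 in state ST:{k} ({arm})"
            )
        if u > 0:
            M[i, NSR0 + k + 1] += (1 - d) * u * suc
            M[i, ST0 + k + 1] += (1 - d) * u * (1 - suc)
        M[i, NSR0 + k] += (1 - d) * (1 - u) * res
        M[i, LT0 + k] += (1 - d) * (1 - u) * prog
        M[i, i] += (1 - d) * (1 - u) * (1 - res - prog)
        M[i, DEATH] = d
        reablation_p[i] = (1 - d) * u
        stroke_p[i] = stroke_q["ST_EPISODIC"]
        hf_p[i] = hf_q["ST_EPISODIC"]

        # LT-k
        i = LT0 + k
        d = death_q["LT_PERSISTENT"]
        u = ci["uptake_lt"] if k < cap else 0.0
        suc = clip01(ci["success"] * rr_suc[k])
        progp = ci["prog_lt_perm"]
        if u > 0:
            M[i, NSR0 + k + 1] += (1 - d) * u * suc
            M[i, LT0 + k + 1] += (1 - d) * u * (1 - suc)
        M[i, PERM] += (1 - d) * (1 - u) * progp
        M[i, i] += (1 - d) * (1 - u) * (1 - progp)
        M[i, DEATH] = d
        reablation_p[i] = (1 - d) * u
        stroke_p[i] = stroke_q["LT_PERSISTENT"]
        hf_p[i] = hf_q["LT_PERSISTENT"]

    d = death_q["PERMANENT"]
    M[PERM, PERM] = 1 - d
    M[PERM, DEATH] = d
    stroke_p[PERM] = stroke_q["PERMANENT"]
    hf_p[PERM] = hf_q["PERMANENT"]
    M[DEATH, DEATH] = 1.0

    rows = M.sum(axis=1)
    if np.max(np.abs(rows - 1.0)) > 1e-8:
        bad = int(np.argmax(np.abs(rows - 1.0)))
        raise ValidationError(
            f"transition row {STATE_LABELS[bad]} sums to {rows[bad]!r} at cycle {cycle}"
        )

    # contact rates, broadcast from health state to sub-states
    cl = p.clinical.per_arm[arm]
    table = cl.year1_contact_rates if cycle < s.tree_cycles else cl.contact_rates
    contacts = {t: np.zeros(N_STATES) for t in CONTACT_TYPES}
    for h, row in table.items():
        idx = {"NSR": range(NSR0, NSR0 + 4),
               "ST_EPISODIC": range(ST0, ST0 + 4),
               "LT_PERSISTENT": range(LT0, LT0 + 4),
               "PERMANENT": [PERM]}[h]
        for t, v in row.items():
            for i in idx:
                contacts[t][i] = v

    tallies = {"reablations": reablation_p, "strokes": stroke_p, "hf_onsets": hf_p}
    tallies.update(contacts)
    return M, tallies


def build_transition_matrix(p: ParameterSet, arm: str, cycle: int) -> np.ndarray:
    """The (14, 14) row-stochastic transition matrix for one arm and cycle."""
    M, _ = build_cycle(p, arm, cycle)
    return M


# --------------------------------------------------------------------------
# running


def _parse_allocation(alloc: dict[str, float]) -> np.ndarray:
    v = np.zeros(N_STATES)
    for key, mass in alloc.items():
        health, _, count = key.partition(":")
        v[state_index(health, int(count) if count else None)] = mass
    if abs(v.sum() - 1.0) > 1e-9:
        raise ValidationError(f"year-1 allocation sums to {v.sum()!r}, expected 1")
    return v


def initial_occupancy() -> np.ndarray:
    """Cohort entry state: symptomatic paroxysmal AF, no re-ablations yet."""
    v = np.zeros(N_STATES)
    v[ST0] = 1.0
    return v


def _propagate(p, arm, occ, events, t0, t1):
    for t in range(t0, t1):
        M, tall = build_cycle(p, arm, t)
        for name in EVENT_COLUMNS:
            events[name][t] = float(occ[t] @ tall[name])
        occ[t + 1] = occ[t] @ M


def run_decision_tree(p: ParameterSet, arm: str):
    """Occupancy at 12 months plus year-one event tallies.

    If the arm carries an explicit ``year1_allocation`` the vector is a
    validated pass-through (tree treated as a black box and its event
    tallies taken as zero unless configured); otherwise the four tree
    cycles are simulated from the entry state.
    """
    cl = p.clinical.per_arm[arm]
    tc = p.settings.tree_cycles
    if cl.year1_allocation is not None:
        vec = _parse_allocation(cl.year1_allocation)
        tallies = {name: np.zeros(tc) for name in EVENT_COLUMNS}
        return vec, pd.DataFrame(tallies)
    occ = np.zeros((tc + 1, N_STATES))
    occ[0] = initial_occupancy()
    events = {name: np.zeros(tc) for name in EVENT_COLUMNS}
    _propagate(p, arm, occ, events, 0, tc)
    return occ[tc], pd.DataFrame(events)


def run_markov(
    initial: np.ndarray, p: ParameterSet, arm: str, start_cycle: int | None = None
) -> CohortTrace:
    """Propagate an occupancy vector from ``start_cycle`` to the horizon."""
    s = p.settings
    start = s.tree_cycles if start_cycle is None else start_cycle
    n = s.n_cycles
    if abs(float(np.sum(initial)) - 1.0) > 1e-9:
        raise ValidationError("initial occupancy must sum to 1")
    occ = np.zeros((n + 1, N_STATES))
    occ[start] = initial
    for t in range(start):
        occ[t] = initial  # padding; callers slicing from start_cycle ignore it
    events = {name: np.zeros(n) for name in EVENT_COLUMNS}
    _propagate(p, arm, occ, events, start, n)
    return CohortTrace(arm=arm, occupancy=occ, events=pd.DataFrame(events),
                       state_space=StateSpace(arm, s.max_total_ablations),
                       cycle_years=s.cycle_years)


def run_arm(p: ParameterSet, arm: str) -> CohortTrace:
    """Full run: decision-tree year then Markov phase, one continuous trace."""
    s = p.settings
    n = s.n_cycles
    tc = s.tree_cycles
    occ = np.zeros((n + 1, N_STATES))
    events = {name: np.zeros(n) for name in EVENT_COLUMNS}
    cl = p.clinical.per_arm[arm]
    if cl.year1_allocation is not None:
        occ[0] = initial_occupancy()
        for t in range(1, tc):
            occ[t] = occ[0]
        occ[tc] = _parse_allocation(cl.year1_allocation)
    else:
        occ[0] = initial_occupancy()
        _propagate(p, arm, occ, events, 0, tc)
    _propagate(p, arm, occ, events, tc, n)
    trace = CohortTrace(arm=arm, occupancy=occ, events=pd.DataFrame(events),
                        state_space=StateSpace(arm, s.max_total_ablations),
                        cycle_years=s.cycle_years)
    forbidden = trace.state_space.forbidden
    if forbidden and np.max(np.abs(occ[:, forbidden])) > 0:
        raise ValidationError(f"mass leaked into forbidden sub-states for arm {arm}")
    return trace


def state_occupancy_years(
    trace: CohortTrace, discounted: bool = False, rate: float = 0.03
) -> dict[str, float]:
    """Years spent per health state (aggregated over sub-states).

    Start-of-cycle occupancy is credited a full cycle length (no half-cycle
    correction); the final boundary row is not counted.
    """
    cy = trace.cycle_years
    occ = trace.health_occupancy().iloc[:-1]
    t_years = np.arange(len(occ)) * cy
    w = (1.0 + rate) ** (-t_years) if discounted else np.ones_like(t_years)
    out = {}
    for h in ("NSR", "ST_EPISODIC", "LT_PERSISTENT", "PERMANENT"):
        out[h] = float(np.sum(occ[h].to_numpy() * w) * cy)
    return out
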