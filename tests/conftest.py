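import copy

import pytest

import afcem
from afcem.params import ParameterSet


@pytest.fixture(scope="session")
def base_params() -> ParameterSet:
    return afcem.base_case()


@pytest.fixture(scope="session")
def det_results(base_params):
    """Deterministic two-arm base-case run, shared across tests."""
    return afcem.run_deterministic(base_params)


def make_degenerate(base: ParameterSet, *, zero_costs: bool = False,
                    mortality_rate: float = 0.0, horizon_years: float | None = None,
                    utility: float | None = None) -> ParameterSet:
    """A parameter set with all clinical and event dynamics switched off.

    The cohort then sits in its entry state forever, which gives closed-form
    expectations for costs, QALYs and occupancy.
    """
    d = base.to_dict()
    for arm in d["clinical"]["per_arm"].values():
        for k in ("recurrence", "resolution", "progression_st_lt",
                  "progression_lt_perm", "reablation_uptake_st",
                  "reablation_uptake_lt"):
            arm[k] = 0.0
        for k in ("recurrence", "resolution", "progression_st_lt", "reablation_uptake"):
            arm["year1"][k] = 0.0
        for tbl in ("contact_rates", "year1_contact_rates"):
            for row in arm[tbl].values():
                for t in row:
                    row[t] = 0.0
    ev = d["events"]
    ev["stroke_risk_by_score"] = [0.0] * 10
    ev["hf_incidence_by_age"] = [[40, 0.0]]
    ev["stroke_case_fatality"] = 0.0
    ev["hf_case_fatality"] = 0.0
    ev["general_mortality"] = [[40, mortality_rate, mortality_rate]]
    if zero_costs:
        c = d["costs"]
        for k in ("reablation_procedure", "cv_hospitalisation", "ae_visit",
                  "outpatient", "cardioversion_pharm", "cardioversion_elec",
                  "stroke_followup_per_cycle"):
            c[k] = 0.0
        c["pharma_per_cycle"] = {"cryo": 0.0, "aad": 0.0}
        c["stroke_event"] = {k: 0.0 for k in c["stroke_event"]}
        c["hf_per_cycle"] = {k: 0.0 for k in c["hf_per_cycle"]}
    if horizon_years is not None:
        d["settings"]["horizon_years"] = horizon_years
    if utility is not None:
        d["utilities"]["baseline_by_age"] = [[40, utility, utility]]
        for key in ("state_decrements",):
            d["utilities"][key] = {k: 0.0 for k in d["utilities"][key]}
    return ParameterSet.from_dict(copy.deepcopy(d))
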