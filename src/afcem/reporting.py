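"""Result tables in the published layout, with render-time currency choice.

Rounding applies only at render: costs to whole currency units, QALYs and
years to 2 decimals, probabilities to 2 decimals; machine-readable
exports keep full precision.
"""

from __future__ import annotations

import pandas as pd

from .economics import ComparativeResult, EconResult
from .params import CurrencyRates, convert_currency
from .psa import PSAResults

ARM_TITLES = {"cryo": "Cryoablation", "aad": "AADs"}


def _cur(amount: float, currency: str, rates: CurrencyRates) -> float:
    if currency.upper() == "DKK":
        return convert_currency(amount, "EUR", "DKK", rates)
    return amount


def render_cost_breakdown(
    e_cryo: EconResult, e_aad: EconResult, currency: str = "EUR",
    rates: CurrencyRates | None = None, rounded: bool = True,
) -> pd.DataFrame:
    """Per-patient deterministic cost breakdown with the incremental column."""
    rates = rates or CurrencyRates()
    rows = [
        ("Initial procedure", "cost_initial_procedure"),
        ("Re-ablations", "cost_reablations"),
        ("Healthcare contact costs", "cost_healthcare_contacts"),
        ("Pharmaceutical costs", "cost_pharma"),
        ("AF-related adverse events", "cost_ae"),
        ("Total cost", "cost_total"),
        ("QALYs", "qalys_total"),
    ]
    table = []
    for label, attr in rows:
        a = getattr(e_cryo, attr)
        b = getattr(e_aad, attr)
        if attr != "qalys_total":
            a, b = _cur(a, currency, rates), _cur(b, currency, rates)
        if rounded:
            nd = 2 if attr == "qalys_total" else 0
            a, b = round(a, nd), round(b, nd)
            inc = round(a - b, nd)
        else:
            inc = a - b
        table.append({"Outcome": label, ARM_TITLES["cryo"]: a,
                      ARM_TITLES["aad"]: b, "Incremental": inc})
    return pd.DataFrame(table)


def render_additional_results(
    e_cryo: EconResult, e_aad: EconResult,
    stroke_metrics: tuple[float, float] | None = None,
    hf_metrics: tuple[float, float] | None = None,
    rounded: bool = True,
) -> pd.DataFrame:
    """State-occupancy years, lifetime event rates and re-ablation counts."""
    def row(label, a, b, nd=2, extra=None):
        if rounded:
            a, b = round(a, nd), round(b, nd)
            inc = round(a - b, nd)
        else:
            inc = a - b
        out = {"Parameter": label, ARM_TITLES["cryo"]: a, ARM_TITLES["aad"]: b,
               "Incremental": inc, "Cost per event avoided": None, "NNT": None}
        if extra:
            out["Cost per event avoided"], out["NNT"] = extra
        return out

    state_labels = {
        "NSR": "Normal sinus rhythm",
        "ST_EPISODIC": "Short-term episodic AF",
        "LT_PERSISTENT": "Long-term persistent AF",
        "PERMANENT": "Permanent AF",
    }
    rows = [
        row(state_labels[h], e_cryo.state_years[h], e_aad.state_years[h])
        for h in state_labels
    ]
    stroke_extra = None
    if stroke_metrics:
        nnt, cpe = stroke_metrics
        stroke_extra = (round(cpe) if rounded else cpe, round(nnt) if rounded else nnt)
    hf_extra = None
    if hf_metrics:
        nnt, cpe = hf_metrics
        hf_extra = (round(cpe) if rounded else cpe, round(nnt) if rounded else nnt)
    rows.append(row("Stroke", e_cryo.strokes_lifetime, e_aad.strokes_lifetime, 3,
                    stroke_extra))
    rows.append(row("Heart failure", e_cryo.hf_lifetime, e_aad.hf_lifetime, 3,
                    hf_extra))
    rows.append(row("Re-ablations, 12 months", e_cryo.reablations_12m,
                    e_aad.reablations_12m))
    rows.append(row("Re-ablations, time horizon", e_cryo.reablations_lifetime,
                    e_aad.reablations_lifetime))
    return pd.DataFrame(rows)


def render_psa_summary(
    r: PSAResults, threshold: float | None = None, currency: str = "EUR",
    rates: CurrencyRates | None = None,
) -> pd.DataFrame:
    """Mean [95% CrI] costs and QALYs per arm plus incremental summaries."""
    rates = rates or CurrencyRates()
    s = r.summary()

    def fmt(block, money=False, nd=2):
        conv = (lambda x: _cur(x, currency, rates)) if money else (lambda x: x)
        nd_ = 0 if money else nd
        return (round(conv(block["mean"]), nd_),
                round(conv(block["cri_low"]), nd_),
                round(conv(block["cri_high"]), nd_))

    rows = []
    for arm in ("cryo", "aad"):
        m, lo, hi = fmt(s[f"cost_{arm}"], money=True)
        rows.append({"Outcome": f"Cost per patient ({ARM_TITLES[arm]})",
                     "Mean": m, "CrI low": lo, "CrI high": hi})
    for arm in ("cryo", "aad"):
        m, lo, hi = fmt(s[f"qalys_{arm}"])
        rows.append({"Outcome": f"QALYs per patient ({ARM_TITLES[arm]})",
                     "Mean": m, "CrI low": lo, "CrI high": hi})
    m, lo, hi = fmt(s["delta_cost"], money=True)
    rows.append({"Outcome": "Incremental cost", "Mean": m, "CrI low": lo, "CrI high": hi})
    m, lo, hi = fmt(s["delta_qalys"])
    rows.append({"Outcome": "Incremental QALYs", "Mean": m, "CrI low": lo, "CrI high": hi})
    m, lo, hi = fmt(s["nmb"], money=True)
    rows.append({"Outcome": "Net monetary benefit", "Mean": m, "CrI low": lo, "CrI high": hi})
    icer = s["icer"]
    rows.append({"Outcome": "ICER", "Mean": icer if isinstance(icer, str)
                 else round(icer), "CrI low": None, "CrI high": None})
    rows.append({"Outcome": "Probability cost-effective",
                 "Mean": round(r.probability_cost_effective(threshold), 4),
                 "CrI low": None, "CrI high": None})
    return pd.DataFrame(rows)


def render_scenario_table(
    scenario_results: pd.DataFrame, currency: str = "EUR",
    rates: CurrencyRates | None = None,
) -> pd.DataFrame:
    """Scenario rows as (label, incremental cost, incremental QALYs, ICER)."""
    rates = rates or CurrencyRates()
    out = []
    for _, r in scenario_results.iterrows():
        icer = r["result"]
        if r["icer"] is not None and not isinstance(r["icer"], str):
            icer = round(_cur(r["icer"], currency, rates))
        out.append({
            "Scenario": r["label"],
            "Incremental costs": round(_cur(r["delta_cost"], currency, rates)),
            "Incremental QALYs": round(r["delta_qalys"], 3),
            "ICER": icer,
        })
    return pd.DataFrame(out)


def comparative_summary(cmp_: ComparativeResult) -> dict:
    return {
        "delta_cost": cmp_.delta_cost,
        "delta_qalys": cmp_.delta_qalys,
        "icer": cmp_.icer_label,
        "nmb": cmp_.nmb,
        "threshold": cmp_.threshold,
    }
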