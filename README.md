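# afcem

A cost-effectiveness model comparing **first-line cryoballoon pulmonary
vein isolation** with **antiarrhythmic drug (AAD) therapy** for
symptomatic paroxysmal atrial fibrillation (PAF), from a Danish
healthcare perspective. The package is aimed at health economists and
methodologists who want a tested, scriptable re-implementation of this
class of decision-analytic model: a hybrid decision-tree / Markov cohort
structure with ablation-count sub-states, adverse-event and mortality
modules, discounted cost/QALY accounting, probabilistic sensitivity
analysis (PSA) and declarative scenario analyses — plus a synthetic
individual-patient-data (IPD) generator and GLM estimation layer that
stand in for the private trial data the original inputs were derived
from.

## The model

A cohort of 1,000 patients (starting age 58, 35% female) enters a
decision tree covering the first 12 months, then a Markov model with
3-month cycles to a 40-year horizon. Health states are

- **NSR** — normal sinus rhythm (no AF within a cycle),
- **ST-episodic** — at least one AF episode within a cycle,
- **LT-persistent** — AF sustained over ≥ 12 months,
- **permanent** — no further rhythm-control attempts,
- **death** (absorbing).

NSR, ST-episodic and LT-persistent each carry sub-states 0–3 counting
ablations beyond the index procedure (total ablations are capped at 3,
so the cryoablation arm — whose index procedure counts — can never reach
sub-state 3). Re-ablation is a within-cycle event with separate uptake
and success probabilities; success returns the patient to NSR with the
count incremented.

Stroke risk combines a CHA₂DS₂-VASc score distribution with per-score
annual probabilities and health-state relative risks; heart-failure
onset uses age-banded incidence. All-cause mortality composes background
mortality (net of stroke/HF deaths) with case-fatality shares of the
event rates on the annual-rate scale, converted to cycle probabilities
by `1 − exp(−r·Δt)`.

Outcomes per arm: discounted (3%/year) costs in five categories (initial
procedure, re-ablations, healthcare contacts, pharmaceuticals, AF-related
adverse events), QALYs, state-occupancy years, lifetime event and
re-ablation counts; comparatively: incremental cost-effectiveness ratio
(ICER) or dominance, net monetary benefit at €23,200/QALY, number needed
to treat and cost per event avoided. The PSA samples costs from gamma and
probabilities/utilities from beta distributions (moment-matched), with
optional jointly-normal regression coefficient blocks via Cholesky
factorisation, over 5,000 iterations by default.

## Worked example

```python
import afcem

p = afcem.base_case()                 # shipped Danish parameter fixture
res = afcem.run_deterministic(p)      # both arms through the cohort model
cmp_ = afcem.compare_arms(res["cryo"], res["aad"], p.settings.wtp_threshold)
print(f"cryo total cost €{res['cryo'].cost_total:,.0f}, "
      f"QALYs {res['cryo'].qalys_total:.2f}")
print(f"AAD  total cost €{res['aad'].cost_total:,.0f}, "
      f"QALYs {res['aad'].qalys_total:.2f}")
print(f"incremental: €{cmp_.delta_cost:,.0f}, {cmp_.delta_qalys:.3f} QALYs "
      f"-> {cmp_.icer_label}")
```

prints

```
cryo total cost €23,284, QALYs 13.60
AAD  total cost €25,938, QALYs 13.45
incremental: €-2,654, 0.146 QALYs -> Dominant
```

First-line cryoablation costs less and yields more QALYs than drug
therapy — it is *dominant*: the €4,554 index procedure is outweighed by
savings on re-ablations (€998 vs €4,184), healthcare contacts,
pharmaceuticals and adverse events over the horizon.

The same pipeline is scriptable from the shell:

```sh
afcem simulate-ipd --seed 42 --out ipd.csv     # synthetic patient-level data
afcem estimate --ipd ipd.csv --out inputs.yaml # GLM-adjusted model inputs
afcem run-deterministic --out results/         # deterministic tables
afcem run-psa --n 5000 --seed 7 --out results/ # PSA draws, summary, CEAC
afcem run-scenarios --out results/scenarios.csv
```

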