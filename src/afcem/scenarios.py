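"""Declarative scenario analyses.

Each scenario is a YAML document of path-addressed transformations over
the parameter set (set / scale / add), so new scenarios need data, not
code.  The shipped set mirrors the deterministic base case plus the 15
published variations (discount rates, blanking, alternative utility
decrements, cost and relative-risk perturbations, 10-year horizon).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import economics, psa
from .params import ParameterSet, ValidationError, validate_parameters

_NUMERIC = (int, float)


@dataclass
class ScenarioConfig:
    scenario_id: str
    label: str
    transforms: list[dict] = field(default_factory=list)
    note: str = ""

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            scenario_id=raw["scenario_id"],
            label=raw.get("label", raw["scenario_id"]),
            transforms=raw.get("transforms", []),
            note=raw.get("note", ""),
        )


def _apply_leaf(node, key, op: str, value):
    current = node[key]
    if isinstance(current, dict):
        for k in current:
            _apply_leaf(current, k, op, value)
        return
    if isinstance(current, list):
        for i in range(len(current)):
            _apply_leaf(current, i, op, value)
        return
    if not isinstance(current, _NUMERIC):
        raise ValidationError(f"cannot transform non-numeric leaf at {key!r}")
    if op == "set":
        node[key] = value
    elif op == "scale":
        if value <= 0:
            raise ValidationError("scale factors must be > 0")
        node[key] = current * value
    elif op == "add":
        node[key] = current + value
    else:
        raise ValidationError(f"unknown transform op {op!r}")


def _resolve(d: dict, path: str):
    parts = path.split(".")
    node = d
    for part in parts[:-1]:
        if isinstance(node, list):
            node = node[int(part)]
        elif part in node:
            node = node[part]
        else:
            raise ValidationError(f"unresolvable parameter path {path!r} at {part!r}")
    last = parts[-1]
    if isinstance(node, list):
        return node, int(last)
    if last not in node:
        raise ValidationError(f"unresolvable parameter path {path!r} at {last!r}")
    return node, last


def apply_scenario(p: ParameterSet, s: ScenarioConfig) -> ParameterSet:
    """A new parameter set with the scenario's transformations applied."""
    d = p.to_dict()
    for t in s.transforms:
        node, key = _resolve(d, t["path"])
        _apply_leaf(node, key, t.get("op", "set"), t.get("value"))
    out = ParameterSet.from_dict(d)
    report = validate_parameters(out)
    if report:
        raise ValidationError(
            f"scenario {s.scenario_id!r} produced an invalid parameter set:\n  "
            + "\n  ".join(report)
        )
    out.meta = dict(out.meta, scenario=s.scenario_id)
    return out


def shipped_scenarios() -> list[ScenarioConfig]:
    """The scenario files bundled with the package, base case first."""
    root = resources.files("afcem.data") / "scenarios"
    configs = []
    with resources.as_file(root) as folder:
        for f in sorted(Path(folder).glob("*.yaml")):
            configs.append(ScenarioConfig.from_yaml(f))
    configs.sort(key=lambda c: (c.scenario_id != "00_base_case", c.scenario_id))
    return configs


def run_scenarios(
    p: ParameterSet, configs: list[ScenarioConfig] | None = None
) -> pd.DataFrame:
    """Deterministic two-arm run per scenario; failures become flagged rows."""
    configs = shipped_scenarios() if configs is None else configs
    rows = []
    for s in configs:
        row = {"scenario_id": s.scenario_id, "label": s.label}
        try:
            ps = apply_scenario(p, s)
            res = psa.run_deterministic(ps)
            cmp_ = economics.compare_arms(res["cryo"], res["aad"],
                                          ps.settings.wtp_threshold)
            row.update(
                delta_cost=cmp_.delta_cost,
                delta_qalys=cmp_.delta_qalys,
                icer=cmp_.icer,
                result=cmp_.icer_label,
                nmb=cmp_.nmb,
                failed=False,
            )
        except Exception as exc:  # keep running the remaining scenarios
            row.update(delta_cost=float("nan"), delta_qalys=float("nan"),
                       icer=None, result=f"failed: {exc}", nmb=float("nan"),
                       failed=True)
        rows.append(row)
    return pd.DataFrame(rows)
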