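"""Model parameter container: loading, validation and currency handling.

All monetary inputs are held internally in EUR (the reporting currency);
DKK output is a presentation-layer conversion.  The shipped base-case
fixture carries the Danish unit costs and utility decrements together with
clinical transition inputs produced by the synthetic estimation pipeline
(flagged ``provenance: synthetic`` / ``assumed`` in the fixture file).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

logger = logging.getLogger(__name__)

HEALTH_STATES = ("NSR", "ST_EPISODIC", "LT_PERSISTENT", "PERMANENT", "DEATH")
ARMS = ("cryo", "aad")
CONTACT_TYPES = (
    "hospitalisation",
    "ae_visit",
    "outpatient",
    "cardioversion_pharm",
    "cardioversion_elec",
)
STROKE_SEVERITIES = ("non_disabling", "moderate", "severe")
NYHA_CLASSES = ("I", "II", "III", "IV")

_CURRENCIES = ("EUR", "DKK", "GBP")


class ConfigurationError(KeyError):
    """A mandatory configuration key is missing."""


class ValidationError(ValueError):
    """A parameter value violates its documented bounds."""


# --------------------------------------------------------------------------
# currency


@dataclass
class CurrencyRates:
    """Exchange rates with DKK as the pivot currency.

    ``dkk_to_eur_presentation`` is the rounded published rate (0.13) used
    only when explicitly requested for presentation; arithmetic conversions
    use the exact reciprocal of ``eur_to_dkk`` so that round trips are
    identities.
    """

    gbp_to_dkk: float = 8.73
    eur_to_dkk: float = 7.45
    dkk_to_eur_presentation: float = 0.13

    def to_dkk_rate(self, code: str) -> float:
        code = code.upper()
        if code == "DKK":
            return 1.0
        if code == "EUR":
            return self.eur_to_dkk
        if code == "GBP":
            return self.gbp_to_dkk
        raise ValidationError(f"unknown currency code {code!r}")


def convert_currency(
    amount: float, from_code: str, to_code: str, rates: CurrencyRates | None = None
) -> float:
    """Convert ``amount`` between EUR/GBP/DKK via the DKK pivot.

    Reversible: ``convert(convert(x, a, b), b, a) == x`` to floating
    tolerance, because the same pivot rate is used in both directions.
    """
    rates = rates or CurrencyRates()
    if from_code.upper() not in _CURRENCIES or to_code.upper() not in _CURRENCIES:
        raise ValidationError(
            f"unknown currency code in ({from_code!r}, {to_code!r})"
        )
    if from_code.upper() == to_code.upper():
        return amount
    dkk = amount * rates.to_dkk_rate(from_code)
    return dkk / rates.to_dkk_rate(to_code)


# --------------------------------------------------------------------------
# parameter blocks


@dataclass
class ModelSettings:
    cycle_length_months: int = 3
    horizon_years: float = 40.0
    decision_tree_years: float = 1.0
    discount_rate_costs: float = 0.03
    discount_rate_qalys: float = 0.03
    wtp_threshold: float = 23_200.0
    cohort_size: int = 1_000
    max_total_ablations: int = 3
    psa_iterations: int = 5_000
    currency: str = "EUR"
    half_cycle_correction: bool = False

    @property
    def cycles_per_year(self) -> int:
        return 12 // self.cycle_length_months

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon_years * self.cycles_per_year))

    @property
    def tree_cycles(self) -> int:
        return int(round(self.decision_tree_years * self.cycles_per_year))

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_months / 12.0


@dataclass
class Demographics:
    start_age: float = 58.0
    fraction_female: float = 0.35


@dataclass
class CostInputs:
    """Unit costs in EUR (per event, per visit or per 3-month cycle)."""

    index_procedure: float = 4_554.0
    reablation_procedure: float = 4_554.0
    cv_hospitalisation: float = 1_996.0
    ae_visit: float = 322.0
    outpatient: float = 59.0
    cardioversion_pharm: float = 1_314.0
    cardioversion_elec: float = 1_314.0
    pharma_per_cycle: dict[str, float] = field(
        default_factory=lambda: {"cryo": 64.0, "aad": 89.0}
    )
    stroke_event: dict[str, float] = field(
        default_factory=lambda: {s: 15_615.0 for s in STROKE_SEVERITIES}
    )
    stroke_followup_per_cycle: float = 756.0
    hf_per_cycle: dict[str, float] = field(
        default_factory=lambda: {c: 909.0 for c in NYHA_CLASSES}
    )

    def contact_unit_cost(self, contact_type: str) -> float:
        return {
            "hospitalisation": self.cv_hospitalisation,
            "ae_visit": self.ae_visit,
            "outpatient": self.outpatient,
            "cardioversion_pharm": self.cardioversion_pharm,
            "cardioversion_elec": self.cardioversion_elec,
        }[contact_type]


@dataclass
class UtilityInputs:
    # rows of [age_lo, utility_female, utility_male]; EQ-5D index scale
    baseline_by_age: list[list[float]] = field(default_factory=list)
    state_decrements: dict[str, float] = field(
        default_factory=lambda: {
            "NSR": 0.0,
            "ST_EPISODIC": 0.0,
            "LT_PERSISTENT": 0.08,
            "PERMANENT": 0.11,
        }
    )
    stroke_short_term: dict[str, float] = field(
        default_factory=lambda: {"non_disabling": 0.0, "moderate": 0.37, "severe": 0.65}
    )
    stroke_long_term: dict[str, float] = field(
        default_factory=lambda: {"non_disabling": 0.03, "moderate": 0.18, "severe": 0.36}
    )
    hf_decrements: dict[str, float] = field(
        default_factory=lambda: {"I": 0.0, "II": 0.07, "III": 0.16, "IV": 0.30}
    )

    def baseline(self, age: float, fraction_female: float) -> float:
        """Sex-weighted baseline utility at ``age`` (step function by band)."""
        if not self.baseline_by_age:
            raise ValidationError("baseline_by_age table is empty")
        row = self.baseline_by_age[0]
        for cand in self.baseline_by_age:
            if age >= cand[0]:
                row = cand
        return fraction_female * row[1] + (1 - fraction_female) * row[2]


@dataclass
class Year1Inputs:
    """Per-cycle transition inputs governing the four decision-tree cycles."""

    recurrence: float = 0.0
    resolution: float = 0.0
    progression_st_lt: float = 0.0
    reablation_uptake: float = 0.0
    reablation_success: float = 0.8


@dataclass
class ArmClinical:
    """Per-cycle clinical transition inputs for one treatment arm."""

    recurrence: float = 0.0  # NSR -> ST-episodic
    resolution: float = 0.0  # ST-episodic -> NSR without ablation
    progression_st_lt: float = 0.0
    progression_lt_perm: float = 0.0
    reablation_uptake_st: float = 0.0
    reablation_uptake_lt: float = 0.0
    reablation_success: float = 0.8
    year1: Year1Inputs = field(default_factory=Year1Inputs)
    # expected contacts per patient per cycle, by health state
    contact_rates: dict[str, dict[str, float]] = field(default_factory=dict)
    year1_contact_rates: dict[str, dict[str, float]] = field(default_factory=dict)
    # optional explicit 12-month endpoint allocation ("NSR:0" -> mass);
    # when present the decision tree is a pass-through of this vector
    year1_allocation: dict[str, float] | None = None


@dataclass
class ClinicalInputs:
    per_arm: dict[str, ArmClinical] = field(
        default_factory=lambda: {a: ArmClinical() for a in ARMS}
    )
    # relative-risk modifiers indexed by ablation-count sub-state 0..3
    rr_recurrence_by_count: list[float] = field(default_factory=lambda: [1.0] * 4)
    rr_resolution_by_count: list[float] = field(default_factory=lambda: [1.0] * 4)
    rr_success_by_count: list[float] = field(default_factory=lambda: [1.0] * 4)


@dataclass
class EventInputs:
    cha2ds2vasc_distribution: list[float] = field(default_factory=lambda: [0.0] * 10)
    stroke_risk_by_score: list[float] = field(default_factory=lambda: [0.0] * 10)
    stroke_rr_by_state: dict[str, float] = field(
        default_factory=lambda: {h: 1.0 for h in HEALTH_STATES[:4]}
    )
    stroke_severity_split: list[float] = field(
        default_factory=lambda: [1 / 3, 1 / 3, 1 / 3]
    )
    stroke_case_fatality: float = 0.0
    hf_incidence_by_age: list[list[float]] = field(default_factory=list)
    hf_rr_by_state: dict[str, float] = field(
        default_factory=lambda: {h: 1.0 for h in HEALTH_STATES[:4]}
    )
    hf_nyha_split: list[float] = field(default_factory=lambda: [0.25] * 4)
    hf_case_fatality: float = 0.0
    # rows of [age_lo, annual_rate_female, annual_rate_male], already net of
    # stroke- and heart-failure-attributable deaths
    general_mortality: list[list[float]] = field(default_factory=list)


@dataclass
class PSASettings:
    cost_se_frac: float = 0.2
    probability_se_frac: float = 0.2
    rate_se_frac: float = 0.2
    utility_decrement_se_frac: float = 0.2
    baseline_utility_se: float = 0.012


@dataclass
class ParameterSet:
    settings: ModelSettings = field(default_factory=ModelSettings)
    demographics: Demographics = field(default_factory=Demographics)
    costs: CostInputs = field(default_factory=CostInputs)
    utilities: UtilityInputs = field(default_factory=UtilityInputs)
    clinical: ClinicalInputs = field(default_factory=ClinicalInputs)
    events: EventInputs = field(default_factory=EventInputs)
    currency_rates: CurrencyRates = field(default_factory=CurrencyRates)
    psa: PSASettings = field(default_factory=PSASettings)
    meta: dict[str, Any] = field(default_factory=dict)

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        d = copy.deepcopy(d)
        try:
            settings = ModelSettings(**d.get("settings", {}))
            demographics = Demographics(**d.get("demographics", {}))
            costs = CostInputs(**d.get("costs", {}))
            utilities = UtilityInputs(**d.get("utilities", {}))
            clin_raw = d.get("clinical", {})
            per_arm = {}
            for arm, block in clin_raw.get("per_arm", {}).items():
                y1 = Year1Inputs(**block.pop("year1", {}))
                per_arm[arm] = ArmClinical(year1=y1, **block)
            clin_kwargs = {
                k: v for k, v in clin_raw.items() if k != "per_arm"
            }
            clinical = ClinicalInputs(per_arm=per_arm or None, **clin_kwargs)
            if not per_arm:
                clinical = ClinicalInputs(**clin_kwargs)
            events = EventInputs(**d.get("events", {}))
            rates = CurrencyRates(**d.get("currency_rates", {}))
            psa = PSASettings(**d.get("psa", {}))
        except TypeError as exc:  # unknown key in the config
            raise ConfigurationError(str(exc)) from exc
        return cls(
            settings=settings,
            demographics=demographics,
            costs=costs,
            utilities=utilities,
            clinical=clinical,
            events=events,
            currency_rates=rates,
            psa=psa,
            meta=d.get("meta", {}),
        )

    def copy(self) -> "ParameterSet":
        return ParameterSet.from_dict(self.to_dict())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


# --------------------------------------------------------------------------
# loading and validation


_MANDATORY_TOP_KEYS = ("settings", "costs", "utilities", "clinical", "events")

_OPTIONAL_DEFAULTS = {
    "wtp_threshold": 23_200.0,
    "psa_iterations": 5_000,
    "cohort_size": 1_000,
}


def load_parameters(config_path: str | Path) -> ParameterSet:
    """Load and validate a full parameter set from a YAML file."""
    path = Path(config_path)
    if not path.exists():
        raise ConfigurationError(f"parameter file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"parameter file {path} did not parse to a mapping")
    for key in _MANDATORY_TOP_KEYS:
        if key not in raw:
            raise ConfigurationError(f"missing mandatory configuration section {key!r}")
    for key, default in _OPTIONAL_DEFAULTS.items():
        if key not in raw.get("settings", {}):
            logger.info("settings.%s not given; using default %s", key, default)
    p = ParameterSet.from_dict(raw)
    report = validate_parameters(p)
    if report:
        raise ValidationError(
            "invalid parameter set:\n  " + "\n  ".join(report)
        )
    return p


def base_case() -> ParameterSet:
    """The shipped Danish base-case parameter fixture."""
    with resources.as_file(
        resources.files("afcem.data") / "table1_base_case.yaml"
    ) as path:
        return load_parameters(path)


def _check(report: list[str], ok: bool, msg: str) -> None:
    if not ok:
        report.append(msg)


def _sum_ok(vec, tol=1e-9) -> bool:
    return abs(sum(vec) - 1.0) <= tol


def validate_parameters(p: ParameterSet) -> list[str]:
    """Check every documented invariant; returns a list of violations.

    Report mode: never raises, an empty list means the set is valid.
    """
    r: list[str] = []
    s = p.settings
    _check(r, 12 % s.cycle_length_months == 0, "settings.cycle_length_months must divide 12")
    _check(r, s.horizon_years >= s.decision_tree_years,
           "settings.horizon_years must be >= decision_tree_years")
    for fld in ("discount_rate_costs", "discount_rate_qalys"):
        v = getattr(s, fld)
        _check(r, 0 <= v < 1, f"settings.{fld} must be in [0, 1): got {v}")
    _check(r, s.max_total_ablations >= 1, "settings.max_total_ablations must be >= 1")
    _check(r, s.currency in ("EUR", "DKK"), f"settings.currency must be EUR or DKK: got {s.currency}")
    _check(r, s.wtp_threshold >= 0, "settings.wtp_threshold must be >= 0")

    d = p.demographics
    _check(r, 0 <= d.fraction_female <= 1, "demographics.fraction_female must be in [0, 1]")
    _check(r, d.start_age > 0, "demographics.start_age must be positive")

    c = p.costs
    for fld in ("index_procedure", "reablation_procedure", "cv_hospitalisation",
                "ae_visit", "outpatient", "cardioversion_pharm",
                "cardioversion_elec", "stroke_followup_per_cycle"):
        _check(r, getattr(c, fld) >= 0, f"costs.{fld} must be >= 0")
    for name, mapping in (("pharma_per_cycle", c.pharma_per_cycle),
                          ("stroke_event", c.stroke_event),
                          ("hf_per_cycle", c.hf_per_cycle)):
        for k, v in mapping.items():
            _check(r, v >= 0, f"costs.{name}[{k}] must be >= 0")

    u = p.utilities
    for row in u.baseline_by_age:
        for v in row[1:]:
            _check(r, -0.59 <= v <= 1.0, f"utilities.baseline value {v} outside [-0.59, 1]")
    for name, mapping in (("state_decrements", u.state_decrements),
                          ("stroke_short_term", u.stroke_short_term),
                          ("stroke_long_term", u.stroke_long_term),
                          ("hf_decrements", u.hf_decrements)):
        for k, v in mapping.items():
            _check(r, 0 <= v <= 1, f"utilities.{name}[{k}] must be in [0, 1]: got {v}")

    for arm, cl in p.clinical.per_arm.items():
        for fld in ("recurrence", "resolution", "progression_st_lt",
                    "progression_lt_perm", "reablation_uptake_st",
                    "reablation_uptake_lt", "reablation_success"):
            v = getattr(cl, fld)
            _check(r, 0 <= v <= 1, f"clinical.per_arm.{arm}.{fld} must be in [0, 1]: got {v}")
        _check(r, cl.resolution + cl.progression_st_lt <= 1,
               f"clinical.per_arm.{arm}: resolution + progression_st_lt exceeds 1")
        y1 = cl.year1
        for fld in ("recurrence", "resolution", "progression_st_lt",
                    "reablation_uptake", "reablation_success"):
            v = getattr(y1, fld)
            _check(r, 0 <= v <= 1, f"clinical.per_arm.{arm}.year1.{fld} must be in [0, 1]: got {v}")
        for label, table in (("contact_rates", cl.contact_rates),
                             ("year1_contact_rates", cl.year1_contact_rates)):
            for st, row in table.items():
                _check(r, st in HEALTH_STATES[:4],
                       f"clinical.per_arm.{arm}.{label}: unknown state {st!r}")
                for t, v in row.items():
                    _check(r, t in CONTACT_TYPES,
                           f"clinical.per_arm.{arm}.{label}[{st}]: unknown contact type {t!r}")
                    _check(r, v >= 0,
                           f"clinical.per_arm.{arm}.{label}[{st}][{t}] must be >= 0")
        if cl.year1_allocation is not None:
            _check(r, _sum_ok(cl.year1_allocation.values()),
                   f"clinical.per_arm.{arm}.year1_allocation must sum to 1")
    for name in ("rr_recurrence_by_count", "rr_resolution_by_count", "rr_success_by_count"):
        for v in getattr(p.clinical, name):
            _check(r, v > 0, f"clinical.{name} entries must be > 0")

    e = p.events
    _check(r, _sum_ok(e.cha2ds2vasc_distribution),
           "events.cha2ds2vasc_distribution must sum to 1")
    _check(r, _sum_ok(e.stroke_severity_split),
           "events.stroke_severity_split must sum to 1")
    _check(r, _sum_ok(e.hf_nyha_split), "events.hf_nyha_split must sum to 1")
    for v in e.stroke_risk_by_score:
        _check(r, 0 <= v <= 1, "events.stroke_risk_by_score entries must be in [0, 1]")
    for mapping, name in ((e.stroke_rr_by_state, "stroke_rr_by_state"),
                          (e.hf_rr_by_state, "hf_rr_by_state")):
        for k, v in mapping.items():
            _check(r, v > 0, f"events.{name}[{k}] must be > 0")
    _check(r, 0 <= e.stroke_case_fatality <= 1, "events.stroke_case_fatality must be in [0, 1]")
    _check(r, 0 <= e.hf_case_fatality <= 1, "events.hf_case_fatality must be in [0, 1]")
    for row in e.hf_incidence_by_age:
        _check(r, row[1] >= 0, "events.hf_incidence_by_age rates must be >= 0")
    _check(r, len(e.general_mortality) > 0, "events.general_mortality table is empty")
    for row in e.general_mortality:
        _check(r, row[1] >= 0 and row[2] >= 0, "events.general_mortality rates must be >= 0")

    cr = p.currency_rates
    for fld in ("gbp_to_dkk", "eur_to_dkk", "dkk_to_eur_presentation"):
        _check(r, getattr(cr, fld) > 0, f"currency_rates.{fld} must be > 0")
    return r
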