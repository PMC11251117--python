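"""Synthetic patient-level trial data with the pooled three-trial structure.

The real individual patient data behind the model (703 patients pooled
from three first-line ablation RCTs) are private, so this module generates
datasets with the same statistical skeleton the estimation layer assumes:

* three studies with study-level random intercepts on the link scale and a
  study-level ECG-monitoring method acting as a confounder,
* Poisson healthcare-contact counts with a log(exposure-months) offset,
* Bernoulli AF-recurrence and re-ablation indicators per 3-month interval,
* beta-distributed EQ-5D index utilities mapped from (0, 1) to [-0.59, 1],
* exponential dropout, and the two data-cleaning rules applied to the real
  data: exclusion of patients leaving within 30 days of their index or
  final ablation, and an optional 12-week blanking of early recurrences.

Generation does not try to match the source trials' baseline tables; only
the structure needed for parameter recovery is emulated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ValidationError

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.0
UTILITY_LOW, UTILITY_HIGH = -0.59, 1.0

RATE_OUTCOMES = (
    "hospitalisations",
    "ae_visits",
    "outpatient_visits",
    "cardioversions_pharm",
    "cardioversions_elec",
)
BINARY_OUTCOMES = ("af_recurrence", "reablation")


@dataclass
class OutcomeParams:
    """Log-linear (or logit-linear) true coefficients for one outcome.

    ``intercept`` is on the link scale for the drug arm at the reference
    ECG method; rates are per exposure month, binary outcomes per 3-month
    interval.
    """

    intercept: float
    arm_effect: float = 0.0  # cryo vs aad, link scale
    ecg_effects: tuple[float, float, float] = (0.0, 0.0, 0.0)
    study_sd: float = 0.0


@dataclass
class UtilityParams:
    intercept: float = 2.058  # logit of the (0,1)-mapped mean index value
    arm_effect: float = 0.05
    ecg_effects: tuple[float, float, float] = (0.0, 0.0, 0.0)
    study_sd: float = 0.05
    precision: float = 40.0


def _default_rate_params() -> dict[str, OutcomeParams]:
    return {
        "hospitalisations": OutcomeParams(math.log(0.018), math.log(0.60), study_sd=0.15),
        "ae_visits": OutcomeParams(math.log(0.012), math.log(0.65), study_sd=0.15),
        "outpatient_visits": OutcomeParams(math.log(0.20), math.log(0.80), study_sd=0.15),
        "cardioversions_pharm": OutcomeParams(math.log(0.006), math.log(0.50), study_sd=0.15),
        "cardioversions_elec": OutcomeParams(math.log(0.006), math.log(0.50), study_sd=0.15),
    }


def _default_binary_params() -> dict[str, OutcomeParams]:
    # intercepts are logits of per-interval probabilities in the drug arm
    return {
        "af_recurrence": OutcomeParams(math.log(0.35 / 0.65), -0.80,
                                       ecg_effects=(0.0, 0.10, 0.25), study_sd=0.10),
        "reablation": OutcomeParams(math.log(0.07 / 0.93), -1.35, study_sd=0.10),
    }


@dataclass
class SyntheticTrialSpec:
    n_patients: int = 703
    study_sizes: tuple[int, ...] = (218, 203, 282)
    ecg_method_by_study: tuple[str, ...] = ("holter", "intermittent", "continuous")
    cryo_fraction: float = 0.5
    followup_months: float = 12.0
    interval_months: float = 3.0
    dropout_hazard: float = 0.01  # per month
    mean_age: float = 58.0
    sd_age: float = 9.0
    fraction_female: float = 0.35
    rate_params: dict[str, OutcomeParams] = field(default_factory=_default_rate_params)
    binary_params: dict[str, OutcomeParams] = field(default_factory=_default_binary_params)
    utility_params: UtilityParams = field(default_factory=UtilityParams)

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValidationError("n_patients must be positive")
        if sum(self.study_sizes) != self.n_patients:
            raise ValidationError("study_sizes must sum to n_patients")
        if any(s <= 0 for s in self.study_sizes):
            raise ValidationError("every study must enrol at least one patient")
        if not 0 <= self.cryo_fraction <= 1:
            raise ValidationError("cryo_fraction must be in [0, 1]")
        if self.utility_params.precision <= 0:
            raise ValidationError("utility precision must be > 0")
        if self.followup_months <= 0 or self.interval_months <= 0:
            raise ValidationError("follow-up and interval lengths must be positive")


def analytic_mean_count(
    spec: SyntheticTrialSpec, outcome: str, arm: str,
    study_effects: dict[str, np.ndarray] | None = None,
) -> float:
    """Expected count per fully exposed interval for one arm.

    Marginalises over the study mix; random study effects are either the
    realised values (``study_effects``) or integrated analytically via the
    lognormal mean ``exp(sd^2 / 2)``.
    """
    pars = spec.rate_params[outcome]
    total = sum(spec.study_sizes)
    mean = 0.0
    for j, size in enumerate(spec.study_sizes):
        eta = pars.intercept + (pars.arm_effect if arm == "cryo" else 0.0)
        eta += pars.ecg_effects[j]
        if study_effects is not None:
            re_term = math.exp(study_effects[outcome][j])
        else:
            re_term = math.exp(pars.study_sd ** 2 / 2.0)
        mean += (size / total) * math.exp(eta) * re_term
    return mean * spec.interval_months


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_trial_cohort(
    spec: SyntheticTrialSpec, seed: int = 0,
    return_study_effects: bool = False,
):
    """Draw a patient-interval dataset; fully reproducible given ``seed``."""
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.n_patients
    n_int = int(math.ceil(spec.followup_months / spec.interval_months))

    study = np.repeat(np.arange(len(spec.study_sizes)), spec.study_sizes)
    # balanced arm allocation within each study
    arm = np.empty(n, dtype=object)
    for j in range(len(spec.study_sizes)):
        idx = np.flatnonzero(study == j)
        n_cryo = int(round(len(idx) * spec.cryo_fraction))
        perm = rng.permutation(idx)
        arm[perm[:n_cryo]] = "cryo"
        arm[perm[n_cryo:]] = "aad"
    sex = np.where(rng.random(n) < spec.fraction_female, "F", "M")
    age = np.clip(rng.normal(spec.mean_age, spec.sd_age, n), 30, 85).round(1)

    if spec.dropout_hazard > 0:
        exit_months = np.minimum(
            rng.exponential(1.0 / spec.dropout_hazard, n), spec.followup_months
        )
    else:
        exit_months = np.full(n, spec.followup_months)

    study_effects = {
        o: rng.normal(0.0, pars.study_sd, len(spec.study_sizes))
        for o, pars in {**spec.rate_params, **spec.binary_params}.items()
    }
    study_effects["utility"] = rng.normal(
        0.0, spec.utility_params.study_sd, len(spec.study_sizes)
    )

    rows = []
    for i in range(n):
        j = study[i]
        is_cryo = arm[i] == "cryo"
        last_abl_day = 0.0
        for k in range(n_int):
            start_m = k * spec.interval_months
            exposure = float(np.clip(exit_months[i] - start_m, 0.0, spec.interval_months))
            if exposure <= 0:
                break
            row = {
                "patient_id": i,
                "study_id": f"S{j + 1}",
                "arm": arm[i],
                "ecg_method": spec.ecg_method_by_study[j],
                "sex": sex[i],
                "age": age[i],
                "interval_index": k,
                "exposure_months": exposure,
                "days_since_index_procedure": (start_m + exposure) * DAYS_PER_MONTH,
            }
            for o, pars in spec.rate_params.items():
                eta = (pars.intercept + (pars.arm_effect if is_cryo else 0.0)
                       + pars.ecg_effects[j] + study_effects[o][j])
                row[o] = int(rng.poisson(math.exp(eta) * exposure))
            for o, pars in spec.binary_params.items():
                eta = (pars.intercept + (pars.arm_effect if is_cryo else 0.0)
                       + pars.ecg_effects[j] + study_effects[o][j])
                # event chance scales with the exposed share of the interval
                pr = float(_invlogit(eta)) * exposure / spec.interval_months
                row[o] = int(rng.random() < pr)
            if row["af_recurrence"]:
                week_lo = start_m * 52.0 / 12.0
                week_hi = (start_m + exposure) * 52.0 / 12.0
                row["recurrence_week"] = float(np.floor(rng.uniform(week_lo, week_hi)))
            else:
                row["recurrence_week"] = np.nan
            if row["reablation"]:
                last_abl_day = (start_m + exposure / 2.0) * DAYS_PER_MONTH
            row["last_ablation_day"] = last_abl_day
            up = spec.utility_params
            eta_u = (up.intercept + (up.arm_effect if is_cryo else 0.0)
                     + up.ecg_effects[j] + study_effects["utility"][j])
            mu = float(_invlogit(eta_u))
            a, b = mu * up.precision, (1 - mu) * up.precision
            u01 = float(rng.beta(a, b))
            row["utility"] = UTILITY_LOW + u01 * (UTILITY_HIGH - UTILITY_LOW)
            rows.append(row)
    df = pd.DataFrame(rows)
    if return_study_effects:
        return df, study_effects
    return df


def apply_exclusions(d: pd.DataFrame) -> pd.DataFrame:
    """Drop patients leaving < 30 days after the index or their final ablation."""
    exit_day = d.groupby("patient_id")["days_since_index_procedure"].max()
    last_abl = d.groupby("patient_id")["last_ablation_day"].max()
    bad = (exit_day < 30) | ((exit_day - last_abl) < 30)
    excluded = bad[bad].index
    if len(excluded):
        logger.info("excluding %d patients under the 30-day rules", len(excluded))
    return d[~d["patient_id"].isin(excluded)].reset_index(drop=True)


def apply_blanking(d: pd.DataFrame, blanking_weeks: int = 12) -> pd.DataFrame:
    """Null out AF recurrences recorded within the blanking window."""
    if blanking_weeks < 0:
        raise ValidationError("blanking_weeks must be >= 0")
    out = d.copy()
    mask = out["recurrence_week"].notna() & (out["recurrence_week"] < blanking_weeks)
    out.loc[mask, "af_recurrence"] = 0
    out.loc[mask, "recurrence_week"] = np.nan
    return out
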