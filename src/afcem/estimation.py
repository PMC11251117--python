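"""GLM layer: fit outcome regressions on patient-level data and derive
model inputs with uncertainty.

Each outcome is a generalised linear model of treatment arm plus the
ECG-monitoring method (always included as a confounder, since monitoring
intensity differed by study); count outcomes carry a log(exposure-months)
offset so coefficients are log rates per month.  Study ID can be added as
a fixed effect where it is not aliased with the ECG method (the default
design leaves it out because the three studies each used one method), or
as a Bayesian random intercept.

Utilities are fitted by beta regression after the affine map from the
EQ-5D index range [-0.59, 1] onto (0, 1), with a half-width-of-epsilon
squeeze for boundary values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.othermod.betareg import BetaModel

from .params import ValidationError
from .synthetic_ipd import UTILITY_LOW, UTILITY_HIGH

FAMILIES = ("poisson_log", "binomial_logit", "beta_logit")


class ConvergenceError(RuntimeError):
    pass


@dataclass
class FittedOutcomeModel:
    outcome_name: str
    family: str
    coefficients: pd.Series
    vcov: pd.DataFrame
    offset_used: bool
    covariates: tuple[str, ...]
    aic: float
    _results: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        v = self.vcov.to_numpy()
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValidationError("variance-covariance matrix is not symmetric")
        eig = np.linalg.eigvalsh((v + v.T) / 2.0)
        if eig.min() < -1e-8 * max(1.0, eig.max()):
            raise ValidationError("variance-covariance matrix is not PSD")


@dataclass
class AdjustedEstimate:
    outcome_name: str
    arm: str
    value: float
    standard_error: float
    scale: str  # rate | probability | utility


def _squeeze01(x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    return np.clip(x, eps / 2.0, 1.0 - eps / 2.0)


def map_utility_to_unit(u: np.ndarray) -> np.ndarray:
    return _squeeze01((np.asarray(u) - UTILITY_LOW) / (UTILITY_HIGH - UTILITY_LOW))


def map_unit_to_utility(x: float) -> float:
    return UTILITY_LOW + x * (UTILITY_HIGH - UTILITY_LOW)


def _build_formula(outcome: str, covariates: tuple[str, ...]) -> str:
    terms = []
    for c in covariates:
        if c == "arm":
            terms.append("C(arm, Treatment('aad'))")
        elif c in ("ecg_method", "study_id", "sex"):
            terms.append(f"C({c})")
        else:
            terms.append(c)
    return f"{outcome} ~ " + " + ".join(terms)


def fit_outcome_model(
    d: pd.DataFrame,
    outcome: str,
    family: str = "poisson_log",
    use_offset: bool = True,
    covariates: tuple[str, ...] = ("arm", "ecg_method"),
    nesting: str | None = None,
) -> FittedOutcomeModel:
    """Maximum-likelihood fit of one outcome regression.

    ``nesting``: ``None`` (default; no study term — with one ECG method per
    study the Study ID is aliased with the mandatory ECG confounder),
    ``"fixed"`` (Study ID fixed effects; rejected if the design becomes
    rank-deficient), or ``"random"`` (variational Bayes random study
    intercept; binomial outcomes only, since the mixed model carries no
    exposure offset).
    """
    if family not in FAMILIES:
        raise ValidationError(f"unknown family {family!r}")
    if outcome not in d.columns:
        raise ValidationError(f"outcome column {outcome!r} not in dataset")
    if "ecg_method" in d.columns and "ecg_method" not in covariates:
        raise ValidationError("ecg_method must be included as a confounder")
    data = d.copy()
    if nesting == "random":
        return _fit_random_intercept(data, outcome, family, covariates)
    if nesting == "fixed" and "study_id" not in covariates:
        covariates = tuple(covariates) + ("study_id",)
    formula = _build_formula("_y" if family == "beta_logit" else outcome, covariates)

    try:
        if family == "poisson_log":
            offset = np.log(data["exposure_months"].to_numpy()) if use_offset else None
            model = smf.glm(formula, data=data, family=sm.families.Poisson(), offset=offset)
            res = model.fit()
        elif family == "binomial_logit":
            model = smf.glm(formula, data=data, family=sm.families.Binomial())
            res = model.fit()
        else:
            data["_y"] = map_utility_to_unit(data[outcome].to_numpy())
            model = BetaModel.from_formula(formula, data)
            res = model.fit(disp=False)
            use_offset = False
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(
            f"fit for {outcome!r} failed ({exc}); a separated or collinear design "
            "may need penalisation or fewer covariates"
        ) from exc
    exog = res.model.exog
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ConvergenceError(
            f"design for {outcome!r} is rank-deficient (aliased covariates, "
            "e.g. Study ID with a study-level ECG method); drop a term or use "
            "nesting='random'"
        )
    converged = getattr(res, "converged", None)
    if converged is None:
        converged = bool(getattr(res, "mle_retvals", {}).get("converged", True))
    if not converged:
        raise ConvergenceError(f"fit for {outcome!r} did not converge: {res.summary()}")

    params = res.params
    vcov = pd.DataFrame(res.cov_params(), index=params.index, columns=params.index)
    return FittedOutcomeModel(
        outcome_name=outcome,
        family=family,
        coefficients=params,
        vcov=vcov,
        offset_used=use_offset,
        covariates=tuple(covariates),
        aic=float(res.aic),
        _results=res,
    )


def _fit_random_intercept(
    data: pd.DataFrame, outcome: str, family: str, covariates: tuple[str, ...]
) -> FittedOutcomeModel:
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    if family != "binomial_logit":
        raise ValidationError(
            "random study intercepts are supported for binomial outcomes only "
            "(the mixed model has no exposure offset); use nesting='fixed' or "
            "the default design for rate outcomes"
        )
    formula = _build_formula(outcome, covariates)
    model = BinomialBayesMixedGLM.from_formula(
        formula, {"study": "0 + C(study_id)"}, data
    )
    res = model.fit_vb()
    names = list(model.exog_names)
    params = pd.Series(res.fe_mean, index=names)
    vcov = pd.DataFrame(np.diag(res.fe_sd**2), index=names, columns=names)
    return FittedOutcomeModel(
        outcome_name=outcome,
        family=family,
        coefficients=params,
        vcov=vcov,
        offset_used=False,
        covariates=tuple(covariates) + ("study_id:random",),
        aic=float("nan"),
        _results=None,
    )


def select_family(
    d: pd.DataFrame, outcome: str, candidates: tuple[str, ...], **kwargs
) -> FittedOutcomeModel:
    """Fit each candidate family and keep the lowest-AIC fit."""
    fits = [fit_outcome_model(d, outcome, family=f, **kwargs) for f in candidates]
    return min(fits, key=lambda m: m.aic)


def arm_effect(m: FittedOutcomeModel) -> tuple[float, float]:
    """The cryo-vs-drug coefficient and its standard error on the link scale."""
    name = [c for c in m.coefficients.index if "arm" in c and "cryo" in c]
    if not name:
        raise ValidationError("model has no arm term")
    c = name[0]
    return float(m.coefficients[c]), float(np.sqrt(m.vcov.loc[c, c]))


def _design_row(m: FittedOutcomeModel, profile: dict) -> np.ndarray:
    res = m._results
    if res is None:
        raise ValidationError("model carries no fitted results for prediction")
    from patsy import dmatrix

    design_info = res.model.data.design_info
    try:
        X = dmatrix(design_info, pd.DataFrame([profile]), return_type="dataframe")
    except Exception as exc:
        raise ValidationError(f"profile is missing a covariate: {exc}") from exc
    return X.to_numpy()[0]


def adjusted_estimate(m: FittedOutcomeModel, profile: dict) -> AdjustedEstimate:
    """Inverse-link prediction at a covariate profile with delta-method SE."""
    x = _design_row(m, profile)
    beta = m.coefficients.to_numpy()[: len(x)]
    eta = float(x @ beta)
    V = m.vcov.to_numpy()[: len(x), : len(x)]
    var_eta = float(x @ V @ x)
    if m.family == "poisson_log":
        value = math.exp(eta)
        grad = value
        scale = "rate"
    else:
        value = 1.0 / (1.0 + math.exp(-eta))
        grad = value * (1.0 - value)
        scale = "utility" if m.family == "beta_logit" else "probability"
    se = abs(grad) * math.sqrt(max(var_eta, 0.0))
    if m.family == "beta_logit":
        value = map_unit_to_utility(value)
        se = se * (UTILITY_HIGH - UTILITY_LOW)
    return AdjustedEstimate(
        outcome_name=m.outcome_name, arm=str(profile.get("arm", "")),
        value=value, standard_error=se, scale=scale,
    )


def monthly_rate_to_cycle_probability(rate: float, cycle_months: float = 3.0) -> float:
    """Constant-hazard conversion of a per-month rate to a per-cycle probability."""
    if rate < 0:
        raise ValidationError("rate must be >= 0")
    return 1.0 - math.exp(-rate * cycle_months)


def monthly_rate_to_cycle_count(rate: float, cycle_months: float = 3.0) -> float:
    """Expected events per cycle (Poisson means add over exposure)."""
    if rate < 0:
        raise ValidationError("rate must be >= 0")
    return rate * cycle_months


_CONTACT_MAP = {
    "hospitalisations": "hospitalisation",
    "ae_visits": "ae_visit",
    "outpatient_visits": "outpatient",
    "cardioversions_pharm": "cardioversion_pharm",
    "cardioversions_elec": "cardioversion_elec",
}

REQUIRED_OUTCOMES = tuple(_CONTACT_MAP) + ("af_recurrence", "reablation", "utility")


def derive_model_inputs(
    models: dict[str, FittedOutcomeModel],
    cycle_months: float = 3.0,
    profile_extra: dict | None = None,
) -> dict:
    """Adjusted per-arm cohort-model inputs plus coefficient blocks for PSA.

    Contact rates come back as expected counts per cycle, binary outcomes
    as per-cycle probabilities, utility as an adjusted mean on the index
    scale; each fitted model also contributes a (mean, vcov) block keyed
    for correlated Cholesky sampling.
    """
    missing = [o for o in REQUIRED_OUTCOMES if o not in models]
    if missing:
        raise ValidationError(f"missing fitted outcomes: {missing}")
    out: dict = {"per_arm": {}, "coefficient_blocks": {}}
    for arm in ("cryo", "aad"):
        block: dict = {"contact_rates": {}}
        for o, m in models.items():
            profile = {"arm": arm, "exposure_months": 1.0}
            if any("ecg_method" in c for c in m.coefficients.index):
                profile["ecg_method"] = _first_level(m, "ecg_method")
            if profile_extra:
                profile.update(profile_extra)
            est = adjusted_estimate(m, profile)
            if o in _CONTACT_MAP:
                block["contact_rates"][_CONTACT_MAP[o]] = monthly_rate_to_cycle_count(
                    est.value, cycle_months
                )
            elif o == "af_recurrence":
                block["recurrence"] = min(1.0, max(0.0, est.value))
            elif o == "reablation":
                block["reablation_uptake"] = min(1.0, max(0.0, est.value))
            elif o == "utility":
                block["utility"] = est.value
        out["per_arm"][arm] = block
    for o, m in models.items():
        out["coefficient_blocks"][o] = {
            "mean": m.coefficients.to_numpy().tolist(),
            "names": list(m.coefficients.index),
            "vcov": m.vcov.to_numpy().tolist(),
        }
    return out


def _first_level(m: FittedOutcomeModel, factor: str) -> str:
    res = m._results
    levels = sorted(res.model.data.frame[factor].unique()) if res is not None else []
    if not levels:
        raise ValidationError(f"cannot resolve levels of {factor}")
    return levels[0]
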