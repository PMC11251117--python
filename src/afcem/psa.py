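"""Probabilistic sensitivity analysis.

Cost parameters are sampled from gamma distributions and probability /
utility parameters from beta distributions, both moment-matched to their
base-case value and a standard error (defaulting to a configurable
fraction of the mean where no estimate-level uncertainty exists).
Regression coefficient blocks, when supplied, are sampled jointly as
multivariate normal on the link scale via the Cholesky factor of the
variance-covariance matrix.  Each draw re-runs the full two-arm model; a
master seed spawns one substream per iteration so results are
reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cohort_model, economics
from .params import ParameterSet, ValidationError, validate_parameters

ARMS = ("cryo", "aad")


def fit_gamma_moments(mean: float, se: float) -> tuple[float, float]:
    """Gamma (shape, rate) reproducing the given mean and standard error."""
    if mean <= 0 or se <= 0:
        raise ValidationError("gamma moment fit needs mean > 0 and se > 0")
    shape = (mean / se) ** 2
    rate = mean / se**2
    return shape, rate


def fit_beta_moments(mean: float, se: float) -> tuple[float, float]:
    """Beta (alpha, beta) reproducing the given mean and standard error."""
    if not 0 < mean < 1:
        raise ValidationError("beta moment fit needs 0 < mean < 1")
    if se <= 0 or se**2 >= mean * (1 - mean):
        raise ValidationError(
            f"infeasible beta moments: se^2 must be below mean(1-mean) = {mean * (1 - mean):.4g}"
        )
    nu = mean * (1 - mean) / se**2 - 1.0
    return mean * nu, (1 - mean) * nu


def sample_correlated_coefficients(
    means: np.ndarray, vcov: np.ndarray, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draws of ``means + L z`` with ``L`` the lower Cholesky factor of vcov."""
    means = np.asarray(means, dtype=float)
    vcov = np.asarray(vcov, dtype=float)
    if not np.allclose(vcov, vcov.T, atol=1e-10):
        raise ValidationError("vcov must be symmetric")
    if np.allclose(vcov, 0.0):
        return np.tile(means, (n, 1))
    try:
        L = np.linalg.cholesky(vcov)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "vcov is not positive definite; consider a nearest-PSD repair "
            "(eigenvalue clipping) before sampling"
        ) from exc
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal((n, len(means)))
    return means + z @ L.T


@dataclass
class PSAResults:
    seed: int
    threshold: float
    costs: pd.DataFrame  # columns cryo, aad; one row per iteration
    qalys: pd.DataFrame
    n_rejected: int = 0

    @property
    def iterations(self) -> int:
        return len(self.costs)

    def deltas(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "delta_cost": self.costs["cryo"] - self.costs["aad"],
                "delta_qalys": self.qalys["cryo"] - self.qalys["aad"],
            }
        )

    def nmb(self, threshold: float | None = None) -> pd.Series:
        lam = self.threshold if threshold is None else threshold
        d = self.deltas()
        return d["delta_qalys"] * lam - d["delta_cost"]

    def probability_cost_effective(self, threshold: float | None = None) -> float:
        return float((self.nmb(threshold) > 0).mean())

    def summary(self) -> dict:
        out: dict = {}
        for name, tbl in (("cost", self.costs), ("qalys", self.qalys)):
            for arm in ARMS:
                v = tbl[arm]
                out[f"{name}_{arm}"] = {
                    "mean": float(v.mean()),
                    "cri_low": float(v.quantile(0.025)),
                    "cri_high": float(v.quantile(0.975)),
                }
        d = self.deltas()
        for col in d.columns:
            out[col] = {
                "mean": float(d[col].mean()),
                "cri_low": float(d[col].quantile(0.025)),
                "cri_high": float(d[col].quantile(0.975)),
            }
        nmb = self.nmb()
        out["nmb"] = {
            "mean": float(nmb.mean()),
            "cri_low": float(nmb.quantile(0.025)),
            "cri_high": float(nmb.quantile(0.975)),
        }
        mean_dc = out["delta_cost"]["mean"]
        mean_dq = out["delta_qalys"]["mean"]
        if mean_dc < 0 and mean_dq > 0:
            out["icer"] = economics.DOMINANT
        elif mean_dc > 0 and mean_dq < 0:
            out["icer"] = economics.DOMINATED
        else:
            out["icer"] = mean_dc / mean_dq if mean_dq else None
        out["probability_cost_effective"] = self.probability_cost_effective()
        return out


def _sample_beta(rng, mean: float, se: float) -> float:
    if mean <= 0 or mean >= 1 or se <= 0:
        return mean
    se = min(se, 0.95 * (mean * (1 - mean)) ** 0.5)
    a, b = fit_beta_moments(mean, se)
    return float(rng.beta(a, b))


def _sample_gamma(rng, mean: float, se: float) -> float:
    if mean <= 0 or se <= 0:
        return mean
    shape, rate = fit_gamma_moments(mean, se)
    return float(rng.gamma(shape, 1.0 / rate))


def sample_parameter_set(p: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One PSA draw of the full parameter set.

    Gamma for costs, contact rates and event rates; beta for transition
    probabilities, splits (via Dirichlet-like renormalised betas), case
    fatalities and utility decrements; a single beta draw shifts the
    baseline-utility table.
    """
    d = p.to_dict()
    fc = p.psa.cost_se_frac
    fp = p.psa.probability_se_frac
    fr = p.psa.rate_se_frac
    fu = p.psa.utility_decrement_se_frac

    costs = d["costs"]
    for key in ("index_procedure", "reablation_procedure", "cv_hospitalisation",
                "ae_visit", "outpatient", "cardioversion_pharm",
                "cardioversion_elec", "stroke_followup_per_cycle"):
        costs[key] = _sample_gamma(rng, costs[key], fc * costs[key])
    for key in ("pharma_per_cycle", "stroke_event", "hf_per_cycle"):
        for k, v in costs[key].items():
            costs[key][k] = _sample_gamma(rng, v, fc * v)

    for arm, block in d["clinical"]["per_arm"].items():
        for key in ("recurrence", "resolution", "progression_st_lt",
                    "progression_lt_perm", "reablation_uptake_st",
                    "reablation_uptake_lt", "reablation_success"):
            block[key] = _sample_beta(rng, block[key], fp * block[key])
        for key in ("recurrence", "resolution", "progression_st_lt", "reablation_uptake"):
            block["year1"][key] = _sample_beta(rng, block["year1"][key],
                                               fp * block["year1"][key])
        for table in ("contact_rates", "year1_contact_rates"):
            for st, row in block[table].items():
                for t, v in row.items():
                    row[t] = _sample_gamma(rng, v, fr * v)

    evd = d["events"]
    evd["stroke_risk_by_score"] = [
        _sample_beta(rng, q, fp * q) if q > 0 else q for q in evd["stroke_risk_by_score"]
    ]
    evd["hf_incidence_by_age"] = [
        [a, _sample_gamma(rng, r, fr * r)] for a, r in evd["hf_incidence_by_age"]
    ]
    for key in ("stroke_case_fatality", "hf_case_fatality"):
        evd[key] = _sample_beta(rng, evd[key], fp * evd[key])

    ud = d["utilities"]
    for key in ("state_decrements", "stroke_short_term", "stroke_long_term",
                "hf_decrements"):
        for k, v in ud[key].items():
            ud[key][k] = _sample_beta(rng, v, fu * v)
    if ud["baseline_by_age"]:
        u0 = ud["baseline_by_age"][0][1]
        if 0 < u0 < 1 and p.psa.baseline_utility_se > 0:
            shift = _sample_beta(rng, u0, p.psa.baseline_utility_se) - u0
            ud["baseline_by_age"] = [
                [row[0], min(1.0, row[1] + shift), min(1.0, row[2] + shift)]
                for row in ud["baseline_by_age"]
            ]
    return ParameterSet.from_dict(d)


def run_deterministic(p: ParameterSet) -> dict[str, economics.EconResult]:
    """Both arms through the cohort engine and the accounting layer."""
    out = {}
    for arm in ARMS:
        trace = cohort_model.run_arm(p, arm)
        out[arm] = economics.accumulate_economics(trace, p, arm)
    return out


def run_psa(
    p: ParameterSet, n: int | None = None, seed: int = 0,
    max_reject_frac: float = 0.01,
) -> PSAResults:
    """Monte-Carlo propagation of parameter uncertainty through the model."""
    n = p.settings.psa_iterations if n is None else n
    streams = np.random.SeedSequence(seed).spawn(n)
    costs = {a: np.empty(n) for a in ARMS}
    qalys = {a: np.empty(n) for a in ARMS}
    rejected = 0
    kept = 0
    for i in range(n):
        rng = np.random.default_rng(streams[i])
        draw = sample_parameter_set(p, rng)
        if validate_parameters(draw):
            rejected += 1
            if rejected > max_reject_frac * n:
                raise ValidationError(
                    f"more than {max_reject_frac:.0%} of PSA draws were invalid"
                )
            continue
        res = run_deterministic(draw)
        for a in ARMS:
            costs[a][kept] = res[a].cost_total
            qalys[a][kept] = res[a].qalys_total
        kept += 1
    costs_df = pd.DataFrame({a: costs[a][:kept] for a in ARMS})
    qalys_df = pd.DataFrame({a: qalys[a][:kept] for a in ARMS})
    return PSAResults(seed=seed, threshold=p.settings.wtp_threshold,
                      costs=costs_df, qalys=qalys_df, n_rejected=rejected)


def ceac(r: PSAResults, thresholds: np.ndarray | list[float]) -> pd.DataFrame:
    """Probability of positive net benefit across willingness-to-pay values."""
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValidationError("threshold grid is empty")
    d = r.deltas()
    probs = [
        float(((d["delta_qalys"] * lam - d["delta_cost"]) > 0).mean())
        for lam in thresholds
    ]
    return pd.DataFrame({"threshold": thresholds, "probability_cost_effective": probs})
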