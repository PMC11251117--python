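"""GLM estimation layer: fits, adjusted estimates, input derivation."""

import math

import numpy as np
import pytest

from afcem import estimation as est
from afcem import synthetic_ipd as si
from afcem.params import ValidationError


@pytest.fixture(scope="module")
def ipd():
    return si.apply_exclusions(si.generate_trial_cohort(si.SyntheticTrialSpec(), seed=101))


@pytest.fixture(scope="module")
def poisson_fit(ipd):
    return est.fit_outcome_model(ipd, "hospitalisations", family="poisson_log")


class TestFitting:
    def test_poisson_fit_shape_and_diagnostics(self, poisson_fit):
        m = poisson_fit
        assert m.family == "poisson_log" and m.offset_used
        assert len(m.coefficients) == m.vcov.shape[0] == m.vcov.shape[1]
        assert np.isfinite(m.aic)
        v = m.vcov.to_numpy()
        assert np.allclose(v, v.T)
        assert np.linalg.eigvalsh(v).min() > 0

    def test_ecg_confounder_is_mandatory(self, ipd):
        with pytest.raises(ValidationError, match="confounder"):
            est.fit_outcome_model(ipd, "hospitalisations", covariates=("arm",))

    def test_unknown_outcome_and_family_rejected(self, ipd):
        with pytest.raises(ValidationError):
            est.fit_outcome_model(ipd, "nonexistent")
        with pytest.raises(ValidationError):
            est.fit_outcome_model(ipd, "hospitalisations", family="gaussian")

    def test_doubling_exposure_halves_fitted_rate(self, ipd, poisson_fit):
        doubled = ipd.copy()
        doubled["exposure_months"] *= 2.0
        m2 = est.fit_outcome_model(doubled, "hospitalisations")
        prof = {"arm": "aad", "ecg_method": "holter"}
        r1 = est.adjusted_estimate(poisson_fit, prof).value
        r2 = est.adjusted_estimate(m2, prof).value
        assert r2 == pytest.approx(r1 / 2.0, rel=1e-8)

    def test_null_arm_effect_gives_small_z_in_most_replicates(self):
        spec = si.SyntheticTrialSpec()
        pars = spec.rate_params["hospitalisations"]
        pars.arm_effect = 0.0
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            d = si.generate_trial_cohort(spec, seed=seed)
            m = est.fit_outcome_model(d, "hospitalisations")
            coef, se = est.arm_effect(m)
            hits += abs(coef / se) < 2.0
        assert hits >= 8

    def test_beta_fit_on_utilities(self, ipd):
        m = est.fit_outcome_model(ipd, "utility", family="beta_logit", use_offset=False)
        val = est.adjusted_estimate(m, {"arm": "cryo", "ecg_method": "holter"})
        assert val.scale == "utility"
        assert si.UTILITY_LOW < val.value < si.UTILITY_HIGH

    def test_fixed_study_nesting_rejected_when_aliased_with_ecg(self, ipd):
        # one ECG method per study makes Study ID collinear with the confounder
        with pytest.raises(est.ConvergenceError, match="rank-deficient"):
            est.fit_outcome_model(ipd, "hospitalisations", nesting="fixed")

    def test_random_intercept_nesting_for_binary_outcome(self, ipd):
        m = est.fit_outcome_model(ipd, "af_recurrence", family="binomial_logit",
                                  use_offset=False, nesting="random")
        coef, se = est.arm_effect(m)
        # true cryo log-odds ratio is -0.8; VB posterior should be in range
        assert -1.6 < coef < -0.2 and se > 0

    def test_random_intercept_rejected_for_rate_outcomes(self, ipd):
        with pytest.raises(ValidationError, match="binomial"):
            est.fit_outcome_model(ipd, "hospitalisations", nesting="random")

    def test_family_selection_minimises_information_criterion(self, ipd):
        chosen = est.select_family(ipd, "af_recurrence",
                                   ("poisson_log", "binomial_logit"))
        alt = est.fit_outcome_model(ipd, "af_recurrence", family="poisson_log")
        bin_ = est.fit_outcome_model(ipd, "af_recurrence", family="binomial_logit",
                                     use_offset=False)
        assert chosen.aic == min(alt.aic, bin_.aic)


class TestAdjustedEstimates:
    def test_logit_linear_predictor_zero_is_half(self, ipd):
        m = est.fit_outcome_model(ipd, "af_recurrence", family="binomial_logit",
                                  use_offset=False)
        m.coefficients[:] = 0.0
        p = est.adjusted_estimate(m, {"arm": "aad", "ecg_method": "holter"})
        assert p.value == pytest.approx(0.5)

    def test_intercept_only_inverse_link(self, ipd):
        d = ipd.drop(columns=["ecg_method"])
        m = est.fit_outcome_model(d, "hospitalisations", covariates=("arm",))
        # fitted rate for the reference arm is exp(intercept)
        r = est.adjusted_estimate(m, {"arm": "aad"})
        assert r.value == pytest.approx(math.exp(m.coefficients.iloc[0]))

    def test_missing_covariate_in_profile_rejected(self, poisson_fit):
        with pytest.raises(ValidationError):
            est.adjusted_estimate(poisson_fit, {"arm": "aad"})

    def test_delta_method_se_matches_parametric_bootstrap(self, poisson_fit):
        """Delta-method SE vs the SD of 10,000 coefficient draws (within 5%)."""
        prof = {"arm": "cryo", "ecg_method": "holter"}
        target = est.adjusted_estimate(poisson_fit, prof)
        rng = np.random.default_rng(0)
        beta = poisson_fit.coefficients.to_numpy()
        draws = rng.multivariate_normal(beta, poisson_fit.vcov.to_numpy(), size=10_000)
        x = est._design_row(poisson_fit, prof)
        boot = np.exp(draws @ x)
        assert target.standard_error == pytest.approx(boot.std(), rel=0.05)


class TestInputDerivation:
    def test_rate_conversions_closed_forms(self):
        assert est.monthly_rate_to_cycle_probability(0.0) == 0.0
        assert est.monthly_rate_to_cycle_probability(0.1) == pytest.approx(
            1 - math.exp(-0.3))
        assert est.monthly_rate_to_cycle_count(0.07) == pytest.approx(0.21)

    def test_missing_outcome_listed(self, ipd, poisson_fit):
        with pytest.raises(ValidationError, match="af_recurrence"):
            est.derive_model_inputs({"hospitalisations": poisson_fit})

    def test_full_derivation_emits_valid_inputs(self, ipd):
        models = {}
        for o in si.RATE_OUTCOMES:
            models[o] = est.fit_outcome_model(ipd, o)
        for o in si.BINARY_OUTCOMES:
            models[o] = est.fit_outcome_model(ipd, o, family="binomial_logit",
                                              use_offset=False)
        models["utility"] = est.fit_outcome_model(ipd, "utility", family="beta_logit",
                                                  use_offset=False)
        out = est.derive_model_inputs(models)
        for arm in ("cryo", "aad"):
            blk = out["per_arm"][arm]
            assert 0 <= blk["recurrence"] <= 1
            assert 0 <= blk["reablation_uptake"] <= 1
            assert si.UTILITY_LOW < blk["utility"] < si.UTILITY_HIGH
            assert all(v >= 0 for v in blk["contact_rates"].values())
        blk = out["coefficient_blocks"]["hospitalisations"]
        assert len(blk["mean"]) == len(blk["names"])
        assert np.asarray(blk["vcov"]).shape == (len(blk["mean"]),) * 2
        # the drug arm has higher contact rates by construction
        assert (out["per_arm"]["aad"]["contact_rates"]["hospitalisation"]
                > out["per_arm"]["cryo"]["contact_rates"]["hospitalisation"])
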