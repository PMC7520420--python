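import warnings

import numpy as np
import pandas as pd
import pytest

from adcpkpd import (
    DosingRegimen,
    IIVSpec,
    ResidualErrorModel,
    StudyDesign,
    TumorStudy,
    condition_number,
    diagnostics,
    fit_tgi,
    fit_tmdd_clinical,
    fit_vehicle_growth,
    fixtures,
    generate_clinical_pk,
    generate_xenograft_study,
)


@pytest.fixture(scope="module")
def clean_fits(clean_study, mouse_pk):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        growth, omega = fit_vehicle_growth(clean_study)
        fit = fit_tgi(clean_study, mouse_pk, growth, seed=0)
    return growth, omega, fit


class TestVehicleGrowth:
    def test_noise_free_recovery(self, clean_fits, jimt1_params):
        growth, _, _ = clean_fits
        assert growth.estimates["kgEx"] == pytest.approx(jimt1_params.kgEx, rel=1e-3)
        # kg and Vmax are only weakly informed by a 28-day window; loose check
        assert growth.estimates["kg"] == pytest.approx(jimt1_params.kg, rel=0.25)

    def test_no_iiv_gives_near_zero_omegas(self, clean_fits):
        _, omega, _ = clean_fits
        assert omega.omega_kgEx < 0.02

    def test_omega_recovery_with_many_animals(self, jimt1, mouse_pk):
        """ω(kgEx) = 0.4 recovered from a 50-animal vehicle arm (median of 3)."""
        design = StudyDesign(n_animals_per_arm=50, dose_arms=(0.0,))
        rec = []
        for seed in range(3):
            study = generate_xenograft_study(
                design, jimt1.params, IIVSpec(0.4, 0.5),
                ResidualErrorModel(jimt1.additive_error, jimt1.proportional_error),
                mouse_pk, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, omega = fit_vehicle_growth(study)
            rec.append(omega.omega_kgEx)
        assert np.median(rec) == pytest.approx(0.4, rel=0.25)

    def test_single_animal_flagged(self, jimt1, mouse_pk):
        design = StudyDesign(n_animals_per_arm=1, dose_arms=(0.0,))
        study = generate_xenograft_study(
            design, jimt1.params, IIVSpec(0, 0), ResidualErrorModel(1.0, 0.05),
            mouse_pk, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit, omega = fit_vehicle_growth(study)
        assert "single_animal:omegas_undefined" in fit.flags

    def test_missing_vehicle_arm_rejected(self, jimt1_study):
        dosed_only = TumorStudy(
            data=jimt1_study.dosed().reset_index(drop=True),
            dose_times=jimt1_study.dose_times)
        with pytest.raises(Exception, match="vehicle"):
            fit_vehicle_growth(dosed_only)


class TestFitTGI:
    def test_noise_free_recovery_of_drug_effect(self, clean_fits, jimt1_params):
        _, _, fit = clean_fits
        assert fit.estimates["kkmax"] == pytest.approx(jimt1_params.kkmax, rel=0.05)
        assert fit.estimates["kc50"] == pytest.approx(jimt1_params.kc50, rel=0.05)
        assert fit.estimates["tau"] == pytest.approx(jimt1_params.tau, rel=0.05)

    def test_objective_at_truth_not_better_than_optimum(
        self, clean_study, mouse_pk, clean_fits, jimt1_params
    ):
        """The optimizer's objective is no worse than at perturbed parameters."""
        growth, _, fit = clean_fits
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            perturbed = fit_tgi(
                clean_study, mouse_pk, growth, seed=0, n_starts=1, n_polish=1,
                irls_rounds=1,
                init={"tau": jimt1_params.tau * 3, "kkmax": jimt1_params.kkmax * 3,
                      "kc50": jimt1_params.kc50 * 3, "n": 1.0},
            )
        assert fit.objective <= perturbed.objective + 1e-6

    def test_requires_dosed_arm(self, jimt1, mouse_pk):
        design = StudyDesign(n_animals_per_arm=4, dose_arms=(0.0,))
        study = generate_xenograft_study(
            design, jimt1.params, IIVSpec(0, 0), ResidualErrorModel(1, 0.05),
            mouse_pk, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            growth, _ = fit_vehicle_growth(study)
            with pytest.raises(Exception, match="dosed"):
                fit_tgi(study, mouse_pk, growth)


class TestFitTMDDClinical:
    def test_noise_free_fit_recovers_shedding_and_data(self, human_tmdd):
        """The shedding rate is well identified; kdeg/kel_complex trade off
        along a near-equivalent manifold of free-drug profiles, so the check
        on them is that the fitted model reproduces the data, not the exact
        generating values."""
        days = [0.1, 0.5, 1, 2, 4, 7, 10, 14, 21]
        profiles = generate_clinical_pk(
            human_tmdd, doses=[0.3, 1.2, 3.0, 4.8], sampling_days=days,
            prop_error=0.0, n_per_dose=1, seed=0)
        from dataclasses import replace

        p0 = replace(human_tmdd, kshed=3.0, kdeg=15.0, kel_complex=10.0,
                     ecd0=None)
        fit = fit_tmdd_clinical(profiles, p0)
        assert fit.estimates["kshed"] == pytest.approx(6.65, rel=0.05)
        r = fit.residual_table
        np.testing.assert_allclose(r["pred"], r["obs"], rtol=0.02)

    def test_truth_initialized_fit_stays_at_truth(self, human_tmdd):
        """On noise-free data the generating parameters are a likelihood optimum."""
        days = [0.1, 0.5, 1, 2, 4, 7, 10, 14, 21]
        profiles = generate_clinical_pk(
            human_tmdd, doses=[0.3, 3.0], sampling_days=days,
            prop_error=0.0, n_per_dose=1, seed=0)
        fit = fit_tmdd_clinical(profiles, human_tmdd)
        assert fit.estimates["kshed"] == pytest.approx(6.65, rel=0.01)
        assert fit.estimates["kdeg"] == pytest.approx(33.3, rel=0.05)
        assert fit.estimates["kel_complex"] == pytest.approx(32.6, rel=0.05)

    def test_noisy_recovery_within_weak_identifiability(self, human_tmdd):
        days = [0.1, 0.5, 1, 2, 4, 7, 10, 14, 21]
        profiles = generate_clinical_pk(
            human_tmdd, doses=[0.3, 1.2, 2.4, 3.6, 4.8], sampling_days=days,
            prop_error=0.05, n_per_dose=2, seed=11)
        from dataclasses import replace

        p0 = replace(human_tmdd, kshed=3.0, kdeg=20.0, kel_complex=15.0, ecd0=None)
        fit = fit_tmdd_clinical(profiles, p0)
        assert fit.estimates["kshed"] == pytest.approx(6.65, rel=0.30)
        assert fit.cv_percent  # CVs reported for the weakly identified set

    def test_single_dose_level_warns(self, human_tmdd):
        days = [0.1, 1, 7, 21]
        profiles = generate_clinical_pk(human_tmdd, doses=[1.0], sampling_days=days,
                                        prop_error=0.0, n_per_dose=1, seed=0)
        with pytest.warns(UserWarning, match="dose level"):
            fit_tmdd_clinical(profiles, human_tmdd)


class TestDiagnostics:
    def test_zero_residuals_for_perfect_fit(self):
        rt = pd.DataFrame({
            "time_day": [0, 1, 2, 3], "obs": [10.0, 20, 30, 40],
            "pred": [10.0, 20, 30, 40]})
        fit = _dummy_fit(rt)
        d = diagnostics(fit, error_model=ResidualErrorModel(1.0, 0.1), seed=0)
        assert np.allclose(d["weighted_residuals"]["weighted_residual"], 0.0)

    def test_vpc_calibration_under_generating_model(self):
        """~80% of observations fall inside the simulated 10-90% band."""
        rng = np.random.default_rng(12)
        pred = rng.uniform(50, 500, 400)
        err = ResidualErrorModel(5.0, 0.1)
        obs = pred + err.sd(pred) * rng.standard_normal(400)
        rt = pd.DataFrame({"time_day": np.arange(400) % 8, "obs": obs, "pred": pred})
        d = diagnostics(_dummy_fit(rt), error_model=err, n_vpc=1000, seed=1)
        assert d["fraction_in_band"] == pytest.approx(0.80, abs=0.06)

    def test_condition_number_identity_is_one(self):
        assert condition_number(np.eye(4)) == pytest.approx(1.0)

    def test_condition_number_matches_analytic_eigenratio(self):
        info = np.diag([100.0, 4.0, 1.0])
        assert condition_number(info) == pytest.approx(100.0)


def _dummy_fit(rt):
    from adcpkpd.estimation import FitResult

    return FitResult(estimates={}, cv_percent={}, objective=0.0,
                     condition_number=1.0, convergence=True, residual_table=rt)
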