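import numpy as np
import pytest

from adcpkpd import (
    DosingRegimen,
    InvalidParameterError,
    TMDDParams,
    TwoCptParams,
    fit_ecd_to_profile,
    fixtures,
    nca_metrics,
    simulate_2cpt,
    simulate_tmdd,
    ugml_to_nm,
)


@pytest.fixture(scope="module")
def grid_21d():
    return np.arange(0.0, 21.0 + 1e-9, 0.01)


def test_baseline_consistency_enforced():
    lin = TwoCptParams(38.1, 5.52, 20.2, 14.9)
    with pytest.raises(InvalidParameterError):
        TMDDParams(linear=lin, KD=0.1, kon=61.3, kshed=6.65, kdeg=33.3,
                   kel_complex=32.6, ecd0=5.0)
    # explicit override allowed (e.g. the 0.206 nM initial condition)
    p = TMDDParams(linear=lin, KD=0.1, kon=61.3, kshed=6.65, kdeg=33.3,
                   kel_complex=32.6, ecd0=0.206, allow_inconsistent_baseline=True)
    assert p.ecd0 == 0.206


def test_default_baseline_is_turnover_steady_state(human_tmdd):
    assert human_tmdd.ecd0 == pytest.approx(6.65 / 33.3, rel=1e-12)
    assert human_tmdd.koff == pytest.approx(0.1 * 61.3)


def test_shedding_rate_consistent_with_reported_values():
    """kshed = kdeg × ECD(0): 33.3/day × 0.2 nM reproduces 6.65 nM/day."""
    assert 33.3 * 0.2 == pytest.approx(6.65, rel=0.01)


def test_undosed_target_stays_at_steady_state(human_tmdd, grid_21d):
    regimen = DosingRegimen.uniform(0.0, 21.0, 1, infusion_h=1.0)
    traj = simulate_tmdd(human_tmdd, regimen, grid_21d)
    np.testing.assert_allclose(traj.C_ECD, human_tmdd.ecd0, rtol=1e-6)
    assert np.all(traj.C_ADC == 0)


def test_no_binding_reduces_to_linear_pk(grid_21d):
    """kon = 0 must reproduce the two-compartment model exactly."""
    lin = TwoCptParams(38.1, 5.52, 20.2, 14.9)
    p = TMDDParams(linear=lin, KD=0.1, kon=0.0, kshed=6.65, kdeg=33.3,
                   kel_complex=32.6)
    regimen = DosingRegimen.uniform(1.0, 21.0, 1, infusion_h=1.0)
    traj = simulate_tmdd(p, regimen, grid_21d)
    free = traj.profile("free", "ug/mL").values
    ref = simulate_2cpt(lin, regimen, grid_21d).values
    mask = ref > 1e-6
    np.testing.assert_allclose(free[mask], ref[mask], rtol=1e-6)


def test_states_nonnegative_under_multidose(human_tmdd):
    times = np.arange(0.0, 84.0, 0.05)
    regimen = DosingRegimen.uniform(3.0, 21.0, 4, infusion_h=1.0)
    traj = simulate_tmdd(human_tmdd, regimen, times)
    for arr in (traj.C_ADC, traj.C_ADC_per, traj.C_ECD, traj.C_ADC_ECD):
        assert np.all(arr >= 0)


def test_adc_mass_balance(human_tmdd):
    """Input = remaining drug (volume-weighted) + eliminated, rel err < 1e-6."""
    p = human_tmdd
    lin = p.linear
    dose = 1.0
    times = np.arange(0.0, 21.0 + 1e-9, 0.002)
    regimen = DosingRegimen.uniform(dose, 21.0, 1, infusion_h=1.0)
    traj = simulate_tmdd(p, regimen, times, rtol=1e-11, atol=1e-13)
    # amounts per kg in nmol: conc (nM = nmol/L) x V (L/kg)
    a_c = traj.C_ADC * lin.Vc / 1000.0
    a_p = traj.C_ADC_per * lin.Vp / 1000.0
    a_x = traj.C_ADC_ECD * lin.Vc / 1000.0  # complex resides in central
    elim = np.concatenate([[0.0], np.cumsum(
        np.diff(times) * 0.5 * (
            (lin.CL / 1000.0 * traj.C_ADC + p.kel_complex * traj.C_ADC_ECD * lin.Vc / 1000.0)[1:]
            + (lin.CL / 1000.0 * traj.C_ADC + p.kel_complex * traj.C_ADC_ECD * lin.Vc / 1000.0)[:-1]
        )
    )])
    from adcpkpd.pk_linear import NMOL_PER_MG_ADC

    dosed = np.where(times >= 1 / 24.0, dose * NMOL_PER_MG_ADC,
                     times * 24.0 * dose * NMOL_PER_MG_ADC)
    total = a_c + a_p + a_x + elim
    np.testing.assert_allclose(total[times > 0.5], dosed[times > 0.5], rtol=1e-5)


def test_dose_normalized_auc_monotone_in_dose(human_tmdd, grid_21d):
    """Saturable elimination: higher dose → higher dose-normalized exposure."""
    prev = -np.inf
    for dose in (0.15, 0.5, 1.0, 3.0):
        regimen = DosingRegimen.uniform(dose, 21.0, 1, infusion_h=1.0)
        traj = simulate_tmdd(human_tmdd, regimen, grid_21d)
        auc = np.trapezoid(traj.profile("free", "ug/mL").values, grid_21d)
        assert auc / dose > prev
        prev = auc / dose


def test_total_assay_exceeds_free(human_tmdd, grid_21d):
    regimen = DosingRegimen.uniform(0.3, 21.0, 1, infusion_h=1.0)
    traj = simulate_tmdd(human_tmdd, regimen, grid_21d)
    free = traj.profile("free", "nM").values
    total = traj.profile("total", "nM").values
    assert np.all(total >= free)


class TestNCA:
    def test_recovers_linear_clearance(self, grid_21d):
        lin = TwoCptParams(38.1, 5.52, 20.2, 14.9)
        times = np.arange(0.0, 120.0, 0.01)
        prof = simulate_2cpt(lin, DosingRegimen.uniform(1.0, 120.0, 1, infusion_h=1.0), times)
        m = nca_metrics(prof, dose=1.0)
        assert m["CL"] == pytest.approx(5.52, rel=0.005)

    def test_predicted_clearance_low_dose(self, human_tmdd, grid_21d):
        regimen = DosingRegimen.uniform(0.15, 21.0, 1, infusion_h=1.0)
        traj = simulate_tmdd(human_tmdd, regimen, grid_21d)
        m = nca_metrics(traj.profile("free", "ug/mL"), dose=0.15)
        assert m["CL"] == pytest.approx(33.6, rel=0.15)
        assert m["half_life"] == pytest.approx(1.0, rel=0.25)

    def test_predicted_clearance_and_half_life_high_dose(self, human_tmdd, grid_21d):
        regimen = DosingRegimen.uniform(3.0, 21.0, 1, infusion_h=1.0)
        traj = simulate_tmdd(human_tmdd, regimen, grid_21d)
        m = nca_metrics(traj.profile("free", "ug/mL"), dose=3.0)
        assert m["CL"] == pytest.approx(7.8, rel=0.15)
        assert m["half_life"] == pytest.approx(4.9, rel=0.20)

    def test_rejects_rising_terminal_window(self, human_tmdd):
        times = np.arange(0.0, 42.0, 0.05)
        regimen = DosingRegimen.uniform(1.0, 21.0, 2, infusion_h=1.0)
        traj = simulate_tmdd(human_tmdd, regimen, times)
        with pytest.raises(InvalidParameterError, match="terminal"):
            nca_metrics(traj.profile("free", "ug/mL"), dose=2.0,
                        terminal_window=(15.0, 25.0))


class TestFitECD:
    def test_noise_free_self_consistency(self, human_tmdd):
        days = np.array([0.1, 0.5, 1, 2, 4, 7, 10, 14, 21])
        regimen = DosingRegimen.uniform(1.0, 21.0, 1, infusion_h=1.0)
        truth = human_tmdd.with_ecd0(0.2)
        obs = simulate_tmdd(truth, regimen, days).profile("free", "nM")
        fitted = fit_ecd_to_profile(obs, human_tmdd, regimen, ecd_bounds=(0.16, 0.28))
        assert fitted == pytest.approx(0.2, abs=1e-4)

    def test_higher_baseline_target_lowers_exposure(self, human_tmdd, grid_21d):
        regimen = DosingRegimen.uniform(1.0, 21.0, 4, infusion_h=1.0)
        times = np.arange(0.0, 84.0, 0.05)
        low = simulate_tmdd(human_tmdd.with_ecd0(ugml_to_nm(2e-3) * 1.5), regimen, times)
        # 2 ng/mL and 750 ng/mL at ECD MW 100 kDa: 0.02 nM and 7.5 nM
        low = simulate_tmdd(human_tmdd.with_ecd0(0.02), regimen, times)
        high = simulate_tmdd(human_tmdd.with_ecd0(7.5), regimen, times)
        f_low = low.profile("free", "ug/mL").values
        f_high = high.profile("free", "ug/mL").values
        sel = times > 0.2
        assert np.all(f_high[sel] <= f_low[sel] + 1e-9)
        # trough ordering at every pre-dose time
        for t_trough in (20.9, 41.9, 62.9, 83.9):
            i = int(round(t_trough / 0.05))
            assert f_high[i] < f_low[i]

    def test_bound_optimum_warns(self, human_tmdd):
        days = np.array([0.1, 1, 4, 7, 14, 21])
        regimen = DosingRegimen.uniform(1.0, 21.0, 1, infusion_h=1.0)
        truth = human_tmdd.with_ecd0(0.5)  # outside the search bounds
        obs = simulate_tmdd(truth, regimen, days).profile("free", "nM")
        with pytest.warns(UserWarning, match="bound"):
            fit_ecd_to_profile(obs, human_tmdd, regimen, ecd_bounds=(0.16, 0.28))
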