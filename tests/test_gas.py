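"""Chamber flux, incubation rates with dilution correction, qPCR chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peatmethane.gas import (
    ChamberSeries,
    IncubationSeries,
    chamber_flux,
    dilution_correct,
    fit_standard_curve,
    potential_rate,
    ppm_to_ug,
    quantify_abundance,
    ug_to_ppm,
)
from peatmethane.synthetic import (
    GasSimConfig,
    simulate_chamber_series,
    simulate_incubation_series,
    simulate_qpcr_curve,
)


def _chamber(times, ppm, h=0.2, t_k=273.15, p_kpa=101.325):
    return ChamberSeries(times, ppm, h, t_k, p_kpa)


# --------------------------------------------------------------------------
# chamber flux
# --------------------------------------------------------------------------

class TestChamberFlux:
    def test_zero_slope_zero_flux(self):
        s = _chamber(np.arange(5) / 30.0, np.full(5, 1.9))
        assert chamber_flux(s).value == 0.0

    def test_hand_unit_analysis_case(self):
        # 1 ppm/h slope, H = 0.2 m, standard T and P:
        # 0.2 m3/m2 air column = 8.923 mol/m2 -> 0.1431 mg CH4 m-2 h-1
        t = np.linspace(0, 0.5, 16)
        s = _chamber(t, 1.9 + 1.0 * t)
        res = chamber_flux(s)
        assert res.value == pytest.approx(0.1431, abs=5e-5)
        assert res.slope_ppm_h == pytest.approx(1.0)

    def test_linear_in_height_and_slope(self):
        t = np.linspace(0, 0.5, 16)
        f1 = chamber_flux(_chamber(t, 1.9 + 1.0 * t, h=0.2)).value
        f2 = chamber_flux(_chamber(t, 1.9 + 1.0 * t, h=0.4)).value
        f3 = chamber_flux(_chamber(t, 1.9 + 2.0 * t, h=0.2)).value
        assert f2 == pytest.approx(2 * f1)
        assert f3 == pytest.approx(2 * f1)

    def test_temperature_scaling_inverse(self):
        t = np.linspace(0, 0.5, 16)
        f1 = chamber_flux(_chamber(t, 1.9 + 1.0 * t, t_k=273.15)).value
        f2 = chamber_flux(_chamber(t, 1.9 + 1.0 * t, t_k=2 * 273.15)).value
        assert f1 == pytest.approx(2 * f2)

    def test_noisy_regression_qc_flag(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 0.5, 16)
        s = _chamber(t, 1.9 + 0.01 * t + rng.normal(0, 0.5, 16))
        res = chamber_flux(s)
        assert res.r_squared < 0.9
        assert "low_r_squared" in res.qc_flags

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3"):
            chamber_flux(_chamber(np.array([0.0, 0.1]), np.array([1.0, 2.0])))


# --------------------------------------------------------------------------
# dilution correction and rates
# --------------------------------------------------------------------------

class TestDilutionCorrect:
    def test_zero_removal_identity(self):
        s = IncubationSeries(np.array([0.0, 24, 48]), np.array([2.0, 5.0, 8.0]),
                             90.0, 0.0, np.array([0.0, 24, 48]), 10.0, 0.9)
        out = dilution_correct(s)
        np.testing.assert_array_equal(out.ch4_ppm, s.ch4_ppm)
        assert out.dilution_corrected

    def test_single_prior_sampling_addback(self):
        # C1 = 100 ppm measured, V = 90 mL, v = 0.5 mL:
        # next point gains back 100*0.5/90 = 0.556 ppm
        s = IncubationSeries(np.array([0.0, 24.0]), np.array([100.0, 50.0]),
                             90.0, 0.5, np.array([0.0, 24.0]), 10.0, 0.9)
        out = dilution_correct(s)
        assert out.ch4_ppm[0] == pytest.approx(100.0)
        assert out.ch4_ppm[1] == pytest.approx(50.0 + 100.0 * 0.5 / 90.0, rel=1e-12)

    def test_mass_conservation_in_noiseless_simulation(self):
        cfg = GasSimConfig(true_rate=8.0, duration_h=72, sampling_interval_h=24,
                           noise_sd_ppm=0.0, headspace_ml=90.0, removal_ml=1.5,
                           initial_ppm=2.0)
        out = dilution_correct(simulate_incubation_series(cfg))
        # corrected final amount equals initial + produced
        expect_final = 2.0 + 8.0 * 72.0
        assert out.ch4_ppm[-1] == pytest.approx(expect_final, rel=1e-12)

    def test_sampling_times_must_be_in_series(self):
        with pytest.raises(ValueError, match="sampling times"):
            IncubationSeries(np.array([0.0, 24.0]), np.array([1.0, 2.0]),
                             90.0, 0.5, np.array([12.0]), 10.0, 0.9)


class TestPotentialRate:
    def test_flat_series_zero_rate(self):
        s = IncubationSeries(np.array([0.0, 24, 48, 72]), np.full(4, 10.0),
                             90.0, 0.0, np.array([0.0, 24, 48, 72]), 10.0, 0.9)
        res = potential_rate(dilution_correct(s), "production")
        assert res.value == pytest.approx(0.0, abs=1e-15)

    def test_roundtrip_production_recovery(self):
        cfg = GasSimConfig(true_rate=8.0, duration_h=72, sampling_interval_h=24,
                           noise_sd_ppm=0.0, headspace_ml=90.0, removal_ml=0.5,
                           initial_ppm=1.9, peat_fresh_mass_g=10.0, water_content=0.9)
        res = potential_rate(dilution_correct(simulate_incubation_series(cfg)),
                             "production")
        # expected: 8 ppm/h in 90 mL at 293.15 K -> ug/h * 24 / 1 g dry
        ug_per_h = ppm_to_ug(8.0, 90.0, 293.15, 101.325)
        expect = float(ug_per_h) * 24.0 / 1.0
        assert res.value == pytest.approx(expect, rel=1e-6)
        assert res.r_squared == pytest.approx(1.0)

    def test_oxidation_of_spiked_bottle(self):
        # 0.5 mL pure CH4 into 90 mL headspace ~ 5556 ppm, consumed linearly
        cfg = GasSimConfig(true_rate=-60.0, duration_h=72, sampling_interval_h=24,
                           noise_sd_ppm=0.0, headspace_ml=90.0, removal_ml=0.5,
                           initial_ppm=0.5 / 90.0 * 1e6)
        res = potential_rate(dilution_correct(simulate_incubation_series(cfg)),
                             "oxidation")
        expect = float(ppm_to_ug(60.0, 90.0, 293.15, 101.325)) * 24.0 / 1.0
        assert res.value == pytest.approx(expect, rel=1e-6)
        assert "sign_mismatch" not in res.qc_flags

    def test_halved_dry_mass_doubles_rate(self):
        base = GasSimConfig(true_rate=8.0, duration_h=72, sampling_interval_h=24,
                            noise_sd_ppm=0.0, removal_ml=0.0,
                            peat_fresh_mass_g=10.0, water_content=0.9)
        half = GasSimConfig(true_rate=8.0, duration_h=72, sampling_interval_h=24,
                            noise_sd_ppm=0.0, removal_ml=0.0,
                            peat_fresh_mass_g=5.0, water_content=0.9)
        r1 = potential_rate(dilution_correct(simulate_incubation_series(base)),
                            "production")
        r2 = potential_rate(dilution_correct(simulate_incubation_series(half)),
                            "production")
        assert r2.value == pytest.approx(2 * r1.value)

    def test_sign_mismatch_flagged(self):
        s = IncubationSeries(np.array([0.0, 24, 48, 72]),
                             np.array([100.0, 80.0, 60.0, 40.0]),
                             90.0, 0.0, np.array([0.0, 24, 48, 72]), 10.0, 0.9)
        res = potential_rate(dilution_correct(s), "production")
        assert "sign_mismatch" in res.qc_flags
        assert res.value < 0  # signed value still reported

    def test_uncorrected_series_rejected(self):
        s = IncubationSeries(np.array([0.0, 24, 48]), np.array([1.0, 2.0, 3.0]),
                             90.0, 0.5, np.array([0.0, 24, 48]), 10.0, 0.9)
        with pytest.raises(ValueError, match="corrected"):
            potential_rate(s, "production")


class TestUnitConversions:
    @given(
        ppm=st.floats(0.01, 1e5),
        vol=st.floats(10.0, 500.0),
        t_k=st.floats(250.0, 320.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_ppm_ug_roundtrip(self, ppm, vol, t_k):
        ug = ppm_to_ug(ppm, vol, t_k, 101.325)
        back = float(ug_to_ppm(ug, vol, t_k, 101.325))
        assert back == pytest.approx(ppm, rel=1e-12)


# --------------------------------------------------------------------------
# qPCR
# --------------------------------------------------------------------------

class TestStandardCurve:
    def test_textbook_slope_is_full_efficiency(self):
        logq = np.arange(3, 9, dtype=float)
        cq = 38.0 - 3.3219 * logq
        curve = fit_standard_curve(pd.DataFrame({"log10_quantity": logq, "cq": cq}))
        assert curve.efficiency == pytest.approx(1.0, abs=1e-4)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.qc_pass

    def test_efficiency_85pct_fails_qc(self):
        logq = np.arange(3, 9, dtype=float)
        cq = 38.0 - 3.743 * logq
        curve = fit_standard_curve(pd.DataFrame({"log10_quantity": logq, "cq": cq}))
        assert curve.efficiency == pytest.approx(0.850, abs=2e-3)
        assert not curve.qc_pass

    @pytest.mark.parametrize(
        "efficiency,expected_pass",
        [(0.90, True), (1.10, True), (0.8999, False), (1.1001, False)],
    )
    def test_qc_boundaries_inclusive(self, efficiency, expected_pass):
        slope = -1.0 / np.log10(1.0 + efficiency)
        logq = np.arange(2, 8, dtype=float)
        cq = 36.0 + slope * logq
        curve = fit_standard_curve(pd.DataFrame({"log10_quantity": logq, "cq": cq}))
        assert curve.qc_pass is expected_pass

    def test_positive_slope_rejected(self):
        logq = np.arange(3, 7, dtype=float)
        with pytest.raises(ValueError, match="slope"):
            fit_standard_curve(pd.DataFrame({"log10_quantity": logq, "cq": logq}))


class TestQuantify:
    @staticmethod
    def _perfect_curve():
        return fit_standard_curve(simulate_qpcr_curve(1.0, intercept=38.0,
                                                      n_dilutions=6, noise_sd=0.0))

    def test_cq_at_intercept_is_one_copy(self):
        curve = self._perfect_curve()
        res = quantify_abundance(curve, cq=38.0, eluate_volume_ul=1.0,
                                 template_volume_ul=1.0, fresh_mass_g=1.0)
        assert res.copies_in_reaction == pytest.approx(1.0)
        assert "extrapolated_beyond_standards" in res.flags

    def test_one_slope_step_is_ten_copies(self):
        curve = self._perfect_curve()
        res = quantify_abundance(curve, cq=38.0 + curve.slope, eluate_volume_ul=1.0,
                                 template_volume_ul=1.0, fresh_mass_g=1.0)
        assert res.copies_in_reaction == pytest.approx(10.0)

    def test_forward_model_roundtrip_per_gram(self):
        # construct a sample at 1e6 copies/g via the forward model
        curve = self._perfect_curve()
        target = 1e6
        eluate, template, mass = 100.0, 2.0, 0.5
        copies_rxn = target * mass / (eluate / template)
        cq = curve.intercept + curve.slope * np.log10(copies_rxn)
        res = quantify_abundance(curve, cq, eluate, template, mass)
        assert res.copies_per_g == pytest.approx(target, rel=1e-6)

    def test_failed_curve_attaches_warning(self):
        bad = fit_standard_curve(simulate_qpcr_curve(0.85, noise_sd=0.0))
        res = quantify_abundance(bad, cq=30.0, eluate_volume_ul=1.0,
                                 template_volume_ul=1.0, fresh_mass_g=1.0)
        assert "standard_curve_qc_failed" in res.flags
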