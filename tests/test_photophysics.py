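"""Unit and property tests for the forward photophysics relations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from dfon2p import (
    InstrumentParams,
    SpeciesParams,
    alpha_from_ensemble,
    bleaching_time,
    brightness_2p,
    calibrate_geometry_factor,
    cross_section_from_psat,
    excitation_rate,
    lorentz_local_field,
    photon_energy,
    psat_from_cross_section,
    pulse_train_emission,
    saturation_curve,
)
from dfon2p.photophysics import ModelAssumptionWarning


class TestPhotonEnergy:
    def test_infrared_photon(self):
        # hc/λ at 1030 nm
        assert photon_energy(1030.0) == pytest.approx(1.929e-19, rel=1e-3)

    @pytest.mark.parametrize("factor", [0.5, 2.0])
    def test_inverse_wavelength_scaling(self, factor):
        assert photon_energy(1030.0 * factor) == pytest.approx(
            photon_energy(1030.0) / factor
        )

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            photon_energy(0.0)


class TestLorentzLocalField:
    def test_vacuum_is_unity(self):
        assert lorentz_local_field(1.0) == pytest.approx(1.0)

    def test_printed_range_endpoints(self):
        # dye refractive indices 1.5 (off-resonance) to 3 (near resonance)
        assert round(lorentz_local_field(1.5)) == 2
        assert round(lorentz_local_field(3.0)) == 13
        assert lorentz_local_field(1.5) == pytest.approx(2.007, abs=5e-3)
        assert lorentz_local_field(3.0) == pytest.approx(13.44, abs=5e-2)

    def test_monotone_in_n(self):
        n = np.linspace(1.0, 3.0, 101)
        assert np.all(np.diff(lorentz_local_field(n)) > 0)

    def test_rejects_subunity_index(self):
        with pytest.raises(ValueError):
            lorentz_local_field(0.9)


class TestSaturationCurve:
    def test_anchors(self):
        assert saturation_curve(0.0, 17.3) == 0.0
        assert saturation_curve(17.3, 17.3) == pytest.approx(1.0 - math.exp(-1.0))

    def test_quadratic_low_power_limit(self):
        assert saturation_curve(1.73, 17.3) == pytest.approx(0.00995, abs=2e-5)
        p = 1e-4
        assert saturation_curve(p, 1.0) == pytest.approx(p**2, rel=1e-6)

    def test_monotone_and_bounded(self):
        p = np.linspace(0, 60, 300)
        f = saturation_curve(p, 17.3)
        assert np.all(np.diff(f) > 0)
        assert np.all(f < 1.0)

    def test_rejects_bad_psat(self):
        with pytest.raises(ValueError):
            saturation_curve(1.0, 0.0)


class TestExcitationRate:
    def test_quadratic_in_power(self, instrument):
        r1 = excitation_rate(2.0, instrument, 710.0)
        r2 = excitation_rate(4.0, instrument, 710.0)
        assert r2 == pytest.approx(4.0 * r1)

    def test_unity_excitation_per_pulse_at_psat(self, instrument):
        # saturation condition: Γ_exc(P_sat)·δt = 1, i.e. Γ_exc = 1/270 fs
        a2s2 = cross_section_from_psat(17.3, instrument)
        gam = excitation_rate(17.3, instrument, a2s2)
        assert gam * instrument.rect_pulse_dt_s == pytest.approx(1.0, rel=1e-12)
        assert gam == pytest.approx(3.70e12, rel=1e-2)


class TestCrossSectionPsatConversion:
    def test_calibrated_instrument_reproduces_published_pair(self, instrument):
        # κ is anchored on the first family; the second is then a prediction
        assert cross_section_from_psat(17.3, instrument) == pytest.approx(710.0)
        assert cross_section_from_psat(5.29, instrument) == pytest.approx(
            7580.0, rel=0.01
        )
        assert cross_section_from_psat(5.29, instrument) == pytest.approx(
            7594.0, rel=2e-3
        )

    def test_published_psats_from_cross_sections(self, instrument):
        assert psat_from_cross_section(710.0, instrument) == pytest.approx(17.3)

    @given(st.floats(min_value=0.1, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, psat):
        inst = InstrumentParams()
        a2s2 = cross_section_from_psat(psat, inst)
        assert psat_from_cross_section(a2s2, inst) == pytest.approx(psat, rel=1e-12)

    @pytest.mark.parametrize("x", [10.0, 710.0, 7580.0])
    def test_round_trip_reverse(self, x, instrument):
        got = cross_section_from_psat(psat_from_cross_section(x, instrument), instrument)
        assert got == pytest.approx(x, rel=1e-12)

    def test_inverse_square_scaling_is_calibration_free(self):
        # α²σ₂·P_sat² constant: the family ratio never depends on κ
        for kappa in (0.5, 1.0, 2.0):
            inst = InstrumentParams(geometry_factor=kappa)
            ratio = cross_section_from_psat(5.29, inst) / cross_section_from_psat(
                17.3, inst
            )
            assert ratio == pytest.approx((17.3 / 5.29) ** 2, rel=1e-12)
        assert (17.3 / 5.29) ** 2 == pytest.approx(7580.0 / 710.0, rel=0.01)

    def test_halving_psat_quadruples_cross_section(self, instrument):
        assert cross_section_from_psat(5.0, instrument) == pytest.approx(
            4.0 * cross_section_from_psat(10.0, instrument)
        )

    def test_calibration_sets_exact_anchor(self):
        inst = calibrate_geometry_factor(17.3, 710.0, InstrumentParams())
        assert cross_section_from_psat(17.3, inst) == pytest.approx(710.0, rel=1e-12)


class TestLocalFieldFromEnsemble:
    def test_published_family_values(self):
        assert round(alpha_from_ensemble(710.0, 60.0), 1) == 3.4
        assert round(alpha_from_ensemble(7580.0, 930.0), 1) == 2.9

    def test_equal_cross_sections_give_unity(self):
        assert alpha_from_ensemble(42.0, 42.0) == pytest.approx(1.0)


class TestBrightness:
    def test_table_rows(self, dfons1, dfons2):
        b1 = brightness_2p(dfons1.sigma2_GM, dfons1.phi, dfons1.n_molecules)
        b2 = brightness_2p(dfons2.sigma2_GM, dfons2.phi, dfons2.n_molecules)
        assert b1 == pytest.approx(148_500)
        assert b2 == pytest.approx(117_180)
        # both round to the same 10⁵-scale brightness: the design goal
        assert round(b1, -4) == 150_000 and round(b2, -4) == 120_000

    def test_identity_factors(self):
        assert brightness_2p(60.0, 1.0, 1) == 60.0


class TestBleachingTime:
    def test_anchor_and_quadratic_scaling(self):
        assert bleaching_time(17.3, 17.3, 1.06) == pytest.approx(1.06)
        assert bleaching_time(2 * 17.3, 17.3, 1.06) == pytest.approx(1.06 / 4)

    def test_family_ratio_is_about_three(self, dfons1, dfons2):
        p = 7.0  # any common excitation power
        ratio = bleaching_time(p, dfons1.psat_mW, dfons1.tau_b0_s) / bleaching_time(
            p, dfons2.psat_mW, dfons2.tau_b0_s
        )
        assert ratio == pytest.approx(2.95, abs=0.01)
        assert round(ratio) == 3

    def test_tau_times_power_squared_constant(self):
        p = np.array([1.0, 3.0, 10.0, 30.0])
        prod = bleaching_time(p, 5.29, 3.84) * p**2
        assert np.allclose(prod, prod[0])

    def test_zero_power_out_of_range(self):
        with pytest.raises(ValueError):
            bleaching_time(0.0, 17.3, 1.06)


class TestPulseTrainEmission:
    def test_normalized_rate_reproduces_saturation_curve(self, instrument, dfons1):
        a2s2 = 710.0
        psat = psat_from_cross_section(a2s2, instrument)
        p = np.linspace(0.1, 60.0, 40)
        rate = pulse_train_emission(p, instrument, dfons1, a2s2)
        plateau = (
            instrument.collection_efficiency
            * dfons1.n_molecules
            * dfons1.phi
            / instrument.rep_period_s
        )
        assert np.allclose(rate / plateau, saturation_curve(p, psat), rtol=1e-12)

    def test_saturates_at_one_photon_per_molecule_per_pulse(self, instrument, dfons1):
        rate = pulse_train_emission(1e4, instrument, dfons1, 710.0)
        plateau = (
            instrument.collection_efficiency
            * dfons1.n_molecules
            * dfons1.phi
            / instrument.rep_period_s
        )
        assert rate == pytest.approx(plateau, rel=1e-9)

    def test_linear_in_molecule_count(self, instrument, dfons1):
        r1 = pulse_train_emission(5.0, instrument, dfons1, 710.0, n_molecules=1000)
        r2 = pulse_train_emission(5.0, instrument, dfons1, 710.0, n_molecules=3000)
        assert r2 == pytest.approx(3.0 * r1)

    def test_warns_when_molecule_not_relaxed_between_pulses(self, instrument, dfons1):
        slow = SpeciesParams(
            name="slow", sigma2_GM=60.0, phi=0.33, diameter_nm=29.0,
            n_molecules=7500, gamma_rad_per_s=1e7,  # 1/Γ = 100 ns > T
        )
        with pytest.warns(ModelAssumptionWarning):
            pulse_train_emission(5.0, instrument, slow, 710.0)

    def test_closed_form_matches_rate_equation_integration(self, instrument):
        # independent oracle: integrate dg/dt = −Γ_exc(t)·g over one period
        # with the rectangular pulse profile; emission/pulse = 1 − g(T)
        dt = instrument.rect_pulse_dt_s
        a2s2 = 710.0
        powers = np.linspace(1.0, 60.0, 13)
        numeric = []
        for p in powers:
            gam = excitation_rate(p, instrument, a2s2)
            # after the pulse Γ_exc = 0, so g stays at g(δt) until the next one
            sol = solve_ivp(
                lambda t, g: [-gam * g[0]],
                (0.0, dt),
                [1.0],
                rtol=1e-12,
                atol=1e-15,
                max_step=dt / 50.0,
            )
            numeric.append(1.0 - sol.y[0, -1])
        psat = psat_from_cross_section(a2s2, instrument)
        closed = saturation_curve(powers, psat)
        assert np.allclose(numeric, closed, rtol=1e-6)


class TestInstrumentParams:
    def test_rectangular_pulse_is_twice_tau(self, instrument):
        assert instrument.rect_pulse_dt_s == pytest.approx(270e-15)

    def test_fwhm_reinterpretation_shortens_pulse(self):
        sech = InstrumentParams()
        fwhm = InstrumentParams(tau_is_fwhm=True)
        assert fwhm.rect_pulse_dt_s == pytest.approx(
            sech.rect_pulse_dt_s / 1.7627, rel=1e-4
        )

    def test_psf_sigma_convention(self, instrument):
        # fluorescence PSF σ = W₀/√2 ≈ 255 nm for W₀ = 360 nm
        assert instrument.psf_sigma_nm == pytest.approx(254.6, abs=0.1)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"wavelength_nm": -1.0},
            {"collection_efficiency": 0.0},
            {"collection_efficiency": 1.2},
            {"pulse_tau_s": 1e-8},  # δt would exceed the period
        ],
    )
    def test_invariant_violations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            InstrumentParams(**kwargs)
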