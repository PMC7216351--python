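"""Generative-platform behaviour: pressure coupling, catalogs, sources,
motion, session determinism and noise calibration."""

import dataclasses

import numpy as np
import pytest

import seeplab as sl
from seeplab.circuit import band_grid, interface_impedance_complex, pair_impedance_complex
from seeplab.errors import (
    InvalidParameterError,
    RangeError,
    SamplingRateError,
)
from seeplab.features import aci_band_features
from seeplab.platforms import (
    LOWER_POTENTIAL_SHARE,
    SAMPLE_NAMES,
    _lower_reference,
    simulate_motion,
)


class TestPressureModulate:
    def test_zero_force_is_identity(self, catalog):
        s = catalog[0]
        assert sl.pressure_modulate(s.base, 0.0, s) == s.base

    def test_saturation_limits(self, catalog):
        s = catalog[0]
        # far beyond saturation the scales approach their asymptotes
        mod = sl.pressure_modulate(s.base, 1e9, s)
        assert mod.R_c / s.base.R_c == pytest.approx(1 / (1 + s.kappa_R), rel=1e-6)
        assert mod.C_t / s.base.C_t == pytest.approx(1 + s.kappa_C, rel=1e-6)

    def test_half_saturation_halves_contact_resistance(self, textile_params):
        sample = sl.ElectrodeSample(
            name="x", base=textile_params, kappa_R=2.0, kappa_C=1.0, F_half=0.5
        )
        mod = sl.pressure_modulate(textile_params, 0.5, sample)
        # s = 0.5 -> scale 1/(1 + 2*0.5) = 0.5
        assert mod.R_c == pytest.approx(textile_params.R_c * 0.5)
        assert mod.R_d == pytest.approx(textile_params.R_d * 0.5)

    def test_skin_side_untouched(self, catalog):
        s = catalog[0]
        mod = sl.pressure_modulate(s.base, 2.0, s)
        for name in ("R_e", "C_e", "R_p", "C_p", "R_a"):
            assert getattr(mod, name) == getattr(s.base, name)

    def test_negative_force_rejected(self, catalog):
        with pytest.raises(InvalidParameterError):
            sl.pressure_modulate(catalog[0].base, -0.1, catalog[0])


class TestSampleCatalog:
    def test_deterministic_and_sized(self):
        a = sl.sample_catalog(7)
        b = sl.sample_catalog(7)
        assert len(a) == 10
        assert a == b  # bitwise-identical dataclasses

    def test_names_follow_the_rack(self, catalog):
        assert tuple(s.name for s in catalog) == SAMPLE_NAMES

    def test_samples_valid_and_finite_at_10hz(self, catalog):
        for s in catalog:
            z = abs(interface_impedance_complex(s.base, 10.0))
            assert np.isfinite(z) and z > 0
            assert s.base.kind == "textile"
            # the monotone-trend guarantee requires kappa_R <= 2 kappa_C
            assert s.kappa_R <= 2.0 * s.kappa_C + 1e-12


class TestSourceSignals:
    def test_sine_amplitude_and_length(self):
        t, x = sl.synth_source_signal("sine", 1.0, 1.0, 1.0, 500.0)
        assert x.size == 500
        assert np.ptp(x) == pytest.approx(2.0, rel=1e-3)

    def test_ecg_peak_count_matches_heart_rate(self):
        _, x = sl.synth_source_signal("ecg", 60.0, 1.0, 10.0, 500.0)
        above = x > 0.5
        crossings = int(np.sum(above[1:] & ~above[:-1]))
        assert crossings == 10
        assert x.max() == pytest.approx(1.0, abs=1e-3)

    def test_source_is_deterministic(self):
        a = sl.synth_source_signal("ecg", 72.0, 1.5, 5.0, 500.0)[1]
        b = sl.synth_source_signal("ecg", 72.0, 1.5, 5.0, 500.0)[1]
        assert np.array_equal(a, b)

    def test_band_and_rate_validation(self):
        with pytest.raises(RangeError):
            sl.synth_source_signal("sine", 300.0, 1.0, 1.0, 1000.0)
        with pytest.raises(SamplingRateError):
            sl.synth_source_signal("sine", 100.0, 1.0, 1.0, 150.0)
        with pytest.raises(SamplingRateError):
            sl.synth_source_signal("ecg", 60.0, 1.0, 1.0, 50.0)


class TestMotion:
    def test_zero_speed_is_flat(self):
        prof = simulate_motion(0.0, 20.0, 10.0)
        assert np.all(prof.displacement_mm == 0)
        assert np.all(prof.z_factor == 1.0)
        assert np.all(prof.pv_artifact_mv == 0.0)

    def test_cycle_kinematics(self):
        # 10 mm/s over 20 mm: out in 2 s, back in 2 s -> 4 s per cycle
        prof = simulate_motion(10.0, 20.0, 8.0, rate=100.0)
        t = prof.time_s
        d = prof.displacement_mm
        assert d[np.argmin(np.abs(t - 2.0))] == pytest.approx(20.0, abs=0.2)
        assert d[np.argmin(np.abs(t - 4.0))] == pytest.approx(0.0, abs=0.2)
        assert d[np.argmin(np.abs(t - 6.0))] == pytest.approx(20.0, abs=0.2)
        assert prof.mean_speed_mm_s == pytest.approx(10.0)

    @pytest.mark.parametrize("speed,path", [(41.0, 20.0), (10.0, 150.0), (-1.0, 10.0)])
    def test_out_of_range_rejected(self, speed, path):
        with pytest.raises(RangeError):
            simulate_motion(speed, path, 5.0)


class TestSessions:
    def test_noise_off_spectra_are_exact(self, quiet_sample, coarse_levels):
        session = sl.simulate_peep_session(quiet_sample, coarse_levels, seed=11)
        for rec in session.records:
            z = pair_impedance_complex(rec.stack, rec.spectrum.frequency_hz)
            assert np.array_equal(rec.spectrum.magnitude_ohm, np.abs(z))
            np.testing.assert_allclose(
                rec.spectrum.phase_deg, np.degrees(np.angle(z)), atol=1e-12
            )

    def test_fixed_seed_reproduces_session(self, catalog, coarse_levels):
        a = sl.simulate_peep_session(catalog[1], coarse_levels, seed=5)
        b = sl.simulate_peep_session(catalog[1], coarse_levels, seed=5)
        for ra, rb in zip(a.records, b.records):
            assert np.array_equal(ra.spectrum.magnitude_ohm, rb.spectrum.magnitude_ohm)
            assert np.array_equal(ra.pv.values, rb.pv.values)
            assert np.array_equal(ra.pressure_upper.values, rb.pressure_upper.values)

    def test_pressure_excursions_within_tolerance(self, catalog, coarse_levels):
        sample = dataclasses.replace(catalog[0], noise=sl.NoiseSpec(sigma_f=1.8))
        session = sl.simulate_peep_session(sample, coarse_levels, seed=2)
        for rec in session.records:
            excursion = np.abs(rec.pressure_upper.values - rec.set_point_n * 100.0)
            assert np.max(excursion) <= 1.8

    def test_out_of_range_level_rejected(self, catalog):
        with pytest.raises(RangeError):
            sl.simulate_peep_session(catalog[0], [7.0], seed=0)

    def test_lower_electrode_keeps_fixed_potential_share(self, catalog):
        ref = _lower_reference(catalog[0].base)
        assert ref.total_potential == pytest.approx(
            catalog[0].base.total_potential * LOWER_POTENTIAL_SHARE
        )


class TestAeepSignals:
    def test_unbounded_input_no_noise_is_identity(self, quiet_sample):
        session = sl.simulate_aeep_session(
            quiet_sample, [1.0], z_in=None, seed=4,
            source={"kind": "sine", "f_or_hr": 10.0, "amplitude": 1.0,
                    "duration": 2.0, "rate": 500.0},
        )
        np.testing.assert_allclose(
            session.signals.sfme_mv, session.signals.sfsg_mv, atol=1e-12
        )

    def test_divider_scales_sine_by_transfer_gain(self, quiet_sample):
        """With noise off, a sine through a finite-input divider comes out
        scaled by exactly |H(f)| of the session's own stack."""
        session = sl.simulate_aeep_session(
            quiet_sample, [1.0], z_in=2e4, seed=4,
            source={"kind": "sine", "f_or_hr": 10.0, "amplitude": 2.0,
                    "duration": 4.0, "rate": 500.0},
        )
        h = abs(sl.transfer_function(session.records[0].stack, 10.0))

        def rms(x):
            return np.sqrt(np.mean(x ** 2))

        # RMS over an integer number of cycles is phase-shift invariant
        ratio = rms(session.signals.sfme_mv) / rms(session.signals.sfsg_mv)
        assert ratio == pytest.approx(h, rel=1e-9)

    def test_noise_adds_broadband_power(self, catalog):
        sample = dataclasses.replace(
            catalog[0], noise=dataclasses.replace(catalog[0].noise, sigma_sig=0.05)
        )
        session = sl.simulate_aeep_session(sample, [1.0], seed=9)
        sg, me = session.signals.sfsg_mv, session.signals.sfme_mv
        # compare power above the source bandwidth where SFSG is empty
        spec_sg = np.abs(np.fft.rfft(sg)) ** 2
        spec_me = np.abs(np.fft.rfft(me)) ** 2
        freqs = np.fft.rfftfreq(sg.size, 1 / session.signals.sampling_rate_hz)
        high = freqs > 150.0
        assert spec_me[high].sum() > spec_sg[high].sum()

    def test_aeep_with_noise_off_and_finite_zin_attenuates(self, quiet_sample):
        session = sl.simulate_aeep_session(
            quiet_sample, [1.0], z_in=1e5, seed=4,
            source={"kind": "sine", "f_or_hr": 10.0, "amplitude": 1.0,
                    "duration": 2.0, "rate": 500.0},
        )
        assert np.ptp(session.signals.sfme_mv) < np.ptp(session.signals.sfsg_mv)


class TestNoiseCalibration:
    def test_uniform_half_ranges_match_spec(self):
        """Empirical half-range of each injected noise channel matches the
        configured tolerance within 5% over 10^4 draws."""
        rng = np.random.default_rng(31)
        for half in (0.14, 1.85, 0.65, 1.8):
            draws = rng.uniform(-half, half, 10_000)
            assert np.abs(draws).max() == pytest.approx(half, rel=0.05)
            assert np.abs(draws).max() <= half

    def test_session_impedance_noise_bounded_by_sigma_z(self, catalog):
        sample = dataclasses.replace(
            catalog[0],
            noise=sl.NoiseSpec(sigma_z=0.14, sigma_phase=0.0, sigma_pv=0.0,
                               sigma_f=0.0, sigma_sig=0.0, sigma_skin=0.0),
        )
        session = sl.simulate_peep_session(sample, [1.0], seed=3)
        rec = session.records[0]
        z = np.abs(pair_impedance_complex(rec.stack, rec.spectrum.frequency_hz))
        err = rec.spectrum.magnitude_ohm - z
        assert np.max(np.abs(err)) <= 0.14
        assert np.max(np.abs(err)) > 0.14 * 0.8  # noise actually injected


class TestMonotoneTrends:
    def test_noise_free_band_features_decrease_with_force(self, quiet_sample):
        """Every AC band feature of the swept electrode, and the pair
        polarization voltage, are non-increasing along a noise-free force
        sweep — the generative encoding of the observed pressure trends."""
        grid = band_grid()
        levels = sl.default_pressure_levels()
        features = []
        pveps = []
        for f_n in levels:
            mod = sl.pressure_modulate(quiet_sample.base, f_n, quiet_sample)
            z = interface_impedance_complex(mod, grid)
            spec = sl.ImpedanceSpectrum.from_complex(grid, z)
            features.append(aci_band_features(spec))
            upper_pot = mod.total_potential
            lower_pot = quiet_sample.base.total_potential * LOWER_POTENTIAL_SHARE
            pveps.append(abs(upper_pot - lower_pot))
        features = np.array(features)
        assert np.all(np.diff(features, axis=0) < 0)
        assert np.all(np.diff(pveps) <= 1e-12)
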