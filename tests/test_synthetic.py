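"""Synthetic A-line generator: calibration, pulse spectrum, echo placement."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import echopress as ep
from echopress.exceptions import CalibrationError, ConfigurationError
from echopress.features import analytic_envelope, detect_echoes, parabolic_peak_fit
from echopress.impedance import reflection_coefficient, transmission_product


class TestIopToImpedances:
    @pytest.mark.parametrize(
        "iop, idx, expected",
        [(10.0, 1, 1.5393), (50.0, 0, 1.5519), (30.0, 1, (1.5393 + 1.5698) / 2)],
    )
    def test_endpoints_and_midpoint(self, cal, iop, idx, expected):
        assert ep.iop_to_impedances(iop, cal)[idx] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("iop", [5.0, 55.0, -1.0])
    def test_out_of_range(self, cal, iop):
        with pytest.raises(ValueError, match="outside calibration range"):
            ep.iop_to_impedances(iop, cal)


class TestEndpointCalibration:
    def test_z0_solves_ratio_equation(self, constants, cal):
        ratio = 2.1454 / 1.6347
        resid = (
            reflection_coefficient(constants.Z0, cal.Z1_high)
            / reflection_coefficient(constants.Z0, cal.Z1_low)
            - ratio
        )
        assert abs(resid) < 1e-10
        assert 0 < constants.Z0 < cal.Z1_low
        assert constants.Z0 == pytest.approx(1.502, abs=5e-4)

    def test_incident_amplitude_from_anterior_endpoint(self, constants, cal):
        assert constants.A0 == pytest.approx(
            1.6347 / reflection_coefficient(constants.Z0, cal.Z1_low), rel=1e-12
        )
        assert constants.A0 == pytest.approx(131.6, abs=0.1)

    def test_forward_reproduces_endpoint_amplitudes(self, constants, cal):
        # Self-consistency: the calibrated forward model returns all three
        # input amplitudes at the endpoints.
        for iop, ant_amp in [(10.0, 1.6347), (50.0, 2.1454)]:
            stack = ep.stack_at_iop(cal, constants, iop)
            a1, _ = ep.forward_amplitudes(stack)
            assert a1 == pytest.approx(ant_amp, rel=1e-9)
        _, ar_low = ep.forward_amplitudes(ep.stack_at_iop(cal, constants, 10.0))
        assert ar_low == pytest.approx(0.5778, rel=1e-9)

    def test_recovers_constructed_z0(self, cal):
        z0_true = 1.45
        low = 1.0
        high = low * (
            reflection_coefficient(z0_true, cal.Z1_high)
            / reflection_coefficient(z0_true, cal.Z1_low)
        )
        out = ep.calibrate_stack_constants(ant_amp_low=low, ant_amp_high=high,
                                           post_amp_low=0.5, cal=cal)
        assert out.Z0 == pytest.approx(z0_true, rel=1e-10)

    def test_no_root_raises(self, cal):
        # A decreasing anterior amplitude has no Z0 solution below the cornea.
        with pytest.raises(CalibrationError):
            ep.calibrate_stack_constants(ant_amp_low=2.0, ant_amp_high=1.8, cal=cal)
        with pytest.raises(CalibrationError):
            ep.calibrate_stack_constants(ant_amp_low=1.0, ant_amp_high=1.0, cal=cal)


class TestGaussianPulse:
    def test_unit_peak_envelope(self, tspec):
        pulse = ep.gaussian_pulse(tspec, dt=1e-9)
        assert pulse[pulse.size // 2] == pytest.approx(1.0)
        assert np.max(np.abs(pulse)) <= 1.0 + 1e-12

    def test_minus6db_bandwidth_and_centre(self, tspec):
        dt = 1e-9
        pulse = ep.gaussian_pulse(tspec, dt)
        n = 1 << 18  # zero-pad for ~4 kHz frequency resolution
        spec = np.abs(np.fft.rfft(pulse, n))
        freqs = np.fft.rfftfreq(n, dt)
        peak = spec.max()
        assert freqs[np.argmax(spec)] == pytest.approx(47e6, abs=1.5 / (n * dt))
        above = freqs[spec >= peak * 10 ** (-6 / 20)]
        width = above.max() - above.min()
        assert width == pytest.approx(0.62 * 47e6, rel=0.02)


class TestSimulateAline:
    def test_zero_contrast_suppresses_anterior_echo(self, constants, tspec, aspec_quiet):
        stack = ep.LayerStack(Z0=1.52, Z1=1.52, Z2=1.56, Z3=1.52,
                              posterior_gain=0.5, A0=100.0)
        rec = ep.simulate_aline(stack, tspec, aspec_quiet, 30.0, np.random.default_rng(0))
        n = rec.samples.size
        # Anterior echo sits at 25% of the record: that quarter must be silent.
        anterior_region = rec.samples[: int(0.35 * n)]
        assert np.max(np.abs(anterior_region)) < 1e-12

    def test_echo_time_difference_matches_geometry(self, cal, constants, tspec, aspec_quiet):
        stack = ep.stack_at_iop(cal, constants, 30.0)
        rec = ep.simulate_aline(stack, tspec, aspec_quiet, 30.0, np.random.default_rng(0))
        env = analytic_envelope(rec.samples)
        (a0, a1), (p0, p1) = detect_echoes(env, rec.dt)
        t_ant = a0 + np.argmax(env[a0:a1])
        t_post = p0 + np.argmax(env[p0:p1])
        measured = (t_post - t_ant) * rec.dt
        assert abs(measured - stack.tof_difference) <= rec.dt

    def test_noiseless_peaks_match_closed_form(self, cal, constants, tspec, aspec_quiet):
        # Envelope-ripple bound: extracted peak amplitudes within 0.5% of the
        # reflection-model amplitudes, at both endpoint pressures.
        for iop in (10.0, 50.0):
            stack = ep.stack_at_iop(cal, constants, iop)
            a1, ar = ep.forward_amplitudes(stack)
            rec = ep.simulate_aline(stack, tspec, aspec_quiet, iop,
                                    np.random.default_rng(0))
            ant, post = ep.extract_features(rec)
            assert ant.amplitude == pytest.approx(a1, rel=5e-3)
            assert post.amplitude == pytest.approx(ar, rel=5e-3)
            assert post.polarity == -1  # Z2 > Z3: phase-inverted echo

    def test_same_seed_reproduces_samples(self, cal, constants, tspec):
        stack = ep.stack_at_iop(cal, constants, 20.0)
        aspec = ep.AcquisitionSpec()
        recs = [
            ep.simulate_aline(stack, tspec, aspec, 20.0, np.random.default_rng(7))
            for _ in range(2)
        ]
        np.testing.assert_array_equal(recs[0].samples, recs[1].samples)

    def test_unresolvable_echoes_rejected(self, constants, tspec, aspec_quiet, cal):
        stack = ep.LayerStack(Z0=constants.Z0, Z1=1.54, Z2=1.56, Z3=constants.Z3,
                              cornea_thickness=5e-6, A0=constants.A0)
        with pytest.raises(ConfigurationError, match="not resolvable"):
            ep.simulate_aline(stack, tspec, aspec_quiet, 30.0, np.random.default_rng(0))

    def test_anterior_amplitude_increases_with_contrast(self, constants, tspec, aspec_quiet):
        # Monotonicity in |Z1 - Z0| verified on extracted (not closed-form) peaks.
        amps = []
        for z1 in (1.52, 1.55, 1.60, 1.70):
            stack = ep.LayerStack(Z0=1.502, Z1=z1, Z2=1.57, Z3=1.502, A0=100.0,
                                  posterior_gain=0.4)
            rec = ep.simulate_aline(stack, tspec, aspec_quiet, 30.0,
                                    np.random.default_rng(0))
            ant, _ = ep.extract_features(rec)
            amps.append(ant.amplitude)
        assert np.all(np.diff(amps) > 0)


class TestSimulateExperiment:
    def test_default_design_counts(self, cal, constants, tspec):
        aspec = ep.AcquisitionSpec(seed=1)
        records = ep.simulate_experiment(cal, constants, tspec, aspec)
        assert len(records) == 5 * 3 * 10
        iops = sorted({r.iop for r in records})
        assert iops == [10.0, 20.0, 30.0, 40.0, 50.0]

    def test_single_record_design(self, cal, constants, tspec):
        aspec = ep.AcquisitionSpec(n_alines=1, n_repeats=1, seed=1)
        records = ep.simulate_experiment(cal, constants, tspec, aspec, iops=[30.0])
        assert len(records) == 1

    def test_dataset_regeneration_is_bit_identical(self, cal, constants, tspec, tmp_path):
        aspec = ep.AcquisitionSpec(n_alines=2, n_repeats=1, seed=11)
        from echopress.io import write_aline_dataset

        manifests = []
        for sub in ("a", "b"):
            records = ep.simulate_experiment(cal, constants, tspec, aspec, iops=[10.0, 50.0])
            mpath = write_aline_dataset(records, tmp_path / sub)
            manifests.append(mpath.read_bytes())
        assert manifests[0] == manifests[1]


class TestReferenceEcho:
    def test_quartz_peak_amplitude(self, constants, tspec, cal):
        stack = ep.stack_at_iop(cal, constants, 10.0)
        rec = ep.simulate_reference_echo(2650.0, 5750.0, stack, tspec,
                                         ep.AcquisitionSpec())
        # Zq = 15.2375 MRayl -> R = 0.8205 relative to Z0 = 1.502; the echo
        # is centred on a sample, so the RF peak equals the envelope peak.
        peak = np.max(np.abs(rec.samples))
        assert peak == pytest.approx(stack.A0 * 0.8205, rel=1e-3)

    def test_matched_impedance_gives_no_echo(self, constants, tspec, cal):
        stack = ep.stack_at_iop(cal, constants, 10.0)
        # density * speed = Z0 exactly
        rec = ep.simulate_reference_echo(1000.0, stack.Z0 * 1e3, stack, tspec,
                                         ep.AcquisitionSpec())
        assert np.max(np.abs(rec.samples)) < 1e-12

    def test_linear_in_incident_amplitude(self, constants, tspec, cal):
        aspec = ep.AcquisitionSpec()
        s1 = ep.stack_at_iop(cal, constants, 10.0)
        s2 = ep.LayerStack(Z0=s1.Z0, Z1=s1.Z1, Z2=s1.Z2, Z3=s1.Z3,
                           posterior_gain=s1.posterior_gain, A0=2 * s1.A0)
        r1 = ep.simulate_reference_echo(2650.0, 5750.0, s1, tspec, aspec)
        r2 = ep.simulate_reference_echo(2650.0, 5750.0, s2, tspec, aspec)
        np.testing.assert_allclose(r2.samples, 2 * r1.samples, atol=1e-12)


@given(
    z1_a=st.floats(min_value=1.51, max_value=1.8),
    z1_b=st.floats(min_value=1.51, max_value=1.8),
)
def test_anterior_contrast_monotonicity_closed_form(z1_a, z1_b):
    """|R(Z0, .)| is strictly ordered by |Z1 - Z0| above Z0."""
    z0 = 1.502
    r_a = abs(reflection_coefficient(z0, z1_a))
    r_b = abs(reflection_coefficient(z0, z1_b))
    if abs(z1_a - z0) < abs(z1_b - z0):
        assert r_a < r_b
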