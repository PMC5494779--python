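"""Synthetic pulse-echo A-line generator for the corneal reflectometry pipeline.

Emulates the acquisition geometry the analysis assumes: a highly focused
47-MHz transducer (62% fractional bandwidth at -6 dB) insonifying an eye
immersed in saline, sampled at 1 GHz, 10 A-lines per acquisition and 3
repeats per eye, at five IOP levels from 10 to 50 mmHg.  Each A-line holds
two temporally separated echoes — anterior and posterior corneal surface —
whose envelope-peak amplitudes follow the single-interface and three-layer
reflection models of :mod:`echopress.impedance`, plus additive white
Gaussian noise.

Ground truth varies linearly with IOP between configurable endpoint
impedances, and :func:`calibrate_stack_constants` solves for the saline
impedance Z0, the incident amplitude A0 and the posterior geometric gain
that make the forward model reproduce a given set of endpoint echo
amplitudes, so simulated data are self-consistent with the analysis stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .exceptions import CalibrationError, ConfigurationError
from .impedance import reflection_coefficient, transmission_product

__all__ = [
    "TransducerSpec",
    "AcquisitionSpec",
    "LayerStack",
    "IOPCalibration",
    "ALineRecord",
    "StackConstants",
    "iop_to_impedances",
    "calibrate_stack_constants",
    "gaussian_pulse",
    "pulse_envelope_sigma",
    "simulate_aline",
    "simulate_experiment",
    "simulate_reference_echo",
    "stack_at_iop",
]

# Fraction of the record duration at which the anterior echo is centred.
# With the 4096-sample/1-GHz defaults this puts the anterior surface at
# ~1.02 us and leaves room for the posterior echo ~1.01 us later.
ANTERIOR_ARRIVAL_FRACTION = 0.25

# Amplitude ratio at -6 dB and the implied half-width factor of a Gaussian
# magnitude spectrum: full -6 dB width = 2*sqrt(2*ln(1/ratio)) * sigma_f.
_MINUS6DB_RATIO = 10.0 ** (-6.0 / 20.0)
_MINUS6DB_WIDTH_FACTOR = 2.0 * np.sqrt(2.0 * np.log(1.0 / _MINUS6DB_RATIO))

# Half-support of the generated pulse in units of the envelope sigma; the
# Gaussian tail beyond 5 sigma is < 4e-6 of the peak.
_PULSE_HALF_WIDTH_SIGMAS = 5.0


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class TransducerSpec:
    """Single-element transducer: centre frequency (Hz) and -6 dB fractional bandwidth."""

    center_frequency: float = 47e6
    fractional_bandwidth: float = 0.62

    def __post_init__(self) -> None:
        _require(self.center_frequency > 0, "center_frequency must be > 0")
        _require(
            0 < self.fractional_bandwidth < 2,
            "fractional_bandwidth must lie in (0, 2)",
        )


@dataclass(frozen=True)
class AcquisitionSpec:
    """Digitiser and experiment-design parameters.

    ``noise_sd`` is the per-sample standard deviation of the additive
    Gaussian noise in amplitude units; ``None`` means 1% of the anterior
    echo amplitude of the record being generated.
    """

    sampling_rate: float = 1e9
    n_alines: int = 10
    n_repeats: int = 3
    noise_sd: float | None = None
    record_length: int = 4096
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.sampling_rate > 0, "sampling_rate must be > 0")
        _require(self.n_alines >= 1, "n_alines must be >= 1")
        _require(self.n_repeats >= 1, "n_repeats must be >= 1")
        if self.noise_sd is not None:
            _require(self.noise_sd >= 0, "noise_sd must be >= 0")
        _require(self.record_length > 0, "record_length must be > 0")

    def validate_against(self, tspec: TransducerSpec) -> None:
        """Nyquist-with-margin check: sampling_rate >= 4 x centre frequency."""
        if self.sampling_rate < 4.0 * tspec.center_frequency:
            raise ConfigurationError(
                f"sampling_rate {self.sampling_rate:g} Hz < 4 x centre frequency "
                f"{tspec.center_frequency:g} Hz"
            )


@dataclass(frozen=True)
class LayerStack:
    """Impedance stack and propagation constants for one acquisition.

    Z0..Z3 in MRayl (saline, anterior cornea, posterior cornea, aqueous
    humor); corneal thickness (m) and longitudinal speed (m/s) set the
    anterior-posterior time-of-flight difference 2*thickness/speed;
    ``posterior_gain`` is the scalar curvature/defocus factor on the
    posterior echo; ``A0`` the incident amplitude in arbitrary units.
    """

    Z0: float
    Z1: float
    Z2: float
    Z3: float
    cornea_thickness: float = 0.8e-3
    cornea_speed: float = 1580.0
    posterior_gain: float = 1.0
    A0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("Z0", "Z1", "Z2", "Z3"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        _require(self.cornea_thickness > 0, "cornea_thickness must be > 0")
        _require(self.cornea_speed > 0, "cornea_speed must be > 0")
        _require(self.posterior_gain > 0, "posterior_gain must be > 0")
        _require(self.A0 > 0, "A0 must be > 0")

    @property
    def tof_difference(self) -> float:
        """Round-trip anterior-to-posterior delay, 2 d / c, in seconds."""
        return 2.0 * self.cornea_thickness / self.cornea_speed


@dataclass(frozen=True)
class IOPCalibration:
    """Linear IOP -> impedance map between measured endpoints.

    Defaults are the study endpoints: anterior 1.5399 -> 1.5519 MRayl and
    posterior 1.5393 -> 1.5698 MRayl over 10 -> 50 mmHg.
    """

    iop_low: float = 10.0
    iop_high: float = 50.0
    Z1_low: float = 1.5399
    Z1_high: float = 1.5519
    Z2_low: float = 1.5393
    Z2_high: float = 1.5698

    def __post_init__(self) -> None:
        _require(self.iop_low < self.iop_high, "iop_low must be < iop_high")
        for name in ("Z1_low", "Z1_high", "Z2_low", "Z2_high"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")


@dataclass(frozen=True)
class ALineRecord:
    """One sampled RF trace with its provenance."""

    samples: np.ndarray
    dt: float
    iop: float
    eye_id: str = "eye01"
    repeat_id: int = 0
    aline_id: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        _require(self.dt > 0, "dt must be > 0")


@dataclass(frozen=True)
class StackConstants:
    """Calibration output: the IOP-independent constants of a LayerStack."""

    Z0: float
    A0: float
    posterior_gain: float
    Z3: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.Z3 is None:
            object.__setattr__(self, "Z3", self.Z0)


def iop_to_impedances(iop: float, cal: IOPCalibration) -> tuple[float, float]:
    """Ground-truth (Z1, Z2) at a pressure, linear between the endpoints."""
    if not (cal.iop_low <= iop <= cal.iop_high):
        raise ValueError(
            f"iop = {iop} mmHg outside calibration range "
            f"[{cal.iop_low}, {cal.iop_high}]"
        )
    frac = (iop - cal.iop_low) / (cal.iop_high - cal.iop_low)
    Z1 = cal.Z1_low + frac * (cal.Z1_high - cal.Z1_low)
    Z2 = cal.Z2_low + frac * (cal.Z2_high - cal.Z2_low)
    return Z1, Z2


def calibrate_stack_constants(
    ant_amp_low: float = 1.6347,
    ant_amp_high: float = 2.1454,
    post_amp_low: float = 0.5778,
    cal: IOPCalibration | None = None,
) -> StackConstants:
    """Solve for (Z0, A0, posterior_gain) from endpoint echo amplitudes.

    The anterior amplitude ratio between the high- and low-pressure
    endpoints depends only on Z0 once the endpoint impedances are fixed:

        R(Z0, Z1_high) / R(Z0, Z1_low) = ant_amp_high / ant_amp_low,

    solved for Z0 in (0, min(Z1_low, Z1_high)) by Brent root finding.
    Then A0 = ant_amp_low / R(Z0, Z1_low), and the posterior gain is set so
    the three-layer forward model (with Z3 = Z0) reproduces the posterior
    amplitude at the low endpoint.  The defaults are the study's measured
    endpoint amplitudes.
    """
    cal = cal or IOPCalibration()
    _require(ant_amp_low > 0 and ant_amp_high > 0, "anterior amplitudes must be > 0")
    _require(post_amp_low > 0, "posterior amplitude must be > 0")
    ratio = ant_amp_high / ant_amp_low
    if np.isclose(ratio, 1.0, rtol=0, atol=1e-12):
        raise CalibrationError("amplitude ratio equals 1: Z0 unidentifiable")

    z_max = min(cal.Z1_low, cal.Z1_high)

    def residual(z0: float) -> float:
        return (
            reflection_coefficient(z0, cal.Z1_high)
            / reflection_coefficient(z0, cal.Z1_low)
            - ratio
        )

    lo, hi = 1e-9 * z_max, z_max * (1.0 - 1e-12)
    if residual(lo) * residual(hi) > 0:
        raise CalibrationError(
            f"no Z0 root in (0, {z_max:g}) MRayl for amplitude ratio {ratio:g}"
        )
    Z0 = brentq(residual, lo, hi, xtol=1e-15, rtol=1e-15)
    A0 = ant_amp_low / reflection_coefficient(Z0, cal.Z1_low)
    gain = post_amp_low / (
        A0
        * transmission_product(Z0, cal.Z1_low)
        * abs(reflection_coefficient(cal.Z2_low, Z0))
    )
    return StackConstants(Z0=Z0, A0=A0, posterior_gain=gain)


def pulse_envelope_sigma(tspec: TransducerSpec) -> float:
    """Gaussian envelope sigma (s) implied by the -6 dB fractional bandwidth.

    A Gaussian envelope exp(-t^2 / 2 sigma_t^2) has a Gaussian magnitude
    spectrum with sigma_f = 1/(2 pi sigma_t); the -6 dB full width is
    2 sqrt(2 ln(10^(6/20))) sigma_f and must equal
    fractional_bandwidth * centre_frequency.
    """
    bw = tspec.fractional_bandwidth * tspec.center_frequency
    sigma_f = bw / _MINUS6DB_WIDTH_FACTOR
    return 1.0 / (2.0 * np.pi * sigma_f)


def gaussian_pulse(tspec: TransducerSpec, dt: float) -> np.ndarray:
    """Unit-peak Gaussian-enveloped cosine pulse, centred in its own window.

    The window spans +-5 envelope sigmas; the envelope maximum is exactly 1
    at the centre sample.
    """
    _require(dt > 0, "dt must be > 0")
    if 1.0 / dt < 4.0 * tspec.center_frequency:
        raise ConfigurationError(
            f"dt = {dt:g} s undersamples a {tspec.center_frequency:g} Hz pulse"
        )
    sigma = pulse_envelope_sigma(tspec)
    half = int(np.ceil(_PULSE_HALF_WIDTH_SIGMAS * sigma / dt))
    t = (np.arange(2 * half + 1) - half) * dt
    return np.exp(-0.5 * (t / sigma) ** 2) * np.cos(2.0 * np.pi * tspec.center_frequency * t)


def _signed_echo_amplitudes(stack: LayerStack) -> tuple[float, float]:
    """Signed envelope-peak amplitudes (anterior, posterior) of the two echoes."""
    a1 = stack.A0 * reflection_coefficient(stack.Z0, stack.Z1)
    ar = (
        stack.A0
        * transmission_product(stack.Z0, stack.Z1)
        * reflection_coefficient(stack.Z2, stack.Z3)
        * stack.posterior_gain
    )
    return a1, ar


def _add_echo(samples: np.ndarray, amp: float, tau: float, dt: float,
              tspec: TransducerSpec) -> None:
    """Add amp * env(t - tau) * cos(2 pi fc (t - tau)) in place (exact sub-sample delay)."""
    sigma = pulse_envelope_sigma(tspec)
    n = samples.size
    half = _PULSE_HALF_WIDTH_SIGMAS * sigma
    i0 = max(0, int(np.floor((tau - half) / dt)))
    i1 = min(n, int(np.ceil((tau + half) / dt)) + 1)
    if i0 >= i1:
        return
    t = np.arange(i0, i1) * dt - tau
    samples[i0:i1] += amp * np.exp(-0.5 * (t / sigma) ** 2) * np.cos(
        2.0 * np.pi * tspec.center_frequency * t
    )


def simulate_aline(
    stack: LayerStack,
    tspec: TransducerSpec,
    aspec: AcquisitionSpec,
    iop: float,
    rng: np.random.Generator,
    eye_id: str = "eye01",
    repeat_id: int = 0,
    aline_id: int = 0,
) -> ALineRecord:
    """Simulate one RF A-line with anterior and posterior corneal echoes.

    The anterior echo is centred at a fixed fraction of the record and the
    posterior echo 2*thickness/speed later; each carries the signed
    amplitude of the reflection model, so the posterior echo is
    phase-inverted when Z2 > Z3.  White Gaussian noise of standard
    deviation ``aspec.noise_sd`` (default: 1% of the anterior amplitude)
    is added per sample.
    """
    aspec.validate_against(tspec)
    dt = 1.0 / aspec.sampling_rate
    duration = aspec.record_length * dt
    sigma = pulse_envelope_sigma(tspec)
    sep = stack.tof_difference
    pulse_duration = 2.0 * _PULSE_HALF_WIDTH_SIGMAS * sigma
    if sep <= pulse_duration:
        raise ConfigurationError(
            f"echo separation {sep:.3g} s <= pulse duration {pulse_duration:.3g} s: "
            "echoes not resolvable"
        )
    tau_a = ANTERIOR_ARRIVAL_FRACTION * duration
    tau_p = tau_a + sep
    if tau_p + pulse_duration / 2.0 >= duration:
        raise ConfigurationError(
            f"posterior echo at {tau_p:.3g} s does not fit in a {duration:.3g} s record"
        )

    a1, ar = _signed_echo_amplitudes(stack)
    samples = np.zeros(aspec.record_length)
    _add_echo(samples, a1, tau_a, dt, tspec)
    _add_echo(samples, ar, tau_p, dt, tspec)

    noise_sd = aspec.noise_sd if aspec.noise_sd is not None else 0.01 * abs(a1)
    if noise_sd > 0:
        samples += rng.normal(0.0, noise_sd, size=samples.shape)

    return ALineRecord(
        samples=samples, dt=dt, iop=iop,
        eye_id=eye_id, repeat_id=repeat_id, aline_id=aline_id,
    )


def simulate_experiment(
    cal: IOPCalibration,
    constants: StackConstants,
    tspec: TransducerSpec,
    aspec: AcquisitionSpec,
    iops: Sequence[float] = (10.0, 20.0, 30.0, 40.0, 50.0),
    cornea_thickness: float = 0.8e-3,
    cornea_speed: float = 1580.0,
    eye_id: str = "eye01",
) -> list[ALineRecord]:
    """Simulate the full pressure-sweep design.

    For each IOP level, n_repeats x n_alines records are generated with the
    ground-truth impedances of :func:`iop_to_impedances`.  Per-record RNG
    streams are spawned deterministically from ``aspec.seed``, so the same
    configuration reproduces the same dataset bit for bit.
    """
    if len(iops) == 0:
        raise ValueError("iops must be nonempty")
    ss = np.random.SeedSequence(aspec.seed)
    children = ss.spawn(len(iops) * aspec.n_repeats * aspec.n_alines)
    records: list[ALineRecord] = []
    k = 0
    for iop in iops:
        Z1, Z2 = iop_to_impedances(iop, cal)
        stack = LayerStack(
            Z0=constants.Z0, Z1=Z1, Z2=Z2, Z3=constants.Z3,
            cornea_thickness=cornea_thickness, cornea_speed=cornea_speed,
            posterior_gain=constants.posterior_gain, A0=constants.A0,
        )
        for rep in range(aspec.n_repeats):
            for al in range(aspec.n_alines):
                rng = np.random.default_rng(children[k])
                k += 1
                records.append(
                    simulate_aline(
                        stack, tspec, aspec, iop, rng,
                        eye_id=eye_id, repeat_id=rep, aline_id=al,
                    )
                )
    return records


def simulate_reference_echo(
    quartz_density: float,
    quartz_speed: float,
    stack: LayerStack,
    tspec: TransducerSpec,
    aspec: AcquisitionSpec,
) -> ALineRecord:
    """Noiseless single echo from a quartz reference reflector.

    The quartz impedance is Zq = density * speed; the echo's envelope peak
    is A0 (Zq - Z0)/(Zq + Z0).  Used to emulate the incident-amplitude
    calibration measurement.
    """
    _require(quartz_density > 0, "quartz_density must be > 0")
    _require(quartz_speed > 0, "quartz_speed must be > 0")
    aspec.validate_against(tspec)
    Zq = quartz_density * quartz_speed / 1e6
    amp = stack.A0 * reflection_coefficient(stack.Z0, Zq)
    dt = 1.0 / aspec.sampling_rate
    duration = aspec.record_length * dt
    tau = ANTERIOR_ARRIVAL_FRACTION * duration
    samples = np.zeros(aspec.record_length)
    _add_echo(samples, amp, tau, dt, tspec)
    return ALineRecord(samples=samples, dt=dt, iop=float("nan"), eye_id="reference")


def stack_at_iop(
    cal: IOPCalibration,
    constants: StackConstants,
    iop: float,
    cornea_thickness: float = 0.8e-3,
    cornea_speed: float = 1580.0,
) -> LayerStack:
    """Ground-truth LayerStack at one pressure (convenience for tests/pipeline)."""
    Z1, Z2 = iop_to_impedances(iop, cal)
    return LayerStack(
        Z0=constants.Z0, Z1=Z1, Z2=Z2, Z3=constants.Z3,
        cornea_thickness=cornea_thickness, cornea_speed=cornea_speed,
        posterior_gain=constants.posterior_gain, A0=constants.A0,
    )
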