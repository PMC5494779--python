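"""Layered reflection/transmission models for corneal pulse-echo reflectometry.

The cornea immersed in saline is treated as a three-layer stack

    saline (Z0) | anterior cornea (Z1) | posterior cornea (Z2) | aqueous humor (Z3)

with all impedances in MRayl (1 MRayl = 1e6 kg m^-2 s^-1) and normal-incidence
pressure-amplitude coefficients.  The anterior echo obeys the single-interface
reflection law

    A1 / A0 = (Z1 - Z0) / (Z1 + Z0)

and the posterior echo the two-way three-layer chain

    Ar / A0 = T01 * R23 * T10 * g,

where T01 = 2 Z1 / (Z1 + Z0), T10 = 2 Z0 / (Z1 + Z0),
R23 = (Z3 - Z2) / (Z3 + Z2), and g is a scalar geometric gain absorbing the
curvature/defocus loss of the non-planar posterior interface.  Both relations
are invertible in closed form, which is what this module provides, together
with the quartz-reference calibration of the incident amplitude A0.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .exceptions import InversionError

__all__ = [
    "ReflectionSetup",
    "ImpedanceEstimate",
    "reflection_coefficient",
    "transmission_product",
    "calibrate_incident_amplitude",
    "invert_anterior",
    "invert_posterior",
    "forward_amplitudes",
    "invert_feature_table",
]


def _check_positive(**values: float) -> None:
    for name, v in values.items():
        if not np.all(np.asarray(v) > 0):
            raise ValueError(f"{name} must be > 0, got {v!r}")


@dataclass(frozen=True)
class ReflectionSetup:
    """Calibration constants shared by all inversions of one experiment.

    Parameters
    ----------
    Z0 : float
        Acoustic impedance of the coupling saline, MRayl.
    Z3 : float
        Acoustic impedance of the aqueous humor, MRayl.  Defaults to Z0
        (both dilute aqueous media).
    A0 : float
        Incident pulse amplitude in the same arbitrary units as the
        measured echo amplitudes.
    posterior_gain : float
        Scalar geometric gain applied multiplicatively to the posterior
        echo (curvature/defocus of the non-planar interface).
    posterior_sign : {"auto", 1, -1}
        Sign of R23 used when inverting envelope magnitudes.  "auto"
        assumes Z2 > Z3 (cornea denser than aqueous humor), i.e. R23 < 0.
    """

    Z0: float
    A0: float
    Z3: float | None = None
    posterior_gain: float = 1.0
    posterior_sign: Literal["auto", 1, -1] = "auto"

    def __post_init__(self) -> None:
        _check_positive(Z0=self.Z0, A0=self.A0, posterior_gain=self.posterior_gain)
        if self.Z3 is None:
            object.__setattr__(self, "Z3", self.Z0)
        _check_positive(Z3=self.Z3)
        if self.posterior_sign not in ("auto", 1, -1):
            raise ValueError("posterior_sign must be 'auto', 1 or -1")


@dataclass(frozen=True)
class ImpedanceEstimate:
    """One inverted impedance with provenance."""

    Z: float
    surface: Literal["anterior", "posterior"]
    iop: float | None = None
    inputs_hash: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        _check_positive(Z=self.Z)


def _hash_inputs(*args: float) -> str:
    return hashlib.sha256(repr(tuple(float(a) for a in args)).encode()).hexdigest()[:16]


def reflection_coefficient(Z_a: float, Z_b: float) -> float:
    """Signed pressure reflection coefficient (Z_b - Z_a)/(Z_b + Z_a).

    Antisymmetric in its arguments and confined to (-1, 1) for positive
    impedances.
    """
    _check_positive(Z_a=Z_a, Z_b=Z_b)
    return (Z_b - Z_a) / (Z_b + Z_a)


def transmission_product(Z0: float, Z1: float) -> float:
    """Two-way transmission T01*T10 = 4 Z0 Z1 / (Z0 + Z1)**2 across one interface.

    Equals 1 - R01**2 (pressure-amplitude conservation), hence lies in (0, 1].
    """
    _check_positive(Z0=Z0, Z1=Z1)
    return 4.0 * Z0 * Z1 / (Z0 + Z1) ** 2


def calibrate_incident_amplitude(
    reference_amp: float,
    quartz_density: float,
    quartz_speed: float,
    Z0: float,
) -> float:
    """Recover the incident amplitude A0 from a quartz reference echo.

    A flat quartz plate of known density (kg/m^3) and longitudinal speed
    (m/s) has impedance Zq = density * speed; its echo amplitude is
    A0 * (Zq - Z0)/(Zq + Z0), so A0 = reference_amp * (Zq + Z0)/(Zq - Z0).
    """
    _check_positive(
        reference_amp=reference_amp,
        quartz_density=quartz_density,
        quartz_speed=quartz_speed,
        Z0=Z0,
    )
    Zq = quartz_density * quartz_speed / 1e6  # Rayl -> MRayl
    if np.isclose(Zq, Z0, rtol=0, atol=1e-12):
        raise InversionError("quartz impedance equals Z0: singular calibration")
    return reference_amp * (Zq + Z0) / (Zq - Z0)


def invert_anterior(
    A1: float,
    setup: ReflectionSetup,
    iop: float | None = None,
    polarity: int = 1,
) -> ImpedanceEstimate:
    """Invert the anterior echo amplitude for Z1.

    With R = A1/A0 the single-interface law gives
    Z1 = Z0 (A0 + A1)/(A0 - A1) on the default branch Z1 > Z0.  A
    ``polarity`` of -1 (echo phase-inverted, Z1 < Z0) selects the mirror
    branch Z1 = Z0 (A0 - A1)/(A0 + A1).
    """
    if A1 < 0:
        raise InversionError(f"amplitude must be nonnegative, got {A1}")
    if A1 >= setup.A0:
        raise InversionError(
            f"A1 = {A1} >= A0 = {setup.A0}: implied reflection coefficient >= 1"
        )
    if polarity not in (1, -1):
        raise ValueError("polarity must be +1 or -1")
    if polarity == 1:
        Z1 = setup.Z0 * (setup.A0 + A1) / (setup.A0 - A1)
    else:
        Z1 = setup.Z0 * (setup.A0 - A1) / (setup.A0 + A1)
    return ImpedanceEstimate(
        Z=Z1, surface="anterior", iop=iop, inputs_hash=_hash_inputs(A1, setup.Z0, setup.A0)
    )


def invert_posterior(
    Ar: float,
    Z1: float,
    setup: ReflectionSetup,
    iop: float | None = None,
) -> ImpedanceEstimate:
    """Invert the posterior echo amplitude for Z2 through the three-layer chain.

    |R23| = Ar / (A0 * T01*T10(Z0, Z1) * g); the sign of R23 follows
    ``setup.posterior_sign`` ("auto" assumes Z2 > Z3 so R23 < 0); then
    Z2 = Z3 (1 - R23)/(1 + R23).
    """
    if Ar < 0:
        raise InversionError(f"amplitude must be nonnegative, got {Ar}")
    _check_positive(Z1=Z1)
    tt = transmission_product(setup.Z0, Z1)
    mag = Ar / (setup.A0 * tt * setup.posterior_gain)
    if mag >= 1.0:
        raise InversionError(f"implied |R23| = {mag:.4g} >= 1: not invertible")
    sign = -1 if setup.posterior_sign == "auto" else setup.posterior_sign
    R23 = sign * mag
    Z2 = setup.Z3 * (1.0 - R23) / (1.0 + R23)
    return ImpedanceEstimate(
        Z=Z2,
        surface="posterior",
        iop=iop,
        inputs_hash=_hash_inputs(Ar, Z1, setup.Z0, setup.Z3, setup.A0, setup.posterior_gain),
    )


def forward_amplitudes(stack) -> tuple[float, float]:
    """Predicted echo envelope magnitudes (A1, Ar) for a layer stack.

    A1 = A0 |R(Z0, Z1)|;  Ar = A0 T01 T10 |R23| g.  Accepts any object
    with Z0..Z3, A0 and posterior_gain attributes (e.g.
    :class:`echopress.synthetic.LayerStack`).
    """
    A1 = stack.A0 * abs(reflection_coefficient(stack.Z0, stack.Z1))
    Ar = (
        stack.A0
        * transmission_product(stack.Z0, stack.Z1)
        * abs(reflection_coefficient(stack.Z2, stack.Z3))
        * stack.posterior_gain
    )
    return A1, Ar


def invert_feature_table(features: pd.DataFrame, setup: ReflectionSetup) -> pd.DataFrame:
    """Invert every A-line of a feature table to (Z1, Z2).

    Expects the columns written by :func:`echopress.features.build_feature_table`
    (iop_mmHg, eye_id, repeat_id, aline_id, ant_amp, post_amp, ...); returns a
    table with one (Z1_MRayl, Z2_MRayl) row per A-line.
    """
    rows = []
    for rec in features.itertuples(index=False):
        z1 = invert_anterior(rec.ant_amp, setup, iop=rec.iop_mmHg)
        z2 = invert_posterior(rec.post_amp, z1.Z, setup, iop=rec.iop_mmHg)
        rows.append(
            {
                "iop_mmHg": rec.iop_mmHg,
                "eye_id": rec.eye_id,
                "repeat_id": rec.repeat_id,
                "aline_id": rec.aline_id,
                "Z1_MRayl": z1.Z,
                "Z2_MRayl": z2.Z,
            }
        )
    return pd.DataFrame(rows)
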