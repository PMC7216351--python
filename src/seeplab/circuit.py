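"""Lumped-element models of the skin-electrode electrochemical interface.

A biopotential electrode couples to the body through an electrochemical
interface that is well described, over the biosignal band (sub-Hz to a few
hundred Hz), by a network of resistors, capacitors and DC offset potentials:

* an electrode double layer — charge-transfer resistance ``R_d`` in parallel
  with the double-layer capacitance ``C_d``, offset by the half-cell
  potential ``E_hc``;
* the epidermis — ``R_e`` parallel ``C_e`` with skin potential ``E_sc``,
  shunted by the sweat-gland path ``R_p`` parallel ``C_p`` with potential
  ``E_p``;
* the dermis and deeper tissue — a plain resistance ``R_a``.

Wet (gel) electrodes add a series gel resistance ``R_s``.  Dry textile
electrodes replace the gel by a fabric contact that behaves capacitively:
a coupling capacitance ``C_t`` (scaled down by skin moisture, since sweat
shorts the fabric gap) in parallel with an ohmic contact resistance ``R_c``
through the fibres that actually touch the skin.  The ohmic path is what
keeps the DC (static) impedance of a dry electrode finite.

Units are fixed throughout the package: resistances in ohm, capacitances in
microfarad, potentials in millivolt, frequency in hertz, phase in degrees.

All impedance functions accept scalar or array frequency and evaluate the
closed-form network impedance; because every branch is a resistor-capacitor
one-port, the resulting impedance is passive (non-negative real part), its
phase stays within [-90, 0] degrees, and its magnitude is non-increasing in
frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import CoverageError, InvalidParameterError

__all__ = [
    "InterfaceParams",
    "PairStack",
    "ComplexImpedance",
    "ImpedanceSpectrum",
    "band_grid",
    "fitting_grid",
    "parallel_rc_impedance",
    "interface_impedance",
    "interface_impedance_complex",
    "pair_impedance",
    "pair_impedance_complex",
    "pair_polarization_voltage",
    "transfer_function",
    "dc_leakage_current",
]

_TWO_PI = 2.0 * math.pi

#: fields that must be positive on every interface
_POSITIVE_COMMON = ("C_d", "R_d", "C_e", "R_e", "C_p", "R_p", "R_a")


@dataclass(frozen=True)
class InterfaceParams:
    """Circuit parameters of one electrode's skin interface.

    Parameters
    ----------
    kind:
        ``"wet"`` (gel electrode, has ``R_s``) or ``"textile"`` (dry fabric
        electrode, has ``C_t`` and ``R_c``).
    E_hc, E_sc, E_p:
        Half-cell, skin-interface and sweat-gland potentials (mV).  They do
        not enter the AC impedance; their sum sets the electrode's
        contribution to the pair polarization voltage.
    C_d, R_d:
        Double-layer capacitance (uF) and charge-transfer resistance (ohm).
    C_e, R_e, C_p, R_p:
        Epidermis and sweat-path capacitances (uF) and resistances (ohm).
    R_a:
        Dermis resistance (ohm).
    R_s:
        Gel series resistance (ohm), wet electrodes only.
    C_t, R_c:
        Fabric coupling capacitance (uF) and ohmic contact resistance (ohm),
        textile electrodes only.
    moisture:
        Dimensionless skin-moisture index (> 0).  The effective coupling
        capacitance is ``C_t / moisture`` — a sweatier contact couples
        capacitively more strongly (smaller capacitive reactance is modelled
        here via the inverse-proportional law).
    """

    kind: str
    E_hc: float
    C_d: float
    R_d: float
    E_sc: float
    C_e: float
    R_e: float
    E_p: float
    C_p: float
    R_p: float
    R_a: float
    R_s: float | None = None
    C_t: float | None = None
    R_c: float | None = None
    moisture: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("wet", "textile"):
            raise InvalidParameterError(f"unknown interface kind {self.kind!r}")
        for name in _POSITIVE_COMMON:
            v = getattr(self, name)
            if not (v is not None and v > 0):
                raise InvalidParameterError(f"{name} must be > 0, got {v!r}")
        if not self.moisture > 0:
            raise InvalidParameterError(f"moisture must be > 0, got {self.moisture!r}")
        if self.kind == "wet":
            if self.R_s is None or not self.R_s > 0:
                raise InvalidParameterError("wet interface requires R_s > 0")
            if self.C_t is not None or self.R_c is not None:
                raise InvalidParameterError("wet interface must not define C_t/R_c")
        else:
            if self.C_t is None or not self.C_t > 0:
                raise InvalidParameterError("textile interface requires C_t > 0")
            if self.R_c is None or not self.R_c > 0:
                raise InvalidParameterError("textile interface requires R_c > 0")
            if self.R_s is not None:
                raise InvalidParameterError("textile interface must not define R_s")

    @property
    def total_potential(self) -> float:
        """Sum of DC offset potentials E_hc + E_sc + E_p (mV)."""
        return self.E_hc + self.E_sc + self.E_p

    @property
    def C_t_eff(self) -> float | None:
        """Moisture-scaled fabric coupling capacitance (uF), textile only."""
        if self.C_t is None:
            return None
        return self.C_t / self.moisture

    def replace(self, **changes) -> "InterfaceParams":
        """Return a copy with the given fields replaced (revalidated)."""
        return replace(self, **changes)


@dataclass(frozen=True)
class PairStack:
    """A two-electrode measurement stack on the simulated skin model.

    The measured impedance is the series path electrode 1 -> tissue
    (electrolyte) -> electrode 2.  ``Z_in`` is the magnitude of the
    (resistive) amplifier input impedance; ``None`` means an ideal,
    unbounded input.
    """

    electrode_1: InterfaceParams
    electrode_2: InterfaceParams
    R_tissue: float = 150.0
    Z_in: float | None = None

    def __post_init__(self) -> None:
        if self.R_tissue < 0:
            raise InvalidParameterError("R_tissue must be >= 0")
        if self.Z_in is not None and not self.Z_in > 0:
            raise InvalidParameterError("Z_in must be > 0 or None (unbounded)")


@dataclass(frozen=True)
class ComplexImpedance:
    """Polar representation of a complex impedance (ohm, degrees)."""

    magnitude: float | np.ndarray
    phase_deg: float | np.ndarray

    @classmethod
    def from_complex(cls, z: complex | np.ndarray) -> "ComplexImpedance":
        return cls(magnitude=np.abs(z), phase_deg=np.degrees(np.angle(z)))

    def to_complex(self) -> complex | np.ndarray:
        return self.magnitude * np.exp(1j * np.radians(self.phase_deg))


@dataclass
class ImpedanceSpectrum:
    """Impedance magnitude and phase sampled on a frequency grid."""

    frequency_hz: np.ndarray
    magnitude_ohm: np.ndarray
    phase_deg: np.ndarray

    def __post_init__(self) -> None:
        self.frequency_hz = np.asarray(self.frequency_hz, dtype=float)
        self.magnitude_ohm = np.asarray(self.magnitude_ohm, dtype=float)
        self.phase_deg = np.asarray(self.phase_deg, dtype=float)
        if not (
            self.frequency_hz.ndim
            == self.magnitude_ohm.ndim
            == self.phase_deg.ndim
            == 1
        ):
            raise InvalidParameterError("spectrum arrays must be one-dimensional")
        n = self.frequency_hz.size
        if self.magnitude_ohm.size != n or self.phase_deg.size != n:
            raise InvalidParameterError("spectrum arrays must have equal length")
        if n == 0:
            raise InvalidParameterError("spectrum must contain at least one point")
        if np.any(self.frequency_hz < 0):
            raise InvalidParameterError("frequencies must be >= 0")
        if n > 1 and np.any(np.diff(self.frequency_hz) <= 0):
            raise InvalidParameterError("frequencies must be strictly increasing")
        if np.any(self.magnitude_ohm < 0):
            raise InvalidParameterError("impedance magnitude must be >= 0")

    def __len__(self) -> int:
        return int(self.frequency_hz.size)

    @classmethod
    def from_complex(cls, frequency_hz, z) -> "ImpedanceSpectrum":
        z = np.asarray(z)
        return cls(frequency_hz, np.abs(z), np.degrees(np.angle(z)))

    def to_complex(self) -> np.ndarray:
        return self.magnitude_ohm * np.exp(1j * np.radians(self.phase_deg))

    def covers(self, f: float) -> bool:
        return bool(self.frequency_hz[0] <= f <= self.frequency_hz[-1])

    def magnitude_at(self, f: float) -> float:
        """Magnitude at ``f`` (ohm), linearly interpolated on the grid."""
        if not self.covers(f):
            raise CoverageError(
                f"spectrum grid [{self.frequency_hz[0]:g}, "
                f"{self.frequency_hz[-1]:g}] Hz does not cover {f:g} Hz"
            )
        return float(np.interp(f, self.frequency_hz, self.magnitude_ohm))


def band_grid() -> np.ndarray:
    """Default linear grid for band features: 0.1 to 100 Hz, step 0.1 Hz."""
    return np.linspace(0.1, 100.0, 1000)


def fitting_grid() -> np.ndarray:
    """Default logarithmic grid for circuit fitting: 0.1-200 Hz, ~50 pts/decade."""
    n = int(round(50 * math.log10(200.0 / 0.1))) + 1
    return np.logspace(math.log10(0.1), math.log10(200.0), n)


def _zrc(R: float, C_uf: float, f) -> np.ndarray | complex:
    """Complex impedance of R parallel C at frequency f (C in uF)."""
    w = _TWO_PI * np.asarray(f, dtype=float)
    return R / (1.0 + 1j * w * R * (C_uf * 1e-6))


def _parallel(z1, z2):
    return z1 * z2 / (z1 + z2)


def parallel_rc_impedance(R: float, C: float, f) -> ComplexImpedance:
    """Impedance of a parallel RC block: ``R / (1 + j*2*pi*f*R*C)``.

    Parameters: R in ohm, C in uF, f in Hz (scalar or array, >= 0).
    At f = 0 the capacitor is open and the block is purely resistive.
    """
    if not R > 0 or not C > 0:
        raise InvalidParameterError("parallel RC requires R > 0 and C > 0")
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise InvalidParameterError("frequency must be >= 0")
    return ComplexImpedance.from_complex(_zrc(R, C, f))


def interface_impedance_complex(params: InterfaceParams, f) -> np.ndarray | complex:
    """Complex impedance of one skin-electrode interface at frequency f.

    Wet:     (R_d || C_d) + R_s + [(R_e || C_e) || (R_p || C_p)] + R_a
    Textile: (R_c || C_t_eff) + (R_d || C_d)
             + [(R_e || C_e) || (R_p || C_p)] + R_a

    DC offset potentials do not enter the impedance.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise InvalidParameterError("frequency must be >= 0")
    skin = _parallel(
        _zrc(params.R_e, params.C_e, f), _zrc(params.R_p, params.C_p, f)
    )
    z = _zrc(params.R_d, params.C_d, f) + skin + params.R_a
    if params.kind == "wet":
        return z + params.R_s
    return z + _zrc(params.R_c, params.C_t_eff, f)


def interface_impedance(params: InterfaceParams, f) -> ComplexImpedance:
    """Magnitude/phase of one interface's impedance (see the complex form)."""
    return ComplexImpedance.from_complex(interface_impedance_complex(params, f))


def pair_impedance_complex(stack: PairStack, f) -> np.ndarray | complex:
    """Complex series impedance electrode 1 + tissue + electrode 2."""
    return (
        interface_impedance_complex(stack.electrode_1, f)
        + stack.R_tissue
        + interface_impedance_complex(stack.electrode_2, f)
    )


def pair_impedance(stack: PairStack, f) -> ComplexImpedance:
    """Magnitude/phase of the electrode-pair impedance."""
    return ComplexImpedance.from_complex(pair_impedance_complex(stack, f))


def pair_spectrum(stack: PairStack, frequency_hz) -> ImpedanceSpectrum:
    """Noise-free pair impedance sampled on a grid, as a spectrum."""
    z = pair_impedance_complex(stack, frequency_hz)
    return ImpedanceSpectrum.from_complex(np.asarray(frequency_hz, float), z)


def pair_polarization_voltage(stack: PairStack) -> float:
    """Polarization voltage of the pair (mV).

    The open-circuit DC offset seen between the two electrodes:
    ``|(E_hc + E_sc + E_p)_1 - (E_hc + E_sc + E_p)_2|``.
    """
    return abs(stack.electrode_1.total_potential - stack.electrode_2.total_potential)


def transfer_function(stack: PairStack, f) -> np.ndarray | complex:
    """Source-to-amplifier voltage transfer H(f) = Z_in / (Z_in + Z_pair).

    ``Z_in`` is treated as a purely resistive input impedance; ``None``
    (unbounded) gives H = 1 at all frequencies.  For any passive pair
    impedance |H| <= 1.
    """
    f = np.asarray(f, dtype=float)
    if stack.Z_in is None:
        return np.ones_like(f, dtype=complex) if f.ndim else complex(1.0)
    return stack.Z_in / (stack.Z_in + pair_impedance_complex(stack, f))


def dc_leakage_current(stack: PairStack, drive: float) -> float:
    """Peak-to-peak current (uA) driven through the pair at DC.

    ``drive`` is the peak-to-peak test voltage in mV; the current is
    ``drive / |Z_pair(0)|`` by Ohm's law.  Used by the disposable-ECG
    compliance check, whose limit is 100 uA peak-to-peak.
    """
    if drive < 0:
        raise InvalidParameterError("drive voltage must be >= 0")
    z0 = abs(pair_impedance_complex(stack, 0.0))
    if z0 == 0.0:
        raise ZeroDivisionError("pair has zero DC impedance")
    return float(drive) / float(z0) * 1e3
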