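"""Generative twin of the passive/active electrochemical evaluation platforms.

The physical platforms press a pair of electrodes against hydrophilic
membranes sealing an electrolyte-filled vessel (the simulated skin model),
sweep the contact force, and record per force level: the static impedance
trace, the AC impedance spectrum, the polarization-voltage trace and the
contact-pressure traces.  The active platform (AEEP) additionally injects a
source signal (sine or synthetic ECG) into the electrolyte and records the
source signal (SFSG) alongside the signal seen through the electrode pair
(SFME).

This module reproduces those measurement sessions from the circuit models:

* contact pressure modulates the contact-dependent circuit elements through
  a saturating law ``s(F) = F / (F + F_half)`` — resistive contact elements
  shrink as ``1 / (1 + kappa_R * s)``, contact capacitances grow as
  ``(1 + kappa_C * s)``, and the electrode's offset potentials shrink as
  ``(1 - gamma_pv * s)``;
* measurement noise is uniform within the instrument tolerances observed on
  the physical platform (impedance +-0.14 ohm, phase 1.85 deg, polarization
  voltage +-0.65 mV, pressure +-1.8 cN);
* electrode re-seating between force levels perturbs the skin-side (membrane
  and electrolyte) elements by a small fractional jitter, which is what
  limits pressure-impedance correlation at high frequency where the fabric
  contact is capacitively shorted.

Only the upper (respectively left) electrode is force-swept; the lower
electrode sits at a fixed set point, mirroring the physical geometry in
which the lower membrane-electrode contact never moves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .circuit import (
    ImpedanceSpectrum,
    InterfaceParams,
    PairStack,
    band_grid,
    fitting_grid,
    interface_impedance_complex,
    pair_impedance_complex,
    pair_polarization_voltage,
    transfer_function,
)
from .errors import (
    InvalidParameterError,
    RangeError,
    SamplingRateError,
    SchemaError,
)

__all__ = [
    "NoiseSpec",
    "ElectrodeSample",
    "SignalPair",
    "MotionProfile",
    "Trace",
    "StaticTrace",
    "LevelRecord",
    "MeasurementSession",
    "DEFAULT_WET",
    "SAMPLE_NAMES",
    "default_pressure_levels",
    "pressure_modulate",
    "sample_catalog",
    "wet_ensemble",
    "synth_source_signal",
    "simulate_motion",
    "simulate_peep_session",
    "simulate_aeep_session",
]

#: platform force range (two 0-600 cN sensors), N
FORCE_RANGE_N = (0.0, 6.0)
#: relative-movement ranges of the motion stage
SPEED_RANGE_MM_S = (0.0, 40.0)
PATH_RANGE_MM = (0.0, 100.0)
#: frequency at which the "static" impedance trace is read (grid minimum)
STATIC_FREQ_HZ = 0.1
#: the fixed lower/right electrode set point: 123 cN, the platform default
LOWER_SETPOINT_N = 1.23
#: share of the base offset potentials retained by the fixed lower
#: electrode; the residual mismatch is what the polarization voltage of a
#: nominally identical pair measures (perfectly symmetric electrodes would
#: give exactly zero at every force)
LOWER_POTENTIAL_SHARE = 0.6
#: sine source band accepted by the signal generator (Hz)
SINE_BAND_HZ = (0.1, 200.0)
#: bandwidth attributed to the synthetic ECG template for Nyquist checks (Hz)
ECG_BANDWIDTH_HZ = 40.0


@dataclass(frozen=True)
class NoiseSpec:
    """Half-ranges of the uniform measurement noise (one per channel).

    ``sigma_sig`` is the RMS of the additive Gaussian noise on the measured
    signal channel; ``sigma_skin`` is the fractional half-range of the
    per-level re-seating jitter applied to skin-side circuit elements.
    """

    sigma_z: float = 0.14  # ohm
    sigma_phase: float = 1.85  # deg
    sigma_pv: float = 0.65  # mV
    sigma_f: float = 1.8  # cN
    sigma_sig: float = 0.02  # mV RMS
    sigma_skin: float = 0.01  # fractional

    def __post_init__(self) -> None:
        for name in ("sigma_z", "sigma_phase", "sigma_pv", "sigma_f",
                     "sigma_sig", "sigma_skin"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")

    @classmethod
    def off(cls) -> "NoiseSpec":
        """All noise channels disabled (exact, reproducible sessions)."""
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ElectrodeSample:
    """One electrode sample: base circuit plus its pressure-coupling law.

    ``kappa_R`` / ``kappa_C`` (dimensionless) set how strongly contact
    resistances shrink / contact capacitances grow with the saturating
    force term ``s(F) = F / (F + F_half)``; ``F_half`` (N) is the
    half-saturation force and ``gamma_pv`` the fractional decline of the
    offset potentials at full saturation.
    """

    name: str
    base: InterfaceParams
    kappa_R: float = 2.0
    kappa_C: float = 1.0
    F_half: float = 0.5
    gamma_pv: float = 0.2
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self) -> None:
        if self.kappa_R < 0 or self.kappa_C < 0:
            raise InvalidParameterError("kappa_R and kappa_C must be >= 0")
        if not self.F_half > 0:
            raise InvalidParameterError("F_half must be > 0")
        if not 0.0 <= self.gamma_pv < 1.0:
            raise InvalidParameterError("gamma_pv must be in [0, 1)")


@dataclass
class SignalPair:
    """Source signal (SFSG) and electrode-measured signal (SFME), mV."""

    sampling_rate_hz: float
    sfsg_mv: np.ndarray
    sfme_mv: np.ndarray
    duration_s: float

    def __post_init__(self) -> None:
        self.sfsg_mv = np.asarray(self.sfsg_mv, dtype=float)
        self.sfme_mv = np.asarray(self.sfme_mv, dtype=float)
        if self.sfsg_mv.shape != self.sfme_mv.shape:
            raise InvalidParameterError("SFSG and SFME must have equal length")


@dataclass
class Trace:
    """A sampled time series (seconds, channel units)."""

    time_s: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_s.shape != self.values.shape:
            raise InvalidParameterError("trace time and values must match")


@dataclass
class StaticTrace:
    """Static impedance trace: magnitude (ohm) and phase (deg) vs time."""

    time_s: np.ndarray
    magnitude_ohm: np.ndarray
    phase_deg: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.magnitude_ohm = np.asarray(self.magnitude_ohm, dtype=float)
        self.phase_deg = np.asarray(self.phase_deg, dtype=float)


@dataclass
class MotionProfile:
    """Triangular back-and-forth relative motion and its artifact factors."""

    time_s: np.ndarray
    displacement_mm: np.ndarray
    speed_mm_s: np.ndarray
    z_factor: np.ndarray  # multiplicative impedance fluctuation
    pv_artifact_mv: np.ndarray  # additive polarization-voltage artifact
    set_speed_mm_s: float
    set_path_mm: float

    @property
    def mean_speed_mm_s(self) -> float:
        return float(np.mean(self.speed_mm_s))

    @property
    def total_path_mm(self) -> float:
        if len(self.displacement_mm) < 2:
            return 0.0
        return float(np.sum(np.abs(np.diff(self.displacement_mm))))


@dataclass
class LevelRecord:
    """Everything recorded at one contact-force set point."""

    set_point_n: float
    stack: PairStack
    pressure_upper: Trace  # cN
    pressure_lower: Trace  # cN
    static: StaticTrace
    spectrum: ImpedanceSpectrum  # pair AC spectrum on the band grid
    upper_spectrum: ImpedanceSpectrum  # swept electrode alone, fitting grid
    pv: Trace  # mV


@dataclass
class MeasurementSession:
    """One simulated PEEP or AEEP run over a force sweep."""

    platform: str  # "PEEP" or "AEEP"
    sample: ElectrodeSample
    pressure_levels: list[float]
    records: list[LevelRecord]
    motion: MotionProfile | None
    signals: SignalPair | None
    seed: int

    def __post_init__(self) -> None:
        if self.platform not in ("PEEP", "AEEP"):
            raise SchemaError(f"unknown platform {self.platform!r}")


# --------------------------------------------------------------------------
# defaults and catalogs

#: default wet (gel) electrode interface; the resistances follow the
#: standard textbook magnitudes for a gelled electrode on prepared skin
DEFAULT_WET = InterfaceParams(
    kind="wet",
    E_hc=8.0, C_d=50.0, R_d=100.0,
    E_sc=3.0, C_e=2.0, R_e=1000.0,
    E_p=1.0, C_p=1.0, R_p=500.0,
    R_a=20.0, R_s=50.0,
)

#: the ten textile sample labels used by the platform's sample rack
SAMPLE_NAMES = (
    "HTL-1", "HTL-2", "LMF-2", "ZZB-1+1", "BTL-1+1",
    "KZZB", "LXG-1", "BTL-1", "ZZB-1", "MZG-1",
)

#: log-uniform draw ranges for textile catalog parameters
CATALOG_RANGES = {
    "R_c": (2000.0, 8000.0),   # ohm
    "C_t": (20.0, 60.0),       # uF
    "R_d": (100.0, 300.0),     # ohm
    "C_d": (50.0, 200.0),      # uF
    "R_e": (500.0, 2000.0),    # ohm
    "C_e": (0.01, 0.05),       # uF
    "R_p": (300.0, 1500.0),    # ohm
    "C_p": (0.02, 0.10),       # uF
    "R_a": (20.0, 80.0),       # ohm
    "E_hc": (10.0, 40.0),      # mV
    "E_sc": (3.0, 12.0),       # mV
    "E_p": (1.0, 6.0),         # mV
}


def default_pressure_levels(n: int = 10, f_max: float = 3.0) -> list[float]:
    """Default force sweep: ``n`` levels uniform in (0, f_max] N."""
    return [f_max * (i + 1) / n for i in range(n)]


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(math.exp(rng.uniform(math.log(lo), math.log(hi))))


def sample_catalog(seed: int, n: int = 10) -> list[ElectrodeSample]:
    """Draw a catalog of ``n`` textile electrode samples (default 10).

    Circuit values are drawn log-uniformly from :data:`CATALOG_RANGES`;
    coupling coefficients are drawn around their documented defaults with
    the constraint ``kappa_R <= 2 * kappa_C``, which guarantees that the
    interface impedance magnitude decreases with force at every frequency.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    samples: list[ElectrodeSample] = []
    for i in range(n):
        name = SAMPLE_NAMES[i] if i < len(SAMPLE_NAMES) else f"SAMPLE-{i + 1}"
        draw = {k: _log_uniform(rng, lo, hi) for k, (lo, hi) in CATALOG_RANGES.items()}
        base = InterfaceParams(kind="textile", moisture=1.0, **draw)
        kappa_C = float(rng.uniform(0.8, 1.3))
        kappa_R = float(rng.uniform(1.2, min(2.5, 2.0 * kappa_C)))
        f_half = _log_uniform(rng, 0.35, 0.7)
        gamma_pv = float(rng.uniform(0.12, 0.28))
        sigma_f = float(rng.uniform(1.1, 5.3))
        samples.append(
            ElectrodeSample(
                name=name,
                base=base,
                kappa_R=kappa_R,
                kappa_C=kappa_C,
                F_half=f_half,
                gamma_pv=gamma_pv,
                noise=NoiseSpec(sigma_f=sigma_f),
            )
        )
    return samples


def wet_ensemble(seed: int, n: int = 12, spread: float = 0.03) -> list[PairStack]:
    """Build ``n`` wet-electrode pair stacks around the default parameters.

    Each resistance/capacitance is jittered log-normally (sigma ``spread``
    in log space) to emulate manufacturing variation between nominally
    identical gel electrodes; potentials are jittered by the same factor
    law.  Used by the disposable-ECG compliance workflow.
    """
    rng = np.random.default_rng(seed)

    def _jitter(p: InterfaceParams) -> InterfaceParams:
        changes = {}
        for name in ("C_d", "R_d", "C_e", "R_e", "C_p", "R_p", "R_a", "R_s",
                     "E_hc", "E_sc", "E_p"):
            changes[name] = getattr(p, name) * float(rng.lognormal(0.0, spread))
        return p.replace(**changes)

    return [
        PairStack(_jitter(DEFAULT_WET), _jitter(DEFAULT_WET), R_tissue=150.0)
        for _ in range(n)
    ]


# --------------------------------------------------------------------------
# pressure coupling

def pressure_modulate(
    base: InterfaceParams, F: float, sample: ElectrodeSample
) -> InterfaceParams:
    """Apply the contact-force law to the contact-dependent elements.

    With ``s = F / (F + F_half)``: contact resistances (``R_d`` plus
    ``R_c`` for textile or ``R_s`` for wet) scale by ``1/(1 + kappa_R*s)``,
    contact capacitances (``C_d``, ``C_t``) by ``(1 + kappa_C*s)``, and the
    offset potentials by ``(1 - gamma_pv*s)``.  Skin-side elements are
    untouched: force changes the electrode-membrane contact, not the
    membrane or electrolyte.  Deterministic; noise enters only at trace
    level.
    """
    if F < 0:
        raise InvalidParameterError("contact force must be >= 0")
    s = F / (F + sample.F_half)
    r_scale = 1.0 / (1.0 + sample.kappa_R * s)
    c_scale = 1.0 + sample.kappa_C * s
    pv_scale = 1.0 - sample.gamma_pv * s
    changes = {
        "R_d": base.R_d * r_scale,
        "C_d": base.C_d * c_scale,
        "E_hc": base.E_hc * pv_scale,
        "E_sc": base.E_sc * pv_scale,
        "E_p": base.E_p * pv_scale,
    }
    if base.kind == "wet":
        changes["R_s"] = base.R_s * r_scale
    else:
        changes["R_c"] = base.R_c * r_scale
        changes["C_t"] = base.C_t * c_scale
    return base.replace(**changes)


# --------------------------------------------------------------------------
# source signals

#: Gaussian-lobe ECG template: (offset s, width s, relative amplitude)
_ECG_LOBES = (
    (-0.22, 0.030, 0.18),   # P
    (-0.045, 0.012, -0.12),  # Q
    (0.0, 0.018, 1.0),       # R
    (0.045, 0.014, -0.22),   # S
    (0.30, 0.060, 0.32),     # T
)


def synth_source_signal(
    kind: str,
    f_or_hr: float,
    amplitude: float,
    duration: float,
    rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize a deterministic source signal for the active platform.

    ``kind="sine"``: a pure sinusoid; ``f_or_hr`` is the frequency in Hz and
    must lie in the generator band 0.1-200 Hz.  ``kind="ecg"``: a periodic
    sum-of-Gaussians P-QRS-T template; ``f_or_hr`` is the heart rate in
    beats per minute and the R peak is scaled to exactly ``amplitude`` mV.

    Returns ``(time_s, signal_mv)`` with ``round(duration * rate)`` samples.
    """
    if duration <= 0 or rate <= 0:
        raise InvalidParameterError("duration and rate must be > 0")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    if kind == "sine":
        f = float(f_or_hr)
        if not SINE_BAND_HZ[0] <= f <= SINE_BAND_HZ[1]:
            raise RangeError(
                f"sine frequency {f:g} Hz outside generator band "
                f"{SINE_BAND_HZ[0]:g}-{SINE_BAND_HZ[1]:g} Hz"
            )
        if rate < 2.0 * f:
            raise SamplingRateError(
                f"rate {rate:g} Hz undersamples a {f:g} Hz sine"
            )
        return t, amplitude * np.sin(2.0 * math.pi * f * t)
    if kind == "ecg":
        hr = float(f_or_hr)
        if hr <= 0:
            raise InvalidParameterError("heart rate must be > 0")
        if rate < 2.0 * ECG_BANDWIDTH_HZ:
            raise SamplingRateError(
                f"rate {rate:g} Hz undersamples the ECG template "
                f"(bandwidth {ECG_BANDWIDTH_HZ:g} Hz)"
            )
        rr = 60.0 / hr
        x = np.zeros(n)
        n_beats = int(math.floor(duration / rr))
        # single-beat template maximum, used to pin the R amplitude exactly
        peak = sum(a * math.exp(-(d ** 2) / (2 * w ** 2)) for d, w, a in _ECG_LOBES)
        for k in range(n_beats + 1):
            t_r = (k + 0.35) * rr
            if t_r >= duration:
                continue
            for d, w, a in _ECG_LOBES:
                x += a * np.exp(-((t - t_r - d) ** 2) / (2.0 * w ** 2))
        return t, amplitude * x / peak
    raise InvalidParameterError(f"unknown source kind {kind!r}")


# --------------------------------------------------------------------------
# relative movement

def simulate_motion(
    speed: float,
    path: float,
    duration: float,
    rate: float = 50.0,
    modulation_depth: float = 0.01,
) -> MotionProfile:
    """Triangular back-and-forth motion of the electrode over the membrane.

    The stage moves at constant ``speed`` (mm/s) over ``path`` mm and back,
    one full cycle every ``2 * path / speed`` seconds.  Motion perturbs the
    contact: the impedance is scaled by ``1 + modulation_depth * |v(t)|``
    and the polarization voltage gains an additive artifact
    ``modulation_depth * |v(t)|`` mV, both proportional to the
    instantaneous speed.
    """
    if not SPEED_RANGE_MM_S[0] <= speed <= SPEED_RANGE_MM_S[1]:
        raise RangeError(
            f"speed {speed:g} mm/s outside range {SPEED_RANGE_MM_S} mm/s"
        )
    if not PATH_RANGE_MM[0] <= path <= PATH_RANGE_MM[1]:
        raise RangeError(f"path {path:g} mm outside range {PATH_RANGE_MM} mm")
    n = max(2, int(round(duration * rate)))
    t = np.arange(n) / rate
    if speed == 0.0 or path == 0.0:
        zero = np.zeros(n)
        return MotionProfile(t, zero, zero, np.ones(n), zero.copy(), speed, path)
    phase = np.mod(speed * t / path, 2.0)
    displacement = path * (1.0 - np.abs(phase - 1.0))
    v = np.full(n, speed)
    z_factor = 1.0 + modulation_depth * v
    pv_artifact = modulation_depth * v
    return MotionProfile(t, displacement, v, z_factor, pv_artifact, speed, path)


# --------------------------------------------------------------------------
# sessions

def _uniform(rng: np.random.Generator, half: float, size: int) -> np.ndarray:
    if half == 0.0:
        return np.zeros(size)
    return rng.uniform(-half, half, size)


_SKIN_FIELDS = ("R_e", "C_e", "R_p", "C_p", "R_a")


def _jitter_skin(
    p: InterfaceParams, rng: np.random.Generator, sigma: float
) -> InterfaceParams:
    """Per-level re-seating jitter on membrane/electrolyte-side elements."""
    if sigma == 0.0:
        rng.uniform(-0.0, 0.0, len(_SKIN_FIELDS))  # keep the draw sequence fixed
        return p
    factors = 1.0 + rng.uniform(-sigma, sigma, len(_SKIN_FIELDS))
    return p.replace(
        **{name: getattr(p, name) * f for name, f in zip(_SKIN_FIELDS, factors)}
    )


def _lower_reference(base: InterfaceParams) -> InterfaceParams:
    """The fixed lower/right electrode: same circuit, offset potentials
    reduced to LOWER_POTENTIAL_SHARE of the base values."""
    return base.replace(
        E_hc=base.E_hc * LOWER_POTENTIAL_SHARE,
        E_sc=base.E_sc * LOWER_POTENTIAL_SHARE,
        E_p=base.E_p * LOWER_POTENTIAL_SHARE,
    )


def _noisy_spectrum(
    z: np.ndarray,
    grid: np.ndarray,
    rng: np.random.Generator,
    noise: NoiseSpec,
    z_factor: float,
) -> ImpedanceSpectrum:
    mag = np.abs(z) * z_factor + _uniform(rng, noise.sigma_z, grid.size)
    phase = np.degrees(np.angle(z)) + _uniform(rng, noise.sigma_phase, grid.size)
    # instrument-style saturation at the physical bounds of an RC network
    return ImpedanceSpectrum(grid, np.maximum(mag, 0.0), np.clip(phase, -90.0, 0.0))


def _simulate_records(
    sample: ElectrodeSample,
    pressure_levels: list[float],
    freq_grid: np.ndarray,
    fit_grid: np.ndarray,
    rng: np.random.Generator,
    r_tissue: float,
    z_in: float | None,
    z_motion: float,
    pv_motion: float,
    trace_points: int,
    trace_duration_s: float,
) -> list[LevelRecord]:
    noise = sample.noise
    lower_base = _lower_reference(sample.base)
    t_trace = np.linspace(0.0, trace_duration_s, trace_points)
    records: list[LevelRecord] = []
    for f_n in pressure_levels:
        if not FORCE_RANGE_N[0] <= f_n <= FORCE_RANGE_N[1]:
            raise RangeError(
                f"force {f_n:g} N outside sensor range {FORCE_RANGE_N} N"
            )
        upper = pressure_modulate(
            _jitter_skin(sample.base, rng, noise.sigma_skin), f_n, sample
        )
        lower = _jitter_skin(lower_base, rng, noise.sigma_skin)
        stack = PairStack(upper, lower, R_tissue=r_tissue, Z_in=z_in)

        z_pair = pair_impedance_complex(stack, freq_grid)
        spectrum = _noisy_spectrum(z_pair, freq_grid, rng, noise, z_motion)
        z_up = interface_impedance_complex(upper, fit_grid)
        upper_spectrum = _noisy_spectrum(z_up, fit_grid, rng, noise, z_motion)

        z_static = pair_impedance_complex(stack, STATIC_FREQ_HZ)
        static_mag = (
            abs(z_static) * z_motion + _uniform(rng, noise.sigma_z, trace_points)
        )
        static_phase = np.clip(
            math.degrees(np.angle(z_static))
            + _uniform(rng, noise.sigma_phase, trace_points),
            -90.0,
            0.0,
        )
        static = StaticTrace(t_trace, np.maximum(static_mag, 0.0), static_phase)

        pv0 = pair_polarization_voltage(stack) + pv_motion
        pv = Trace(t_trace, pv0 + _uniform(rng, noise.sigma_pv, trace_points))

        p_upper = Trace(
            t_trace, f_n * 100.0 + _uniform(rng, noise.sigma_f, trace_points)
        )
        p_lower = Trace(
            t_trace,
            LOWER_SETPOINT_N * 100.0 + _uniform(rng, noise.sigma_f, trace_points),
        )
        records.append(
            LevelRecord(
                set_point_n=f_n,
                stack=stack,
                pressure_upper=p_upper,
                pressure_lower=p_lower,
                static=static,
                spectrum=spectrum,
                upper_spectrum=upper_spectrum,
                pv=pv,
            )
        )
    return records


def _motion_profile(
    motion: tuple[float, float] | None,
    trace_duration_s: float,
    modulation_depth: float,
) -> tuple[MotionProfile | None, float, float]:
    if motion is None:
        return None, 1.0, 0.0
    speed, path = motion
    profile = simulate_motion(
        speed, path, trace_duration_s, modulation_depth=modulation_depth
    )
    return profile, float(np.mean(profile.z_factor)), float(
        np.mean(profile.pv_artifact_mv)
    )


def simulate_peep_session(
    sample: ElectrodeSample,
    pressure_levels: list[float] | None = None,
    freq_grid: np.ndarray | None = None,
    seed: int = 0,
    *,
    fit_grid: np.ndarray | None = None,
    r_tissue: float = 150.0,
    motion: tuple[float, float] | None = None,
    modulation_depth: float = 0.01,
    trace_points: int = 50,
    trace_duration_s: float = 10.0,
) -> MeasurementSession:
    """Simulate a passive-platform session over a contact-force sweep.

    For each force level the upper electrode is force-modulated while the
    lower electrode stays at its fixed seat; the pair spectrum, static
    impedance trace, polarization-voltage trace and both pressure traces
    are recorded with instrument noise per ``sample.noise``.  ``motion``,
    if given as ``(speed mm/s, path mm)``, superimposes a relative-movement
    artifact on impedance and polarization voltage.  Fully deterministic
    for a fixed seed.
    """
    levels = list(default_pressure_levels() if pressure_levels is None else pressure_levels)
    grid = band_grid() if freq_grid is None else np.asarray(freq_grid, float)
    fgrid = fitting_grid() if fit_grid is None else np.asarray(fit_grid, float)
    rng = np.random.default_rng(seed)
    profile, z_motion, pv_motion = _motion_profile(
        motion, trace_duration_s, modulation_depth
    )
    records = _simulate_records(
        sample, levels, grid, fgrid, rng, r_tissue, None,
        z_motion, pv_motion, trace_points, trace_duration_s,
    )
    return MeasurementSession(
        platform="PEEP",
        sample=sample,
        pressure_levels=levels,
        records=records,
        motion=profile,
        signals=None,
        seed=seed,
    )


def simulate_aeep_session(
    sample: ElectrodeSample,
    pressure_levels: list[float] | None = None,
    source: tuple[np.ndarray, np.ndarray, float] | dict | None = None,
    z_in: float | None = 1e6,
    seed: int = 0,
    *,
    freq_grid: np.ndarray | None = None,
    fit_grid: np.ndarray | None = None,
    r_tissue: float = 150.0,
    motion: tuple[float, float] | None = None,
    modulation_depth: float = 0.01,
    trace_points: int = 50,
    trace_duration_s: float = 10.0,
) -> MeasurementSession:
    """Simulate an active-platform session: PEEP records plus signal pair.

    ``source`` is either ``(time_s, signal_mv, rate_hz)`` or a dict of
    :func:`synth_source_signal` arguments (default: a 1 mV, 60 bpm ECG
    template, 10 s at 500 Hz).  The measured signal SFME is the source
    filtered through the amplifier divider ``H(f) = Z_in/(Z_in + Z_pair)``
    of the stack at the first force level, plus Gaussian noise of RMS
    ``sample.noise.sigma_sig``.
    """
    levels = list(default_pressure_levels() if pressure_levels is None else pressure_levels)
    grid = band_grid() if freq_grid is None else np.asarray(freq_grid, float)
    fgrid = fitting_grid() if fit_grid is None else np.asarray(fit_grid, float)
    rng = np.random.default_rng(seed)
    profile, z_motion, pv_motion = _motion_profile(
        motion, trace_duration_s, modulation_depth
    )
    records = _simulate_records(
        sample, levels, grid, fgrid, rng, r_tissue, z_in,
        z_motion, pv_motion, trace_points, trace_duration_s,
    )

    if source is None:
        source = {"kind": "ecg", "f_or_hr": 60.0, "amplitude": 1.0,
                  "duration": 10.0, "rate": 500.0}
    if isinstance(source, dict):
        t_sig, sfsg = synth_source_signal(**source)
        rate = float(source["rate"])
    else:
        t_sig, sfsg, rate = source
        sfsg = np.asarray(sfsg, dtype=float)
    n = sfsg.size
    stack = records[0].stack
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    h = transfer_function(stack, freqs)
    sfme = np.fft.irfft(np.fft.rfft(sfsg) * h, n=n)
    if sample.noise.sigma_sig > 0:
        sfme = sfme + rng.normal(0.0, sample.noise.sigma_sig, n)
    signals = SignalPair(
        sampling_rate_hz=rate, sfsg_mv=sfsg, sfme_mv=sfme, duration_s=n / rate
    )
    return MeasurementSession(
        platform="AEEP",
        sample=sample,
        pressure_levels=levels,
        records=records,
        motion=profile,
        signals=signals,
        seed=seed,
    )
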