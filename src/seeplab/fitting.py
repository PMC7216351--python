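"""Inverse problems: circuit parameters from spectra, coupling laws from sweeps.

The AC spectrum of either interface kind reduces, over the measurement
band, to a series resistance plus parallel-RC blocks:

* wet:      Z = R_series + RC(R_d, C_d) + RC(R_skin, C_skin)
  where R_series = R_s + R_a, R_skin = R_e || R_p and C_skin = C_e + C_p
  (two parallel RC branches in parallel are exactly one RC block);
* textile:  Z = R_series + RC(R_c, C_t_eff) + RC(R_d, C_d)
            + RC(R_skin, C_skin)
  with R_series = R_a.  The skin block's corner usually lies far above
  the band, in which case its capacitance is weakly determined — but
  keeping the block keeps the model exact for synthetic data.

Only these combinations are identifiable from AC data; series resistances
that enter as a sum are reported as the lumped sum and never split, and
the DC offset potentials do not enter the spectrum at all.  Fitted blocks
are labelled by descending time constant, which maps them onto the named
elements for default-scale parameters.

Fits minimize the modulus of the complex residual weighted by 1/|Z|
(proportional weighting) so low- and high-frequency regions contribute
comparably; parameters are optimized in log10 space to enforce positivity,
with a seeded multi-start to escape local minima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.optimize import least_squares

from .circuit import ImpedanceSpectrum, InterfaceParams
from .errors import InputError
from .features import sepv_feature
from .platforms import LOWER_POTENTIAL_SHARE, ElectrodeSample, MeasurementSession

__all__ = [
    "FitResult",
    "PressureCouplingFit",
    "identifiable_params",
    "fit_interface_params",
    "fit_pressure_coupling",
]

#: names of the identifiable parameters per interface kind, in block order
#: (pairs of R, C per block, then the series resistance)
_PARAM_NAMES = {
    "wet": ("R_d", "C_d", "R_skin", "C_skin", "R_series"),
    "textile": ("R_c", "C_t_eff", "R_d", "C_d", "R_skin", "C_skin", "R_series"),
}
_N_BLOCKS = {"wet": 2, "textile": 3}


def identifiable_params(p: InterfaceParams) -> dict[str, float]:
    """Map full circuit parameters onto the AC-identifiable set."""
    r_skin = p.R_e * p.R_p / (p.R_e + p.R_p)
    c_skin = p.C_e + p.C_p
    if p.kind == "wet":
        return {
            "R_d": p.R_d,
            "C_d": p.C_d,
            "R_skin": r_skin,
            "C_skin": c_skin,
            "R_series": p.R_s + p.R_a,
        }
    return {
        "R_c": p.R_c,
        "C_t_eff": p.C_t_eff,
        "R_d": p.R_d,
        "C_d": p.C_d,
        "R_skin": r_skin,
        "C_skin": c_skin,
        "R_series": p.R_a,
    }


@dataclass
class FitResult:
    """Outcome of a spectrum fit.

    ``params`` holds the identifiable parameters keyed by the names in
    :func:`identifiable_params` for the requested kind; ``blocks`` the raw
    (R ohm, C uF) pairs sorted by descending time constant; ``rel_errors``
    the per-parameter relative errors when the true parameters were given.
    """

    kind: str
    params: dict[str, float]
    blocks: list[tuple[float, float]]
    residual: float
    success: bool
    message: str
    nfev: int
    rel_errors: dict[str, float] | None = None


def _model(f: np.ndarray, r_series: float, blocks) -> np.ndarray:
    w = 2.0 * math.pi * f
    z = np.full(f.shape, r_series, dtype=complex)
    for r, c_uf in blocks:
        z = z + r / (1.0 + 1j * w * r * (c_uf * 1e-6))
    return z


def _unpack(values: lmfit.Parameters, n_blocks: int):
    r_series = 10.0 ** values["log_r_series"].value
    blocks = [
        (10.0 ** values[f"log_r{k}"].value, 10.0 ** values[f"log_c{k}"].value)
        for k in range(n_blocks)
    ]
    return r_series, blocks


def _heuristic_start(spectrum: ImpedanceSpectrum, n_blocks: int) -> tuple[float, list]:
    """Data-driven starting point: split the resistive drop across blocks
    whose corners are spread across the measurement band."""
    mag = spectrum.magnitude_ohm
    f = spectrum.frequency_hz
    r_series = max(float(mag[-1]) * 0.8, 1e-3)
    drop = max(float(mag[0]) - r_series, 1e-2)
    shares = {2: (0.7, 0.3), 3: (0.6, 0.3, 0.1)}[n_blocks]
    positions = {2: (0.3, 0.7), 3: (0.2, 0.5, 0.8)}[n_blocks]
    blocks = []
    for share, pos in zip(shares, positions):
        r = share * drop
        fc = f[0] * (f[-1] / f[0]) ** pos
        c_uf = 1e6 / (2.0 * math.pi * fc * r)
        blocks.append((r, c_uf))
    return r_series, blocks


def fit_interface_params(
    spectrum: ImpedanceSpectrum,
    kind: str,
    init: InterfaceParams | dict | None = None,
    truth: InterfaceParams | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Estimate the identifiable circuit parameters from one spectrum.

    The spectrum must span at least two decades of frequency with at least
    20 points.  ``init`` may be full circuit parameters, a dict of
    identifiable parameters, or ``None`` for a data-driven start.  The fit
    never raises on non-convergence; ``success`` reports the optimizer
    status.  If ``truth`` is given, per-parameter relative errors against
    its identifiable set are attached.
    """
    if kind not in _PARAM_NAMES:
        raise InputError(f"unknown interface kind {kind!r}")
    if len(spectrum) < 20:
        raise InputError("need at least 20 spectrum points")
    span = spectrum.frequency_hz[-1] / max(spectrum.frequency_hz[0], 1e-12)
    if span < 100.0:
        raise InputError("spectrum must span at least two decades")

    names = _PARAM_NAMES[kind]
    n_blocks = _N_BLOCKS[kind]
    if isinstance(init, InterfaceParams):
        init = identifiable_params(init)
    if init is not None:
        r_series0 = float(init["R_series"])
        blocks0 = [
            (float(init[names[2 * k]]), float(init[names[2 * k + 1]]))
            for k in range(n_blocks)
        ]
    else:
        r_series0, blocks0 = _heuristic_start(spectrum, n_blocks)

    f = spectrum.frequency_hz
    z = spectrum.to_complex()
    weight = 1.0 / np.abs(z)

    def residual(params: lmfit.Parameters) -> np.ndarray:
        r_series, blocks = _unpack(params, n_blocks)
        d = (_model(f, r_series, blocks) - z) * weight
        return np.concatenate([d.real, d.imag])

    base_logs = [math.log10(r_series0)]
    for r, c in blocks0:
        base_logs.extend([math.log10(r), math.log10(c)])

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        logs = list(base_logs)
        if start > 0:
            logs = [v + rng.normal(0.0, 0.3) for v in logs]
        params = lmfit.Parameters()
        params.add("log_r_series", value=logs[0], min=-4, max=8)
        for k in range(n_blocks):
            params.add(f"log_r{k}", value=logs[1 + 2 * k], min=-4, max=8)
            params.add(f"log_c{k}", value=logs[2 + 2 * k], min=-7, max=7)
        out = lmfit.minimize(residual, params, method="leastsq")
        cost = float(np.sum(out.residual ** 2))
        norm = float(np.sum([v.value ** 2 for v in out.params.values()]))
        key = (cost, norm)
        if best is None or key < best[0]:
            best = (key, out)
    out = best[1]

    r_series, blocks = _unpack(out.params, n_blocks)
    blocks = sorted(blocks, key=lambda rc: rc[0] * rc[1], reverse=True)
    fitted = {"R_series": r_series}
    for k, (r, c) in enumerate(blocks):
        fitted[names[2 * k]] = r
        fitted[names[2 * k + 1]] = c
    rel_errors = None
    if truth is not None:
        true_vals = identifiable_params(truth)
        rel_errors = {
            k: abs(fitted[k] - true_vals[k]) / abs(true_vals[k]) for k in fitted
        }
    return FitResult(
        kind=kind,
        params=fitted,
        blocks=blocks,
        residual=float(np.sqrt(np.mean(out.residual ** 2))),
        success=bool(out.success),
        message=str(out.message),
        nfev=int(out.nfev),
        rel_errors=rel_errors,
    )


@dataclass
class PressureCouplingFit:
    """Estimated pressure-coupling coefficients from a force sweep."""

    kappa_R: float
    kappa_C: float
    F_half: float
    gamma_pv: float
    per_level: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    success: bool = True


def fit_pressure_coupling(
    session: MeasurementSession, seed: int = 0
) -> PressureCouplingFit:
    """Recover the pressure-coupling law from a simulated force sweep.

    Per force level, the swept electrode's spectrum is fitted for the
    contact elements (warm-starting each level from the previous fit);
    the saturating law ``R(F) = R0 / (1 + kappa_R * s)``,
    ``C(F) = C0 * (1 + kappa_C * s)`` with ``s = F/(F + F_half)`` is then
    fitted jointly to the per-level contact estimates in log space.
    ``gamma_pv`` comes from a linear fit of the polarization voltage
    against ``s``, using the session's fixed lower-electrode potential
    share.  Needs at least 5 force levels.
    """
    if len(session.records) < 5:
        raise InputError("need at least 5 force levels to fit the coupling law")
    kind = session.sample.base.kind
    contact_r_name, contact_c_name = _PARAM_NAMES[kind][0], _PARAM_NAMES[kind][1]

    forces = np.array([rec.set_point_n for rec in session.records])
    r_contact = []
    c_contact = []
    pvep = []
    init: dict | None = None
    for rec in session.records:
        fr = fit_interface_params(
            rec.upper_spectrum, kind, init=init, n_starts=3, seed=seed
        )
        init = fr.params
        r_contact.append(fr.params[contact_r_name])
        c_contact.append(fr.params[contact_c_name])
        pvep.append(sepv_feature(rec.pv))
    r_contact = np.array(r_contact)
    c_contact = np.array(c_contact)
    pvep = np.array(pvep)

    def law_residual(theta: np.ndarray) -> np.ndarray:
        log_r0, log_c0, kappa_r, kappa_c, log_fh = theta
        s = forces / (forces + 10.0 ** log_fh)
        r_model = 10.0 ** log_r0 / (1.0 + kappa_r * s)
        c_model = 10.0 ** log_c0 * (1.0 + kappa_c * s)
        return np.concatenate(
            [np.log(r_model / r_contact), np.log(c_model / c_contact)]
        )

    theta0 = np.array(
        [math.log10(r_contact.max()), math.log10(c_contact.min()), 1.0, 1.0,
         math.log10(0.5)]
    )
    sol = least_squares(
        law_residual,
        theta0,
        bounds=([-4, -7, 0.0, 0.0, math.log10(0.02)], [8, 7, 50.0, 50.0, math.log10(20.0)]),
    )
    log_r0, log_c0, kappa_r, kappa_c, log_fh = sol.x
    f_half = 10.0 ** log_fh

    s = forces / (forces + f_half)
    slope, intercept = np.polyfit(s, pvep, 1)
    gap = 1.0 - LOWER_POTENTIAL_SHARE
    gamma = 0.0 if intercept <= 0 else max(0.0, -slope * gap / intercept)

    return PressureCouplingFit(
        kappa_R=float(kappa_r),
        kappa_C=float(kappa_c),
        F_half=float(f_half),
        gamma_pv=float(gamma),
        per_level={
            "force_n": forces,
            "r_contact": r_contact,
            "c_contact": c_contact,
            "pvep_mv": pvep,
        },
        success=bool(sol.success),
    )
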