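"""Feature-parameter schema of the evaluation platforms.

The platform summarizes each measurement session into a fixed schema:

* 11 AC-impedance band features ACI_1..ACI_11 — sums of the absolute
  impedance readings over the frequency bands 0-1, 1-2, 2-3, 3-4, 4-5,
  5-10, 10-20, 20-30, 30-40, 40-50 and 50-100 Hz (and the analogous sums
  of absolute phase readings, ACIphase_1..ACIphase_11);
* static impedance and phase (trace means) Z_se_static / Phi_se_static;
* the pair polarization voltage PVEP (mean absolute trace value);
* contact-pressure features USECP / LSECP (trace means, cN) with their
  difference SECP_D and sum SECP_S;
* relative-movement features (mean speed, total path).

The 14 "electrochemical" characteristics used by the correlation analysis
are Z_se_static, Phi_se_static, ACI_1..ACI_11 and PVEP.  Band sums are over
discrete grid points of the fixed default grid (0.1 Hz linear spacing), so
features are comparable across sessions; band edges are half-open
``[lo, hi)`` with the final band closed at 100 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circuit import ImpedanceSpectrum
from .errors import CoverageError, EmptyInputError, InputError, SchemaError
from .platforms import MeasurementSession

__all__ = [
    "BandScheme",
    "DEFAULT_BANDS",
    "ELECTROCHEMICAL_COLUMNS",
    "PHASE_BAND_COLUMNS",
    "SECP_COLUMNS",
    "MOVEMENT_COLUMNS",
    "aci_band_features",
    "static_features",
    "sepv_feature",
    "secp_features",
    "parameter_report",
    "feature_table",
    "PEEP_PARAMETER_CODES",
    "AEEP_PARAMETER_CODES",
]


@dataclass(frozen=True)
class BandScheme:
    """Frequency bands for the AC-impedance features.

    ``edges`` is a tuple of (low, high) pairs in Hz.  Bands are half-open
    low-inclusive; the last band includes its upper edge so the union
    covers [0, 100] exactly.
    """

    edges: tuple[tuple[float, float], ...] = (
        (0.0, 1.0), (1.0, 2.0), (2.0, 3.0), (3.0, 4.0), (4.0, 5.0),
        (5.0, 10.0), (10.0, 20.0), (20.0, 30.0), (30.0, 40.0),
        (40.0, 50.0), (50.0, 100.0),
    )

    def __post_init__(self) -> None:
        for (lo, hi), (lo2, _) in zip(self.edges, self.edges[1:]):
            if hi != lo2 or lo >= hi:
                raise InputError("bands must be contiguous and increasing")

    def __len__(self) -> int:
        return len(self.edges)

    def masks(self, frequency_hz: np.ndarray) -> list[np.ndarray]:
        f = np.asarray(frequency_hz, dtype=float)
        out = []
        last = len(self.edges) - 1
        for k, (lo, hi) in enumerate(self.edges):
            if k == last:
                out.append((f >= lo) & (f <= hi))
            else:
                out.append((f >= lo) & (f < hi))
        return out


DEFAULT_BANDS = BandScheme()

ELECTROCHEMICAL_COLUMNS = (
    ["Z_se_static", "Phi_se_static"]
    + [f"ACI_{k}" for k in range(1, 12)]
    + ["PVEP"]
)
PHASE_BAND_COLUMNS = [f"ACIphase_{k}" for k in range(1, 12)]
SECP_COLUMNS = ["USECP", "LSECP", "SECP_D", "SECP_S"]
MOVEMENT_COLUMNS = ["speed_mm_s", "path_mm"]

PEEP_PARAMETER_CODES = (
    "USECP", "LSECP", "USERS", "LSERS", "USERPM", "LSERPM",
    "SIEP", "ACIEP", "PVEP",
)
AEEP_PARAMETER_CODES = (
    "LSECP", "RSECP", "LSERS", "RSERS", "USERPM", "LSERPM",
    "SIEP", "ACIEP", "PVEP", "SFSG", "SFME",
)


def aci_band_features(
    spectrum: ImpedanceSpectrum,
    scheme: BandScheme = DEFAULT_BANDS,
    channel: str = "magnitude",
) -> np.ndarray:
    """Band features: per band, the sum of absolute readings (ohm or deg).

    ``channel`` selects impedance magnitude or phase.  The spectrum grid
    must reach the top edge of the last band (100 Hz); grid points above
    it are ignored.
    """
    top = scheme.edges[-1][1]
    if spectrum.frequency_hz[-1] < top:
        raise CoverageError(
            f"spectrum grid ends at {spectrum.frequency_hz[-1]:g} Hz, "
            f"below the top band edge {top:g} Hz"
        )
    if channel == "magnitude":
        values = spectrum.magnitude_ohm
    elif channel == "phase":
        values = spectrum.phase_deg
    else:
        raise InputError(f"unknown channel {channel!r}")
    absval = np.abs(values)
    return np.array(
        [float(absval[m].sum()) for m in scheme.masks(spectrum.frequency_hz)]
    )


def static_features(static) -> tuple[float, float]:
    """Mean magnitude (ohm) and mean phase (deg) of the static trace."""
    mag = np.asarray(static.magnitude_ohm, dtype=float)
    phase = np.asarray(static.phase_deg, dtype=float)
    if mag.size == 0 or phase.size == 0:
        raise EmptyInputError("static trace is empty")
    return float(mag.mean()), float(phase.mean())


def sepv_feature(pv_values) -> float:
    """Polarization-voltage feature: mean absolute trace value (mV)."""
    v = np.asarray(
        pv_values.values if hasattr(pv_values, "values") else pv_values,
        dtype=float,
    )
    if v.size == 0:
        raise EmptyInputError("polarization-voltage trace is empty")
    return float(np.abs(v).mean())


def secp_features(upper, lower) -> tuple[float, float, float, float]:
    """(USECP, LSECP, SECP_D, SECP_S) from the two pressure traces (cN)."""
    u = np.asarray(upper.values if hasattr(upper, "values") else upper, float)
    low = np.asarray(lower.values if hasattr(lower, "values") else lower, float)
    if u.size == 0 or low.size == 0:
        raise EmptyInputError("pressure trace is empty")
    usecp = float(u.mean())
    lsecp = float(low.mean())
    return usecp, lsecp, usecp - lsecp, usecp + lsecp


def _movement(session: MeasurementSession) -> tuple[float, float]:
    if session.motion is None:
        return 0.0, 0.0
    return session.motion.mean_speed_mm_s, session.motion.total_path_mm


def parameter_report(
    session: MeasurementSession, platform: str | None = None
) -> dict[str, float]:
    """Session-level parameter record keyed by the platform's codes.

    A passive (PEEP) session yields the 9-parameter record (USECP, LSECP,
    USERS, LSERS, USERPM, LSERPM, SIEP, ACIEP, PVEP); an active (AEEP)
    session yields 11 parameters with left/right pressure naming plus the
    SFSG/SFME signal amplitudes (RMS, mV).  Impedance summaries are
    averaged over the force sweep.
    """
    if platform is not None and platform != session.platform:
        raise SchemaError(
            f"session is {session.platform}, report requested for {platform}"
        )
    if not session.records:
        raise EmptyInputError("session has no records")
    upper_p = float(
        np.mean([r.pressure_upper.values.mean() for r in session.records])
    )
    lower_p = float(
        np.mean([r.pressure_lower.values.mean() for r in session.records])
    )
    siep = float(np.mean([r.static.magnitude_ohm.mean() for r in session.records]))
    aciep = float(np.mean([r.spectrum.magnitude_ohm.mean() for r in session.records]))
    pvep = float(np.mean([sepv_feature(r.pv) for r in session.records]))
    speed, path = _movement(session)
    if session.platform == "PEEP":
        return {
            "USECP": upper_p, "LSECP": lower_p,
            "USERS": speed, "LSERS": 0.0,
            "USERPM": path, "LSERPM": 0.0,
            "SIEP": siep, "ACIEP": aciep, "PVEP": pvep,
        }
    if session.signals is None:
        raise SchemaError("AEEP session lacks a signal pair")
    sfsg = float(np.sqrt(np.mean(session.signals.sfsg_mv ** 2)))
    sfme = float(np.sqrt(np.mean(session.signals.sfme_mv ** 2)))
    return {
        "LSECP": upper_p, "RSECP": lower_p,
        "LSERS": speed, "RSERS": 0.0,
        "USERPM": path, "LSERPM": 0.0,
        "SIEP": siep, "ACIEP": aciep, "PVEP": pvep,
        "SFSG": sfsg, "SFME": sfme,
    }


def feature_table(
    sessions: MeasurementSession | list[MeasurementSession],
    scheme: BandScheme = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Per-(sample, force-level) feature rows for the correlation methods.

    Columns: ``sample``, ``pressure_n``, the 14 electrochemical
    characteristics (Z_se_static, Phi_se_static, ACI_1..11, PVEP), the 11
    phase-band features, the 4 contact-pressure characteristics and the 2
    movement features.
    """
    if isinstance(sessions, MeasurementSession):
        sessions = [sessions]
    if not sessions:
        raise EmptyInputError("no sessions given")
    rows = []
    for session in sessions:
        speed, path = _movement(session)
        for rec in session.records:
            z_static, phi_static = static_features(rec.static)
            aci = aci_band_features(rec.spectrum, scheme, "magnitude")
            aci_phase = aci_band_features(rec.spectrum, scheme, "phase")
            usecp, lsecp, d, s = secp_features(rec.pressure_upper, rec.pressure_lower)
            row = {
                "sample": session.sample.name,
                "pressure_n": rec.set_point_n,
                "Z_se_static": z_static,
                "Phi_se_static": phi_static,
            }
            row.update({f"ACI_{k + 1}": aci[k] for k in range(len(scheme))})
            row.update(
                {f"ACIphase_{k + 1}": aci_phase[k] for k in range(len(scheme))}
            )
            row.update(
                {
                    "PVEP": sepv_feature(rec.pv),
                    "USECP": usecp, "LSECP": lsecp,
                    "SECP_D": d, "SECP_S": s,
                    "speed_mm_s": speed, "path_mm": path,
                }
            )
            rows.append(row)
    columns = (
        ["sample", "pressure_n"]
        + ELECTROCHEMICAL_COLUMNS[:-1]
        + PHASE_BAND_COLUMNS
        + ["PVEP"]
        + SECP_COLUMNS
        + MOVEMENT_COLUMNS
    )
    return pd.DataFrame(rows, columns=columns)
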