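"""File formats, run configuration and the end-to-end pipeline.

All artifacts are plain text: CSV for spectra, traces, signals and feature
tables (units fixed in the column names), JSON for catalogs, reports,
configuration and the run manifest.  Writers emit 9 significant digits so
write -> read round-trips are lossless to float text representation, and a
run manifest (seed, config hash, library versions) makes any run exactly
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .circuit import ImpedanceSpectrum, InterfaceParams, PairStack, pair_spectrum
from .errors import InputError, SpectrumParseError
from .evaluate import (
    CLASReport,
    ComplianceRecord,
    CorrelationReport,
    clas_metrics,
    method1_correlate,
    yyt_compliance,
)
from .features import feature_table, parameter_report
from .platforms import (
    ElectrodeSample,
    LevelRecord,
    MeasurementSession,
    MotionProfile,
    NoiseSpec,
    SignalPair,
    StaticTrace,
    Trace,
    sample_catalog,
    simulate_aeep_session,
    simulate_peep_session,
    wet_ensemble,
)

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_trace",
    "write_trace",
    "read_signals",
    "write_signals",
    "sample_to_dict",
    "sample_from_dict",
    "write_catalog",
    "read_catalog",
    "session_to_dir",
    "session_from_dir",
    "write_feature_table",
    "read_feature_table",
    "write_correlation_report",
    "write_clas_report",
    "write_compliance_record",
    "RunConfig",
    "SourceSpec",
    "run_pipeline",
]

log = logging.getLogger("seeplab")

SPECTRUM_HEADER = "frequency_hz,z_mod_ohm,z_phase_deg"
_FMT = "%.9g"


def _fmt(x: float) -> str:
    return _FMT % x


# --------------------------------------------------------------------------
# spectrum CSV

def write_spectrum(spectrum: ImpedanceSpectrum, path) -> None:
    """Write a spectrum as CSV with 9 significant digits."""
    lines = [SPECTRUM_HEADER]
    for f, m, p in zip(
        spectrum.frequency_hz, spectrum.magnitude_ohm, spectrum.phase_deg
    ):
        lines.append(f"{_fmt(f)},{_fmt(m)},{_fmt(p)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum(path) -> ImpedanceSpectrum:
    """Read a spectrum CSV, validating grid and physical bounds.

    Errors name the offending line: malformed rows, non-increasing
    frequencies, negative magnitudes and phases outside [-90, 0] degrees
    (the attainable range of the RC interface circuits) are all rejected.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != SPECTRUM_HEADER:
        raise SpectrumParseError(
            f"{path.name} line 1: expected header {SPECTRUM_HEADER!r}"
        )
    freq, mag, phase = [], [], []
    tol = 1e-9
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise SpectrumParseError(f"{path.name} line {i}: expected 3 fields")
        try:
            f, m, p = (float(v) for v in parts)
        except ValueError as exc:
            raise SpectrumParseError(f"{path.name} line {i}: {exc}") from exc
        if freq and f <= freq[-1]:
            raise SpectrumParseError(
                f"{path.name} line {i}: frequencies must be strictly increasing"
            )
        if m < 0:
            raise SpectrumParseError(
                f"{path.name} line {i}: negative impedance magnitude"
            )
        if not (-90.0 - tol <= p <= 0.0 + tol):
            raise SpectrumParseError(
                f"{path.name} line {i}: phase {p:g} outside [-90, 0] degrees"
            )
        freq.append(f)
        mag.append(m)
        phase.append(p)
    if not freq:
        raise SpectrumParseError(f"{path.name}: no data rows")
    return ImpedanceSpectrum(np.array(freq), np.array(mag), np.array(phase))


# --------------------------------------------------------------------------
# traces and signals

def write_trace(trace: Trace, path, value_name: str = "value") -> None:
    lines = [f"time_s,{value_name}"]
    for t, v in zip(trace.time_s, trace.values):
        lines.append(f"{_fmt(t)},{_fmt(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trace(path) -> Trace:
    df = pd.read_csv(path)
    if df.shape[1] != 2 or df.columns[0] != "time_s":
        raise SpectrumParseError(f"{Path(path).name}: expected time_s,<value>")
    return Trace(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


def write_signals(pair: SignalPair, path) -> None:
    lines = ["time_s,sfsg_mv,sfme_mv"]
    t = np.arange(pair.sfsg_mv.size) / pair.sampling_rate_hz
    for ti, a, b in zip(t, pair.sfsg_mv, pair.sfme_mv):
        lines.append(f"{_fmt(ti)},{_fmt(a)},{_fmt(b)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_signals(path, sampling_rate_hz: float | None = None) -> SignalPair:
    df = pd.read_csv(path)
    expected = ["time_s", "sfsg_mv", "sfme_mv"]
    if list(df.columns) != expected:
        raise SpectrumParseError(f"{Path(path).name}: expected columns {expected}")
    t = df["time_s"].to_numpy()
    if sampling_rate_hz is None:
        if t.size < 2:
            raise InputError("cannot infer sampling rate from one sample")
        sampling_rate_hz = 1.0 / (t[1] - t[0])
    return SignalPair(
        sampling_rate_hz=float(sampling_rate_hz),
        sfsg_mv=df["sfsg_mv"].to_numpy(),
        sfme_mv=df["sfme_mv"].to_numpy(),
        duration_s=t.size / float(sampling_rate_hz),
    )


# --------------------------------------------------------------------------
# catalogs (JSON)

def sample_to_dict(sample: ElectrodeSample) -> dict:
    base = {k: v for k, v in asdict(sample.base).items() if v is not None}
    return {
        "name": sample.name,
        "base": base,
        "kappa_R": sample.kappa_R,
        "kappa_C": sample.kappa_C,
        "F_half": sample.F_half,
        "gamma_pv": sample.gamma_pv,
        "noise": asdict(sample.noise),
    }


def sample_from_dict(d: dict) -> ElectrodeSample:
    return ElectrodeSample(
        name=d["name"],
        base=InterfaceParams(**d["base"]),
        kappa_R=d["kappa_R"],
        kappa_C=d["kappa_C"],
        F_half=d["F_half"],
        gamma_pv=d["gamma_pv"],
        noise=NoiseSpec(**d["noise"]),
    )


def write_catalog(samples: list[ElectrodeSample], path, seed: int | None = None) -> None:
    doc = {
        "format": "seeplab-catalog-v1",
        "seed": seed,
        "samples": [sample_to_dict(s) for s in samples],
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_catalog(path) -> list[ElectrodeSample]:
    doc = json.loads(Path(path).read_text())
    return [sample_from_dict(d) for d in doc["samples"]]


# --------------------------------------------------------------------------
# sessions (directory of CSVs + JSON manifest)

def session_to_dir(session: MeasurementSession, outdir) -> Path:
    """Serialize a session to a directory of CSV files plus session.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "format": "seeplab-session-v1",
        "platform": session.platform,
        "sample": sample_to_dict(session.sample),
        "pressure_levels": list(session.pressure_levels),
        "seed": session.seed,
        "n_records": len(session.records),
        "stacks": [
            {
                "electrode_1": {k: v for k, v in asdict(r.stack.electrode_1).items() if v is not None},
                "electrode_2": {k: v for k, v in asdict(r.stack.electrode_2).items() if v is not None},
                "R_tissue": r.stack.R_tissue,
                "Z_in": r.stack.Z_in,
            }
            for r in session.records
        ],
        "motion": None
        if session.motion is None
        else {
            "set_speed_mm_s": session.motion.set_speed_mm_s,
            "set_path_mm": session.motion.set_path_mm,
        },
        "sampling_rate_hz": None
        if session.signals is None
        else session.signals.sampling_rate_hz,
    }
    (outdir / "session.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )
    for i, rec in enumerate(session.records):
        tag = f"level_{i:02d}"
        write_spectrum(rec.spectrum, outdir / f"{tag}_spectrum.csv")
        write_spectrum(rec.upper_spectrum, outdir / f"{tag}_upper_spectrum.csv")
        write_trace(rec.pressure_upper, outdir / f"{tag}_pressure_upper.csv", "force_cn")
        write_trace(rec.pressure_lower, outdir / f"{tag}_pressure_lower.csv", "force_cn")
        write_trace(rec.pv, outdir / f"{tag}_pv.csv", "pv_mv")
        static = pd.DataFrame(
            {
                "time_s": rec.static.time_s,
                "z_mod_ohm": rec.static.magnitude_ohm,
                "z_phase_deg": rec.static.phase_deg,
            }
        )
        static.to_csv(outdir / f"{tag}_static.csv", index=False, float_format=_FMT)
    if session.signals is not None:
        write_signals(session.signals, outdir / "signals.csv")
    if session.motion is not None:
        motion = pd.DataFrame(
            {
                "time_s": session.motion.time_s,
                "displacement_mm": session.motion.displacement_mm,
                "speed_mm_s": session.motion.speed_mm_s,
                "z_factor": session.motion.z_factor,
                "pv_artifact_mv": session.motion.pv_artifact_mv,
            }
        )
        motion.to_csv(outdir / "motion.csv", index=False, float_format=_FMT)
    return outdir


def session_from_dir(indir) -> MeasurementSession:
    """Re-assemble a session from :func:`session_to_dir` output."""
    indir = Path(indir)
    meta = json.loads((indir / "session.json").read_text())
    sample = sample_from_dict(meta["sample"])
    records = []
    for i in range(meta["n_records"]):
        tag = f"level_{i:02d}"
        stack_d = meta["stacks"][i]
        stack = PairStack(
            InterfaceParams(**stack_d["electrode_1"]),
            InterfaceParams(**stack_d["electrode_2"]),
            R_tissue=stack_d["R_tissue"],
            Z_in=stack_d["Z_in"],
        )
        static_df = pd.read_csv(indir / f"{tag}_static.csv")
        records.append(
            LevelRecord(
                set_point_n=meta["pressure_levels"][i],
                stack=stack,
                pressure_upper=read_trace(indir / f"{tag}_pressure_upper.csv"),
                pressure_lower=read_trace(indir / f"{tag}_pressure_lower.csv"),
                static=StaticTrace(
                    static_df["time_s"].to_numpy(),
                    static_df["z_mod_ohm"].to_numpy(),
                    static_df["z_phase_deg"].to_numpy(),
                ),
                spectrum=read_spectrum(indir / f"{tag}_spectrum.csv"),
                upper_spectrum=read_spectrum(indir / f"{tag}_upper_spectrum.csv"),
                pv=read_trace(indir / f"{tag}_pv.csv"),
            )
        )
    motion = None
    if meta["motion"] is not None:
        mdf = pd.read_csv(indir / "motion.csv")
        motion = MotionProfile(
            time_s=mdf["time_s"].to_numpy(),
            displacement_mm=mdf["displacement_mm"].to_numpy(),
            speed_mm_s=mdf["speed_mm_s"].to_numpy(),
            z_factor=mdf["z_factor"].to_numpy(),
            pv_artifact_mv=mdf["pv_artifact_mv"].to_numpy(),
            set_speed_mm_s=meta["motion"]["set_speed_mm_s"],
            set_path_mm=meta["motion"]["set_path_mm"],
        )
    signals = None
    if meta["sampling_rate_hz"] is not None:
        signals = read_signals(indir / "signals.csv", meta["sampling_rate_hz"])
    return MeasurementSession(
        platform=meta["platform"],
        sample=sample,
        pressure_levels=list(meta["pressure_levels"]),
        records=records,
        motion=motion,
        signals=signals,
        seed=meta["seed"],
    )


# --------------------------------------------------------------------------
# tables and reports

def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format=_FMT)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_correlation_report(report: CorrelationReport, path) -> None:
    """Write the cross-sample correlation table (mean +- sd, flags)."""
    table = report.to_table()
    table.index.name = "characteristic"
    table.to_csv(path)
    raw = Path(path).with_suffix(".per_sample.csv")
    report.per_sample.to_csv(raw, float_format=_FMT)


def write_clas_report(report: CLASReport, path) -> None:
    doc = {
        "attenuation": report.attenuation,
        "rmse_mv": report.rmse_mv,
        "lag_s": report.lag_s,
        "band_loss": [None if math.isnan(v) else v for v in report.band_loss],
        "snr_difference_db": report.snr_difference_db,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def write_compliance_record(record: ComplianceRecord, path) -> None:
    doc = {
        "z10_ohm": list(record.z10_ohm),
        "mean_z10_ohm": record.mean_z10_ohm,
        "max_z10_ohm": record.max_z10_ohm,
        "current_pp_ua": record.current_pp_ua,
        "drive_mv": record.drive_mv,
        "mean_rule_pass": record.mean_rule_pass,
        "pair_rule_pass": record.pair_rule_pass,
        "current_rule_pass": record.current_rule_pass,
        "overall_pass": record.overall_pass,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


# --------------------------------------------------------------------------
# run configuration and pipeline

class SourceSpec(BaseModel):
    """Active-platform source signal specification."""

    model_config = ConfigDict(extra="forbid")

    kind: Literal["sine", "ecg"] = "ecg"
    frequency_hz: float = 10.0  # sine only
    heart_rate_bpm: float = 60.0  # ecg only
    amplitude_mv: float = 1.0
    duration_s: float = 10.0
    rate_hz: float = 500.0

    def to_args(self) -> dict:
        return {
            "kind": self.kind,
            "f_or_hr": self.frequency_hz if self.kind == "sine" else self.heart_rate_bpm,
            "amplitude": self.amplitude_mv,
            "duration": self.duration_s,
            "rate": self.rate_hz,
        }


class NoiseOverrides(BaseModel):
    model_config = ConfigDict(extra="forbid")

    sigma_z: float | None = None
    sigma_phase: float | None = None
    sigma_pv: float | None = None
    sigma_f: float | None = None
    sigma_sig: float | None = None
    sigma_skin: float | None = None


class RunConfig(BaseModel):
    """Validated configuration for a full pipeline run.

    Unknown keys are rejected, so a stored config is a complete and exact
    description of the run (together with the seed in the manifest).
    """

    model_config = ConfigDict(extra="forbid")

    platform: Literal["PEEP", "AEEP"] = "PEEP"
    catalog_seed: int = 0
    catalog_path: str | None = None
    n_samples: int = Field(default=10, ge=2)
    pressure_levels: list[float] | None = None
    z_in_ohm: float | None = 1e6
    source: SourceSpec = Field(default_factory=SourceSpec)
    noise: NoiseOverrides | None = None
    with_fit: bool = False
    with_compliance: bool = True
    outdir: str = "runs/out"
    seed: int = 0
    verbosity: int = 1


def _apply_noise_overrides(
    sample: ElectrodeSample, overrides: NoiseOverrides | None
) -> ElectrodeSample:
    if overrides is None:
        return sample
    changes = {
        k: v for k, v in overrides.model_dump().items() if v is not None
    }
    if not changes:
        return sample
    noise = NoiseSpec(**{**asdict(sample.noise), **changes})
    return ElectrodeSample(
        name=sample.name,
        base=sample.base,
        kappa_R=sample.kappa_R,
        kappa_C=sample.kappa_C,
        F_half=sample.F_half,
        gamma_pv=sample.gamma_pv,
        noise=noise,
    )


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Simulate -> extract -> evaluate (-> fit, -> compliance) on disk.

    Writes per-sample session directories, the feature table, the
    method-1 correlation report, parameter reports, the conduction-loss
    report (active platform), the compliance record for the default wet
    ensemble, optional coupling fits, and a manifest.  Identical
    config + seed give byte-identical numeric outputs.  Returns a dict of
    artifact paths keyed by artifact name.
    """
    from .fitting import fit_pressure_coupling  # deferred: heavy import

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    level = logging.WARNING if config.verbosity < 1 else logging.INFO
    logging.basicConfig(level=level, format="%(name)s: %(message)s")

    if config.catalog_path is not None:
        samples = read_catalog(config.catalog_path)
    else:
        samples = sample_catalog(config.catalog_seed, n=config.n_samples)
    samples = [_apply_noise_overrides(s, config.noise) for s in samples]
    artifacts: dict[str, str] = {}
    write_catalog(samples, outdir / "catalog.json", seed=config.catalog_seed)
    artifacts["catalog"] = str(outdir / "catalog.json")

    sessions = []
    reports = {}
    for i, sample in enumerate(samples):
        seed_i = (config.seed * 100003 + i) % (2 ** 31)
        log.info("simulating %s session for %s", config.platform, sample.name)
        if config.platform == "PEEP":
            session = simulate_peep_session(
                sample, config.pressure_levels, seed=seed_i
            )
        else:
            session = simulate_aeep_session(
                sample,
                config.pressure_levels,
                source=config.source.to_args(),
                z_in=config.z_in_ohm,
                seed=seed_i,
            )
        sessions.append(session)
        sdir = session_to_dir(session, outdir / "sessions" / sample.name)
        artifacts[f"session:{sample.name}"] = str(sdir)
        reports[sample.name] = parameter_report(session)
    (outdir / "parameter_reports.json").write_text(
        json.dumps(reports, indent=2, sort_keys=True) + "\n"
    )
    artifacts["parameter_reports"] = str(outdir / "parameter_reports.json")

    table = feature_table(sessions)
    write_feature_table(table, outdir / "features.csv")
    artifacts["features"] = str(outdir / "features.csv")

    report = method1_correlate(table)
    write_correlation_report(report, outdir / "correlation_method1.csv")
    artifacts["correlation_method1"] = str(outdir / "correlation_method1.csv")

    if config.platform == "AEEP":
        clas = clas_metrics(sessions[0].signals)
        write_clas_report(clas, outdir / "clas.json")
        artifacts["clas"] = str(outdir / "clas.json")

    if config.with_compliance:
        stacks = wet_ensemble(seed=config.seed)
        grid = np.logspace(math.log10(0.1), math.log10(200.0), 100)
        spectra = [pair_spectrum(st, grid) for st in stacks]
        record = yyt_compliance(spectra)
        write_compliance_record(record, outdir / "compliance.json")
        artifacts["compliance"] = str(outdir / "compliance.json")

    if config.with_fit:
        fits = {}
        for session in sessions:
            fit = fit_pressure_coupling(session, seed=config.seed)
            fits[session.sample.name] = {
                "kappa_R": fit.kappa_R,
                "kappa_C": fit.kappa_C,
                "F_half": fit.F_half,
                "gamma_pv": fit.gamma_pv,
                "success": fit.success,
            }
        (outdir / "coupling_fits.json").write_text(
            json.dumps(fits, indent=2, sort_keys=True) + "\n"
        )
        artifacts["coupling_fits"] = str(outdir / "coupling_fits.json")

    config_json = config.model_dump_json(indent=2)
    manifest = {
        "seeplab_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "artifacts": artifacts,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    artifacts["manifest"] = str(outdir / "manifest.json")
    return artifacts
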