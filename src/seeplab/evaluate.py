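"""Evaluation methods for electrode samples.

Three quantitative methods, mirroring how the physical platforms are used:

1. correlation between the electrochemical characteristics and the contact
   pressure characteristics across a force sweep (per sample, then averaged
   across samples, with a two-sided t-test significance flag);
2. the same correlation analysis against relative-movement features;
3. conduction-loss metrics comparing the source signal (SFSG) with the
   electrode-measured signal (SFME) in time and frequency domain.

A compliance checker implements the disposable-ECG electrode pass rules
(YY/T 0196-2005): ensemble-average AC impedance at 10 Hz at most 2 kOhm
over 12 pairs, every single pair at most 3 kOhm, and test current at most
100 uA peak-to-peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .circuit import ImpedanceSpectrum
from .errors import (
    CoverageError,
    InputError,
    UndefinedCorrelationError,
    UndefinedMetricError,
)
from .features import ELECTROCHEMICAL_COLUMNS, MOVEMENT_COLUMNS, SECP_COLUMNS
from .features import BandScheme, DEFAULT_BANDS
from .platforms import SignalPair

__all__ = [
    "pearson",
    "critical_r",
    "CorrelationReport",
    "method1_correlate",
    "method2_correlate",
    "CLASReport",
    "clas_metrics",
    "ComplianceRecord",
    "yyt_compliance",
    "YYT_MEAN_LIMIT_OHM",
    "YYT_PAIR_LIMIT_OHM",
    "YYT_CURRENT_LIMIT_UA",
]

YYT_MEAN_LIMIT_OHM = 2000.0
YYT_PAIR_LIMIT_OHM = 3000.0
YYT_CURRENT_LIMIT_UA = 100.0


def pearson(x, y) -> float:
    """Product-moment correlation coefficient of two equal-length samples.

    Raises :class:`UndefinedCorrelationError` when either input has zero
    variance, and :class:`InputError` on length mismatch or fewer than
    three points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("inputs must have equal length")
    if x.size < 3:
        raise InputError("need at least 3 points for a correlation")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedCorrelationError("constant input: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def critical_r(alpha: float, df: int) -> float:
    """Two-sided critical |r| for a t-test of zero correlation.

    ``t = r * sqrt(df) / sqrt(1 - r^2)`` maps the t critical value at
    significance ``alpha`` with ``df`` degrees of freedom back to
    ``r = t / sqrt(t^2 + df)``.
    """
    if df < 1:
        raise InputError("need df >= 1")
    t = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t / math.sqrt(t * t + df))


@dataclass
class CorrelationReport:
    """Cross-sample correlation grid (characteristics x conditioners).

    ``mean``/``sd``/``var`` hold the cross-sample mean, standard deviation
    and variance of per-sample coefficients; ``significant`` flags cells
    whose |mean| reaches the critical value at ``alpha`` with
    ``n_levels - 2`` degrees of freedom.  ``per_sample`` keeps the raw
    per-sample coefficients (NaN where undefined).
    """

    mean: pd.DataFrame
    sd: pd.DataFrame
    var: pd.DataFrame
    significant: pd.DataFrame
    per_sample: pd.DataFrame
    n_levels: int
    n_samples: int
    alpha: float
    critical: float

    def to_table(self) -> pd.DataFrame:
        """Human-readable table: "mean +- sd" strings plus flag columns."""
        out = {}
        for cond in self.mean.columns:
            out[cond] = [
                "" if np.isnan(m) else f"{m:.4f} ± {s:.4f}"
                for m, s in zip(self.mean[cond], self.sd[cond])
            ]
            out[f"{cond}_significant"] = list(self.significant[cond])
        return pd.DataFrame(out, index=self.mean.index)


def _correlate(
    table: pd.DataFrame,
    characteristics: list[str],
    conditioners: list[str],
    alpha: float,
) -> CorrelationReport:
    if "sample" not in table.columns:
        raise InputError("feature table needs a 'sample' column")
    groups = list(table.groupby("sample", sort=False))
    if len(groups) < 2:
        raise InputError("need at least 2 samples")
    sizes = {len(g) for _, g in groups}
    n_levels = min(sizes)
    if n_levels < 3:
        raise InputError("need at least 3 force levels per sample")
    rows = []
    for name, g in groups:
        for char in characteristics:
            coeffs = {}
            for cond in conditioners:
                try:
                    coeffs[cond] = pearson(g[char], g[cond])
                except UndefinedCorrelationError:
                    coeffs[cond] = np.nan
            rows.append({"sample": name, "characteristic": char, **coeffs})
    per_sample = pd.DataFrame(rows).set_index(["sample", "characteristic"])
    grouped = per_sample.groupby(level="characteristic", sort=False)
    mean = grouped.mean().reindex(characteristics)
    sd = grouped.std(ddof=1).reindex(characteristics)
    var = grouped.var(ddof=1).reindex(characteristics)
    crit = critical_r(alpha, n_levels - 2)
    significant = mean.abs().ge(crit) & mean.notna()
    return CorrelationReport(
        mean=mean,
        sd=sd,
        var=var,
        significant=significant,
        per_sample=per_sample,
        n_levels=n_levels,
        n_samples=len(groups),
        alpha=alpha,
        critical=crit,
    )


def method1_correlate(table: pd.DataFrame, alpha: float = 0.01) -> CorrelationReport:
    """Method 1: electrochemical characteristics vs contact pressure.

    ``table`` is a feature table (one row per sample and force level); for
    each sample, each of the 14 electrochemical characteristics is
    correlated with each of USECP, LSECP, SECP_D and SECP_S across force
    levels, then averaged across samples.
    """
    return _correlate(table, list(ELECTROCHEMICAL_COLUMNS), SECP_COLUMNS, alpha)


def method2_correlate(
    table: pd.DataFrame,
    alpha: float = 0.01,
    conditioners: tuple[str, ...] = tuple(MOVEMENT_COLUMNS),
) -> CorrelationReport:
    """Method 2: electrochemical characteristics vs relative movement.

    Identical machinery to method 1, conditioned on the movement features
    (mean speed, total path).  Sessions without movement yield constant
    conditioners and hence undefined (NaN) coefficients — they are
    reported as missing, never coerced to zero.
    """
    return _correlate(
        table, list(ELECTROCHEMICAL_COLUMNS), list(conditioners), alpha
    )


@dataclass
class CLASReport:
    """Conduction-loss metrics between source and measured signal."""

    attenuation: float  # 1 - p2p(SFME)/p2p(SFSG)
    rmse_mv: float  # after lag alignment
    lag_s: float  # argmax of the cross-correlation
    band_loss: np.ndarray  # per-band power loss ratio, clipped at 0
    snr_difference_db: float  # excess received power over the coherent part


def clas_metrics(pair: SignalPair, scheme: BandScheme = DEFAULT_BANDS) -> CLASReport:
    """Conduction loss of active signals: SFSG vs SFME.

    Time domain: lag from the cross-correlation peak, RMSE after
    alignment, and the peak-to-peak attenuation ``1 - p2p(SFME)/p2p(SFSG)``.
    Frequency domain: per band ``1 - P_band(SFME)/P_band(SFSG)`` clipped at
    zero (NaN where the source has no power in a band).  The SNR difference
    is ``10*log10(1 + P_residual/P_coherent)`` after optimal scaling of the
    aligned source — zero exactly when SFME reproduces a scaled copy of
    SFSG, positive as soon as incoherent noise is added.
    """
    sg = np.asarray(pair.sfsg_mv, dtype=float)
    me = np.asarray(pair.sfme_mv, dtype=float)
    n = sg.size
    if n < 2:
        raise InputError("signal pair too short")
    p_sg = float(np.mean(sg ** 2))
    if p_sg == 0.0:
        raise UndefinedMetricError("zero-power source signal")
    rate = pair.sampling_rate_hz

    xc = sps.correlate(me, sg, mode="full")
    lag = int(np.argmax(xc)) - (n - 1)
    if lag > 0:
        me_al, sg_al = me[lag:], sg[: n - lag]
    elif lag < 0:
        me_al, sg_al = me[: n + lag], sg[-lag:]
    else:
        me_al, sg_al = me, sg
    rmse = float(np.sqrt(np.mean((me_al - sg_al) ** 2)))

    p2p_sg = float(np.ptp(sg))
    attenuation = 1.0 - float(np.ptp(me)) / p2p_sg

    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    psg = np.abs(np.fft.rfft(sg)) ** 2
    pme = np.abs(np.fft.rfft(me)) ** 2
    losses = []
    for m in scheme.masks(freqs):
        band_sg = float(psg[m].sum())
        if band_sg == 0.0:
            losses.append(np.nan)
        else:
            losses.append(max(0.0, 1.0 - float(pme[m].sum()) / band_sg))

    denom = float(np.dot(sg_al, sg_al))
    a = float(np.dot(sg_al, me_al)) / denom if denom > 0 else 0.0
    resid = me_al - a * sg_al
    p_coh = a * a * float(np.mean(sg_al ** 2))
    if p_coh == 0.0:
        snr_diff = math.inf
    else:
        snr_diff = 10.0 * math.log10(1.0 + float(np.mean(resid ** 2)) / p_coh)

    return CLASReport(
        attenuation=attenuation,
        rmse_mv=rmse,
        lag_s=lag / rate,
        band_loss=np.array(losses),
        snr_difference_db=snr_diff,
    )


@dataclass
class ComplianceRecord:
    """Outcome of the disposable-ECG electrode pass rules."""

    z10_ohm: np.ndarray  # per-pair |Z| at 10 Hz
    mean_z10_ohm: float
    max_z10_ohm: float
    current_pp_ua: float  # worst-case pair current at the drive voltage
    drive_mv: float
    mean_rule_pass: bool  # mean |Z(10 Hz)| <= 2 kOhm
    pair_rule_pass: bool  # every |Z(10 Hz)| <= 3 kOhm
    current_rule_pass: bool  # current <= 100 uA peak-to-peak

    @property
    def overall_pass(self) -> bool:
        return self.mean_rule_pass and self.pair_rule_pass and self.current_rule_pass


def yyt_compliance(
    spectra: list[ImpedanceSpectrum], drive: float = 100.0
) -> ComplianceRecord:
    """Apply the disposable-ECG pass rules to 12 electrode-pair spectra.

    ``drive`` is the peak-to-peak test voltage in mV.  Rule (a): the mean
    of |Z| at 10 Hz across the 12 pairs must not exceed 2 kOhm.  Rule (b):
    no single pair may exceed 3 kOhm.  Rule (c): the test current, taken
    as ``drive`` over each pair's lowest-frequency (DC-offset proxy)
    impedance, must not exceed 100 uA peak-to-peak.
    """
    if len(spectra) != 12:
        raise InputError(f"expected 12 pair spectra, got {len(spectra)}")
    z10 = []
    currents = []
    for spec in spectra:
        if not spec.covers(10.0):
            raise CoverageError("every spectrum must cover 10 Hz")
        z10.append(spec.magnitude_at(10.0))
        z_low = float(spec.magnitude_ohm[0])
        if z_low == 0.0:
            raise ZeroDivisionError("pair has zero low-frequency impedance")
        currents.append(drive / z_low * 1e3)
    z10 = np.array(z10)
    current = float(np.max(currents))
    return ComplianceRecord(
        z10_ohm=z10,
        mean_z10_ohm=float(z10.mean()),
        max_z10_ohm=float(z10.max()),
        current_pp_ua=current,
        drive_mv=drive,
        mean_rule_pass=bool(z10.mean() <= YYT_MEAN_LIMIT_OHM),
        pair_rule_pass=bool(z10.max() <= YYT_PAIR_LIMIT_OHM),
        current_rule_pass=bool(current <= YYT_CURRENT_LIMIT_UA),
    )
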