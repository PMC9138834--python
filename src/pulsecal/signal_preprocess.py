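"""Waveform conditioning ahead of fiducial detection.

PPG: fourth-order Chebyshev type-II band-pass (0.5--10 Hz, 20 dB stop band)
followed by mean removal; first/second derivatives give the velocity (VPG)
and acceleration (APG) plethysmograms.  ECG: fourth-order Butterworth
high-pass at 0.5 Hz (baseline wander) and low-pass at 50 Hz (muscle noise and
mains).  All filters are applied forward-backward (zero phase) so that timing
features such as the pulse arrival time are not biased by group delay.

An automated quality gate stands in for visual artifact triage: flat arterial
pressure, ECG/PPG beat-rate disagreement and clipped or non-finite stretches
reject a record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synthetic_cohort import SignalRecord


@dataclass
class ProcessedSignals:
    ppg_f: np.ndarray
    vpg: np.ndarray
    apg: np.ndarray
    ecg_f: np.ndarray
    abp: np.ndarray | None
    fs: float


def _check_input(x: np.ndarray, fs: float, min_len: int, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if x.ndim != 1 or len(x) < min_len:
        raise ValueError(f"{name}: need a 1-D sequence of at least {min_len} samples")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name}: non-finite samples")
    return x


def ppg_bandpass_sos(fs: float, low: float = 0.5, high: float = 10.0,
                     order: int = 4, rs_db: float = 20.0) -> np.ndarray:
    """Design the PPG band-pass (Chebyshev II).

    ``order`` follows the convention of the classic design routines (an
    order-4 band-pass prototype, i.e. 4 poles per band edge).  A literal
    4-pole band-pass spanning 0.5--10 Hz has such soft edges that it
    attenuates the pulse fundamental and its first harmonics in-band, which
    visibly distorts pulse feet; the prototype convention keeps the passband
    flat from ~0.9 to ~9 Hz.
    """
    return sps.cheby2(order, rs_db, [low, high], btype="bandpass",
                      fs=fs, output="sos")


def filter_ppg(ppg: np.ndarray, fs: float, low: float = 0.5, high: float = 10.0,
               order: int = 4, rs_db: float = 20.0) -> np.ndarray:
    """Band-pass the raw PPG and remove the residual mean."""
    if fs <= 20:
        raise ValueError("fs must exceed 20 Hz for the 0.5-10 Hz band")
    x = _check_input(ppg, fs, 10 * order + 1, "ppg")
    y = sps.sosfiltfilt(ppg_bandpass_sos(fs, low, high, order, rs_db), x)
    return y - y.mean()


def ecg_filter_sos(fs: float, low: float = 0.5, high: float = 50.0,
                   order: int = 4) -> tuple[np.ndarray, np.ndarray]:
    hp = sps.butter(order, low, btype="highpass", fs=fs, output="sos")
    lp = sps.butter(order, high, btype="lowpass", fs=fs, output="sos")
    return hp, lp


def filter_ecg(ecg: np.ndarray, fs: float, low: float = 0.5, high: float = 50.0,
               order: int = 4) -> np.ndarray:
    """High-pass then low-pass the ECG (both zero-phase Butterworth)."""
    x = _check_input(ecg, fs, 10 * order + 1, "ecg")
    if high >= fs / 2:
        raise ValueError("low-pass cutoff must lie below Nyquist")
    hp, lp = ecg_filter_sos(fs, low, high, order)
    return sps.sosfiltfilt(lp, sps.sosfiltfilt(hp, x))


def derive_vpg_apg(ppg_f: np.ndarray, fs: float,
                   apg_smooth: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """First and second time derivatives of the filtered PPG, physical units.

    Central differences in the interior, one-sided at the edges.  The APG is
    additionally smoothed by a short centered moving average (default 5
    samples): extremum search on a second difference is noise-dominated
    otherwise, and a symmetric kernel adds no timing bias.
    """
    x = np.asarray(ppg_f, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    vpg = np.gradient(x, 1.0 / fs)
    apg = np.gradient(vpg, 1.0 / fs)
    if apg_smooth and apg_smooth > 1:
        kernel = np.ones(apg_smooth) / apg_smooth
        apg = np.convolve(apg, kernel, mode="same")
    return vpg, apg


def preprocess_record(record: SignalRecord, apg_smooth: int = 5) -> ProcessedSignals:
    ppg_f = filter_ppg(record.ppg, record.fs)
    vpg, apg = derive_vpg_apg(ppg_f, record.fs, apg_smooth=apg_smooth)
    ecg_f = filter_ecg(record.ecg, record.fs)
    abp = None if record.abp is None else np.asarray(record.abp, dtype=float)
    return ProcessedSignals(ppg_f=ppg_f, vpg=vpg, apg=apg, ecg_f=ecg_f, abp=abp,
                            fs=record.fs)


def _clipped_fraction(x: np.ndarray, min_run: int = 5) -> float:
    """Fraction of samples sitting in runs of >= min_run identical extreme values."""
    x = np.asarray(x, dtype=float)
    finite = np.isfinite(x)
    bad = np.count_nonzero(~finite)
    if finite.sum() == 0:
        return 1.0
    lo, hi = np.min(x[finite]), np.max(x[finite])
    if hi == lo:
        return 1.0
    at_rail = finite & ((x == lo) | (x == hi))
    # count samples inside long constant runs at a rail
    n = len(x)
    i = 0
    clipped = 0
    while i < n:
        if at_rail[i]:
            j = i
            while j < n and at_rail[j] and x[j] == x[i]:
                j += 1
            if j - i >= min_run:
                clipped += j - i
            i = j
        else:
            i += 1
    return (clipped + bad) / n


def _rate_from_peaks(x: np.ndarray, fs: float, min_dist_s: float = 0.45) -> float:
    x = np.asarray(x, dtype=float)
    prom = 0.3 * (np.percentile(x, 95) - np.percentile(x, 5))
    if prom <= 0:
        return 0.0
    peaks, _ = sps.find_peaks(x, distance=max(1, int(min_dist_s * fs)), prominence=prom)
    if len(peaks) < 2:
        return 0.0
    return float((len(peaks) - 1) / ((peaks[-1] - peaks[0]) / fs))


def quality_gate(record: SignalRecord,
                 processed: ProcessedSignals | None = None) -> tuple[bool, list[str]]:
    """Automated proxy for visual artifact screening.  Always returns a verdict.

    Fails on: arterial pulse excursion below 10 mmHg ("flat ABP"); ECG- and
    PPG-derived beat rates disagreeing by more than 20%; any signal with more
    than 1% non-finite or rail-clipped samples.
    """
    from . import fiducial_detect  # local import; detector reuses this module's types

    reasons: list[str] = []
    signals = {"ecg": record.ecg, "ppg": record.ppg}
    if record.abp is not None:
        signals["abp"] = record.abp
        abp = np.asarray(record.abp, dtype=float)
        finite = abp[np.isfinite(abp)]
        if len(finite) == 0 or (np.max(finite) - np.min(finite)) < 10.0:
            reasons.append("flat ABP")
    for name, x in signals.items():
        x = np.asarray(x, dtype=float)
        frac = np.count_nonzero(~np.isfinite(x)) / len(x)
        if frac > 0.01:
            reasons.append(f"non-finite {name} samples ({frac:.1%})")
            continue
        cf = _clipped_fraction(np.nan_to_num(x))
        if cf > 0.01:
            reasons.append(f"clipped {name} samples ({cf:.1%})")

    if not any(r.startswith(("non-finite", "clipped")) for r in reasons):
        try:
            proc = processed or preprocess_record(record)
            r_peaks = fiducial_detect.detect_r_peaks(proc.ecg_f, record.fs)
            if len(r_peaks) >= 2:
                ecg_rate = (len(r_peaks) - 1) / ((r_peaks[-1] - r_peaks[0]) / record.fs)
            else:
                ecg_rate = 0.0
            ppg_rate = _rate_from_peaks(proc.ppg_f, record.fs)
            if ecg_rate <= 0 or ppg_rate <= 0:
                reasons.append("undetectable beat rate")
            elif abs(ecg_rate - ppg_rate) / ((ecg_rate + ppg_rate) / 2) > 0.20:
                reasons.append(
                    f"ECG/PPG rate mismatch ({ecg_rate:.2f} vs {ppg_rate:.2f} Hz)")
        except ValueError as exc:
            reasons.append(f"preprocessing failed: {exc}")
    return (len(reasons) == 0, reasons)
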