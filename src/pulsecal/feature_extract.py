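"""The 23 discriminatory features per beat, and their per-segment aggregate.

Propagation features: three pulse arrival times (R peak to pulse foot,
maximum-slope point and systolic peak) and the transit interval between the
ABP systolic peak and the PPG systolic peak.  Morphology features: systolic
amplitudes on PPG and VPG, inter-beat intervals (peak-to-peak TPP, onset-to-
onset TPI, a-to-a), rising time, half-height width, the three pulse areas and
their inflection-point ratio (IPA = A2/A1), and the signed APG wave ratios
b/a, c/a, d/a, e/a plus the four composite ratios (b-c-d-e)/a, (b-e)/a,
(b-c-d)/a and (c+d-b)/a.

Amplitudes, widths and areas are measured relative to the PPG value at the
beat's onset point: the mean-removed signal has no natural per-beat zero, so
the onset value serves as the beat baseline.  Inter-beat features use the
current and the next physiologically consecutive beat and are undefined on
the last beat of a run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fiducial_detect import FiducialSet
from .signal_preprocess import ProcessedSignals

FEATURE_NAMES = [
    "pat_foot", "pat_derivative", "pat_peak", "ptt",
    "amp_s_ppg", "amp_w_vpg", "tpp", "tpi", "rising_time", "width",
    "pulse_area", "area1", "area2", "ipa", "a_a",
    "b_a", "c_a", "d_a", "e_a",
    "r_bcde_a", "r_be_a", "r_bcd_a", "r_cdb_a",
]

#: features needing the next consecutive beat
_INTERBEAT = {"tpp", "tpi", "a_a", "area2", "pulse_area", "ipa"}


def _half_height_width(ppg: np.ndarray, o: int, s: int, end: int,
                       baseline: float, fs: float) -> float:
    """Pulse width at half the systolic height above baseline (interpolated)."""
    h = baseline + 0.5 * (ppg[s] - baseline)
    left = np.nan
    for i in range(s, o, -1):
        if ppg[i - 1] <= h <= ppg[i]:
            frac = (h - ppg[i - 1]) / (ppg[i] - ppg[i - 1]) if ppg[i] != ppg[i - 1] else 0.0
            left = (i - 1) + frac
            break
    right = np.nan
    for i in range(s, min(end, len(ppg) - 1)):
        if ppg[i] >= h >= ppg[i + 1]:
            frac = (ppg[i] - h) / (ppg[i] - ppg[i + 1]) if ppg[i] != ppg[i + 1] else 0.0
            right = i + frac
            break
    if np.isnan(left) or np.isnan(right):
        return np.nan
    return (right - left) / fs


def beat_features(signals: ProcessedSignals, fid: FiducialSet, i: int,
                  include_ptt: bool = True) -> dict[str, float]:
    """Feature vector for accepted beat ``i``; undefined entries are NaN."""
    fs = fid.fs
    ppg, vpg, apg = signals.ppg_f, signals.vpg, signals.apg
    r, o, s, w = int(fid.r[i]), int(fid.o[i]), int(fid.s[i]), int(fid.w[i])
    a, b, c, d, e = (int(fid.a[i]), int(fid.b[i]), int(fid.c[i]),
                     int(fid.d[i]), int(fid.e[i]))
    baseline = float(ppg[o])

    f: dict[str, float] = {name: np.nan for name in FEATURE_NAMES}
    f["pat_foot"] = (o - r) / fs
    f["pat_derivative"] = (w - r) / fs
    f["pat_peak"] = (s - r) / fs
    if include_ptt and fid.sbp_idx[i] >= 0 and np.isfinite(fid.sbp[i]):
        f["ptt"] = abs(s - int(fid.sbp_idx[i])) / fs
    f["amp_s_ppg"] = float(ppg[s]) - baseline
    f["amp_w_vpg"] = float(vpg[w])
    f["rising_time"] = (s - o) / fs

    av = float(apg[a])
    if av != 0.0:
        bv, cv, dv, ev = float(apg[b]), float(apg[c]), float(apg[d]), float(apg[e])
        f["b_a"] = bv / av
        f["c_a"] = cv / av
        f["d_a"] = dv / av
        f["e_a"] = ev / av
        f["r_bcde_a"] = (bv - cv - dv - ev) / av
        f["r_be_a"] = (bv - ev) / av
        f["r_bcd_a"] = (bv - cv - dv) / av
        f["r_cdb_a"] = (cv + dv - bv) / av

    has_next = (i + 1 < fid.n_beats) and (fid.next_r[i] == fid.r[i + 1])
    o_next = int(fid.o[i + 1]) if has_next else None
    end_for_width = o_next if o_next is not None else min(len(ppg) - 1, s + int(1.0 * fs))
    f["width"] = _half_height_width(ppg, o, s, end_for_width, baseline, fs)

    x = ppg - baseline
    f["area1"] = float(np.trapezoid(x[o:s + 1], dx=1.0 / fs))
    if has_next:
        s_next, a_next = int(fid.s[i + 1]), int(fid.a[i + 1])
        f["tpp"] = (s_next - s) / fs
        f["tpi"] = (o_next - o) / fs
        f["a_a"] = (a_next - a) / fs
        f["area2"] = float(np.trapezoid(x[s:o_next + 1], dx=1.0 / fs))
        f["pulse_area"] = float(np.trapezoid(x[o:o_next + 1], dx=1.0 / fs))
        f["ipa"] = f["area2"] / f["area1"] if f["area1"] != 0.0 else np.nan
    return f


def beats_to_frame(signals: ProcessedSignals, fid: FiducialSet,
                   include_ptt: bool = True) -> pd.DataFrame:
    """All accepted beats as rows; adds the beat's R index and onset time."""
    rows = [beat_features(signals, fid, i, include_ptt) for i in range(fid.n_beats)]
    df = pd.DataFrame(rows, columns=FEATURE_NAMES)
    df.insert(0, "r_index", fid.r)
    df.insert(1, "sbp_beat", fid.sbp)
    return df


class SegmentRejected(ValueError):
    """Raised when a (sub-)segment has too few usable beats to aggregate."""


def aggregate_features(beats: pd.DataFrame, min_beats: int = 3) -> tuple[dict[str, float], int]:
    """Median over beats per feature, excluding undefined beat values.

    Returns the aggregate vector and the number of beats used.  Rejects the
    segment when fewer than ``min_beats`` beats carry the core timing
    features.
    """
    usable = int(beats["pat_foot"].notna().sum()) if len(beats) else 0
    if usable < min_beats:
        raise SegmentRejected(f"only {usable} usable beats (< {min_beats})")
    agg = {name: float(beats[name].median(skipna=True)) for name in FEATURE_NAMES}
    return agg, usable
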