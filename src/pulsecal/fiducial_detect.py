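"""Fiducial-point detection: ECG R peaks, PPG/VPG/APG landmarks, per-pulse SBP.

R peaks come from a phasor-transform detector: the ECG is mapped sample-wise
to a phase angle phi[n] = arctan(x[n] / Rv), which compresses amplitude while
sharpening the QRS into a near-saturating phase excursion; peaks of phi above
an adaptive threshold, separated by a refractory period, mark the beats.  A
narrow QRS-band zero-phase pre-filter (5--18 Hz) inside the detector keeps T
waves and broadband noise from saturating the phase the same way, and the
reported index is refined to the ECG maximum near each phase peak.

Per R--R interval the PPG systolic peak (S), pulse onset (O), VPG peak (W)
and the APG a--e extremum sequence are located by windowed min/max search;
beats missing any landmark are dropped and counted.  Per-pulse systolic
pressure is the ABP maximum within the beat; the segment label follows the
130 mmHg rule (mean SBP < 130 -> NTS, otherwise HTS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signal_preprocess import ProcessedSignals

NTS = "NTS"
HTS = "HTS"

#: decision boundary for the binary normotensive/hypertensive rule, mmHg
SBP_THRESHOLD = 130.0


@dataclass
class FiducialSet:
    """Per-beat fiducial indices (0-based) and per-beat systolic pressure.

    Arrays hold accepted beats only; ``next_r`` is the R peak closing each
    beat, so row ``i`` and ``i+1`` describe physiologically consecutive beats
    iff ``next_r[i] == r[i+1]``.
    """

    r: np.ndarray
    next_r: np.ndarray
    o: np.ndarray
    s: np.ndarray
    w: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    e: np.ndarray
    sbp: np.ndarray
    sbp_idx: np.ndarray
    fs: float
    dropped: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_beats(self) -> int:
        return len(self.r)


@dataclass
class SegmentLabel:
    label: str
    sbp_summary: float


def detect_r_peaks(ecg_f: np.ndarray, fs: float, refractory: float = 0.25,
                   rv_fraction: float = 0.25, threshold_frac: float = 0.60) -> np.ndarray:
    """Locate R peaks via the phasor transform of a QRS-enhanced ECG.

    Returns sorted sample indices, one per detected QRS; an empty array for
    flat input.  ``threshold_frac`` scales the running median of the last 8
    accepted peak phases into the acceptance threshold.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    x = np.asarray(ecg_f, dtype=float)
    if len(x) == 0 or np.max(np.abs(x)) == 0:
        return np.array([], dtype=int)

    high = min(18.0, 0.45 * fs)
    sos = sps.butter(2, [5.0, high], btype="bandpass", fs=fs, output="sos")
    xb = sps.sosfiltfilt(sos, x)
    m = float(np.max(np.abs(xb)))
    if m == 0:
        return np.array([], dtype=int)
    rv = rv_fraction * m
    phi = np.arctan(xb / rv)

    dist = max(1, int(round(refractory * fs)))
    cand, _ = sps.find_peaks(phi, distance=dist)
    cand = cand[phi[cand] > 0]
    if len(cand) == 0:
        return np.array([], dtype=int)

    # adaptive threshold: seeded from the strongest candidates, then tracking
    # the running median of the last 8 accepted peak phases
    strong = np.sort(phi[cand])[-max(1, len(cand) // 10):]
    recent: list[float] = list(np.full(8, float(np.median(strong))))
    accepted = []
    for p in cand:
        thr = threshold_frac * float(np.median(recent[-8:]))
        if phi[p] >= thr:
            accepted.append(p)
            recent.append(float(phi[p]))

    # refine to the ECG maximum around each phase peak; drop duplicates
    half = max(1, int(round(0.06 * fs)))
    refined = []
    for p in accepted:
        lo, hi = max(0, p - half), min(len(x), p + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(refined)
    if len(refined) > 1:
        keep = [refined[0]]
        for p in refined[1:]:
            if p - keep[-1] >= dist:
                keep.append(p)
        refined = np.array(keep)
    return refined.astype(int)


def _local_extrema(x: np.ndarray):
    """Indices and kinds (+1 max / -1 min) of interior local extrema."""
    d = np.diff(x)
    sign = np.sign(d)
    for i in range(1, len(sign)):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    turns = np.nonzero(sign[1:] != sign[:-1])[0] + 1
    kinds = sign[turns - 1]
    return turns, kinds


def detect_ppg_fiducials(signals: ProcessedSignals, r_peaks: np.ndarray,
                         s_window_frac: float = 0.6,
                         apg_span: float = 0.75) -> FiducialSet:
    """Per-beat O, S, W and a--e landmarks between consecutive R peaks.

    Beats with any undetectable landmark are excluded (complete-case per
    beat) and recorded in ``dropped`` with a reason.  Raises if no beat at
    all is detectable.
    """
    r_peaks = np.asarray(r_peaks, dtype=int)
    if len(r_peaks) < 2:
        raise ValueError("need at least 2 R peaks")
    fs = signals.fs
    ppg, vpg, apg = signals.ppg_f, signals.vpg, signals.apg
    med_rr = float(np.median(np.diff(r_peaks)))
    s_win = int(round(s_window_frac * med_rr))

    rows = {k: [] for k in "rosw"} | {k: [] for k in "abcde"}
    next_rs, sbps, sbp_idxs, dropped = [], [], [], []

    for i in range(len(r_peaks) - 1):
        r0, r1 = int(r_peaks[i]), int(r_peaks[i + 1])
        win_end = min(r0 + s_win, r1 - 1)
        if win_end <= r0 + 2:
            dropped.append((i, "window too short")); continue
        seg = ppg[r0 + 1:win_end + 1]
        s_idx = r0 + 1 + int(np.argmax(seg))
        if s_idx >= win_end:
            dropped.append((i, "systolic peak at window edge")); continue
        if s_idx <= r0 + 1:
            dropped.append((i, "no onset before systolic peak")); continue
        o_idx = r0 + 1 + int(np.argmin(ppg[r0 + 1:s_idx]))
        if not (r0 < o_idx < s_idx):
            dropped.append((i, "onset ordering failed")); continue
        w_idx = o_idx + 1 + int(np.argmax(vpg[o_idx + 1:s_idx + 1]))
        a_idx = o_idx + 1 + int(np.argmax(apg[o_idx + 1:s_idx + 1]))

        span_end = min(r1, a_idx + int(round(apg_span * fs)))
        aseg = apg[a_idx:span_end]
        if len(aseg) < 5:
            dropped.append((i, "APG span too short")); continue
        turns, kinds = _local_extrema(aseg)
        try:
            b_rel = next(t for t, k in zip(turns, kinds) if k < 0)
            c_rel = next(t for t, k in zip(turns, kinds) if k > 0 and t > b_rel)
            d_rel = next(t for t, k in zip(turns, kinds) if k < 0 and t > c_rel)
            e_rel = next(t for t, k in zip(turns, kinds) if k > 0 and t > d_rel)
        except StopIteration:
            dropped.append((i, "incomplete APG a-e sequence")); continue

        sbp_rel = int(np.argmax(signals.abp[r0:r1])) if signals.abp is not None else 0
        rows["r"].append(r0); rows["o"].append(o_idx); rows["s"].append(s_idx)
        rows["w"].append(w_idx)
        rows["a"].append(a_idx); rows["b"].append(a_idx + int(b_rel))
        rows["c"].append(a_idx + int(c_rel)); rows["d"].append(a_idx + int(d_rel))
        rows["e"].append(a_idx + int(e_rel))
        next_rs.append(r1)
        if signals.abp is not None:
            sbps.append(float(signals.abp[r0 + sbp_rel])); sbp_idxs.append(r0 + sbp_rel)
        else:
            sbps.append(np.nan); sbp_idxs.append(-1)

    if not rows["r"]:
        raise ValueError("no valid pulses")
    return FiducialSet(
        r=np.array(rows["r"]), next_r=np.array(next_rs), o=np.array(rows["o"]),
        s=np.array(rows["s"]), w=np.array(rows["w"]), a=np.array(rows["a"]),
        b=np.array(rows["b"]), c=np.array(rows["c"]), d=np.array(rows["d"]),
        e=np.array(rows["e"]), sbp=np.array(sbps), sbp_idx=np.array(sbp_idxs),
        fs=fs, dropped=dropped,
    )


def detect_sbp(abp: np.ndarray, beat_bounds) -> np.ndarray:
    """Per-beat systolic pressure: the ABP maximum within each (start, end) bound."""
    bounds = list(beat_bounds)
    if not bounds:
        raise ValueError("empty beat bounds")
    abp = np.asarray(abp, dtype=float)
    out = np.empty(len(bounds))
    for i, (lo, hi) in enumerate(bounds):
        if hi <= lo:
            raise ValueError("invalid beat bound")
        out[i] = np.max(abp[int(lo):int(hi)])
    return out


def label_segment(sbp_per_beat) -> SegmentLabel:
    """Mean SBP over beats, thresholded at 130 mmHg (boundary assigned HTS)."""
    sbp = np.asarray(sbp_per_beat, dtype=float)
    if len(sbp) == 0:
        raise ValueError("empty SBP list")
    summary = float(np.mean(sbp))
    return SegmentLabel(label=NTS if summary < SBP_THRESHOLD else HTS,
                        sbp_summary=summary)


def fiducials_to_frame(fid: FiducialSet):
    """Long-format export (beat, point, index, time_s) for plotting/debug."""
    import pandas as pd

    rows = []
    for i in range(fid.n_beats):
        for point in "roswabcde":
            idx = int(getattr(fid, point)[i])
            rows.append((i, point.upper(), idx, idx / fid.fs))
    return pd.DataFrame(rows, columns=["beat", "point", "index", "time_s"])
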