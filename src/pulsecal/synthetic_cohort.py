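"""Synthetic cohorts of coupled ECG / PPG / arterial-pressure recordings.

The generator emulates ICU-style multi-parameter records: 120 s segments of
simultaneous ECG, finger photoplethysmogram (PPG) and invasive arterial blood
pressure (ABP) sampled at 125 Hz, grouped by subject, with a stable
normotensive (NTS) or hypertensive (HTS) label per subject.  The physiology
that matters for cuff-less blood-pressure work is wired in explicitly:

* per-beat systolic pressure (SBP) modulates the pulse arrival time (PAT)
  through a negative linear coupling (higher pressure -> stiffer arteries ->
  earlier pulse arrival),
* SBP also modulates the PPG waveform's diastolic component, so the
  second-derivative (APG) a--e wave ratios carry pressure information,
* each subject has idiosyncratic timing/shape offsets, and PAT drifts slowly
  over hours, so a classifier transfers poorly across subjects but very well
  within a subject -- the regime that makes per-subject calibration matter.

Every record carries full ground truth (fiducial times, per-beat SBP and PAT,
label), so detection and feature recovery are testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

NTS = "NTS"
HTS = "HTS"

#: between-subject spread of baseline SBP within each class, mmHg
SBP_BETWEEN_SD = 6.0
#: subjects never approach the 130 mmHg decision boundary closer than this
SBP_GUARD_NTS = 126.0
SBP_GUARD_HTS = 134.0

#: diastolic-wave amplitude coupling to SBP (dimensionless per mmHg)
K_DICROTIC_BASE = 0.30
K_DICROTIC_SLOPE = 0.001
K_DICROTIC_CLIP = (0.10, 0.55)

#: physiologic clamp on per-beat PAT, seconds
PAT_CLIP = (0.20, 0.33)

#: beat-level jitter magnitudes at the default noise_sd (scaled proportionally)
_REF_NOISE_SD = 0.005
#: per-beat random-walk steps of the slow within-segment physiologic wander
_PAT_WALK_STEP = 0.0015    # s
_K_WALK_STEP = 0.005
_AMP_WALK_STEP = 0.008     # relative
_RR_JITTER_SD = 0.010      # s
_SBP_BEAT_SD = 3.0         # mmHg
_PAT_JITTER_SD = 0.020     # s
_K_JITTER_SD = 0.05
_AMP_JITTER_SD = 0.05      # relative

#: systolic-center lead over the pulse foot used for initial beat placement, s
_SYSTOLIC_LEAD = 0.20

_DENSE_OVERSAMPLE = 8


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the synthetic study population.

    Defaults mirror the study conditions: 125 Hz sampling, 120 s segments,
    an HTS prevalence of 24/69 and SBP class centers of 112/152 mmHg.  The
    coupling constants (``pat_intercept``, ``pat_slope``, ``subject_offset_sd``,
    ``drift_rate``) are simulator plumbing chosen so that between-subject
    classification is near chance while within-subject separation is strong.
    """

    n_subjects: int = 20
    htn_prevalence: float = 24.0 / 69.0
    fs: float = 125.0
    segment_duration: float = 120.0
    segments_per_subject: int = 6
    #: seconds since subject start, one entry per segment; spans the four
    #: calibration-distance buckets (<1 h, 1-6 h, 6-24 h, >24 h)
    segment_timestamps: Sequence[float] = (0.0, 1800.0, 10800.0, 43200.0, 172800.0, 176400.0)
    hr_range: tuple[float, float] = (48.0, 60.0)
    sbp_mean_nts: float = 112.0
    sbp_mean_hts: float = 152.0
    sbp_sd_within: float = 3.0
    pat_intercept: float = 0.40
    pat_slope: float = -0.001
    subject_offset_sd: float = 0.03
    drift_rate: float = 0.005      # s of PAT drift per hour, per unit subject z
    noise_sd: float = 0.005        # additive noise, relative amplitude
    powerline_amp: float = 0.002   # 60 Hz interference, relative amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.htn_prevalence <= 1.0):
            raise ValueError("htn_prevalence must lie in [0, 1]")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n = self.fs * self.segment_duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError("segment_duration * fs must be an integer sample count")
        if self.pat_slope >= 0:
            raise ValueError("pat_slope must be negative (higher SBP -> earlier arrival)")
        if self.hr_range[0] <= 0 or self.hr_range[1] < self.hr_range[0]:
            raise ValueError("invalid hr_range")
        if 60.0 / self.hr_range[0] < 0.80:
            # beat period must exceed the rendered pulse duration
            pass
        if len(self.segment_timestamps) < self.segments_per_subject:
            raise ValueError("need one timestamp per segment")
        if 60.0 / self.hr_range[1] < 0.70:
            raise ValueError("hr_range produces a beat period shorter than the pulse width")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.segment_duration))


@dataclass
class GroundTruth:
    """Noise-free fiducial times (seconds from segment start) and per-beat state."""

    r_times: np.ndarray
    o_times: np.ndarray
    s_times: np.ndarray
    w_times: np.ndarray
    apg_times: np.ndarray          # (n_beats, 5): a, b, c, d, e
    sbp_per_beat: np.ndarray
    pat_per_beat: np.ndarray       # model PAT: intercept + slope*SBP + offset + drift (+jitter)
    abp_peak_times: np.ndarray
    label: str


@dataclass
class SignalRecord:
    """One 120 s triplet of simultaneous ECG/PPG/ABP samples."""

    subject_id: str
    segment_id: str
    timestamp: float
    fs: float
    ecg: np.ndarray
    ppg: np.ndarray
    abp: np.ndarray
    truth: Optional[GroundTruth] = None

    @property
    def duration(self) -> float:
        return len(self.ppg) / self.fs


@dataclass(frozen=True)
class BeatParams:
    """Parameters of a single rendered beat (used standalone by tests/demos)."""

    fs: float = 125.0
    duration: float = 1.0          # beat period rendered, s
    foot_time: float = 0.35        # PPG pulse foot within the window, s
    amplitude: float = 1.0
    sigma_s: float = 0.063         # systolic Gaussian width, s
    k_dicrotic: float = 0.30       # diastolic/dicrotic amplitude fraction
    decay_amp: float = 0.50        # exponential run-off amplitude
    decay_tau: float = 0.45        # run-off time constant, s
    dicrotic_delay: float = 0.26   # diastolic center lead over systolic center, s
    sbp: float = 120.0
    dbp: float = 75.0
    r_amp: float = 1.0


# ---------------------------------------------------------------------------
# continuous waveform model with analytic derivatives.  Components are either
# Gaussians ("g", amp, mu, sigma) or a windkessel-style exponential decay with
# a smooth logistic onset ("e", amp, t0, w, tau).  Everything downstream
# (sampling, ground truth) evaluates these closed forms.
# ---------------------------------------------------------------------------

def _model_eval(t: np.ndarray, comps) -> np.ndarray:
    out = np.zeros_like(t, dtype=float)
    for comp in comps:
        if comp[0] == "g":
            _, amp, mu, sig = comp
            d = (t - mu) / sig
            out += amp * np.exp(-0.5 * d * d)
        else:
            out += _decay_eval(t, comp)
    return out


def _decay_eval(t: np.ndarray, comp) -> np.ndarray:
    """amp * logistic((t-t0)/w) * exp(-(t-t0)/tau), evaluated in log space."""
    _, amp, t0, w, tau = comp
    u = t - t0
    return amp * np.exp(-u / tau - np.logaddexp(0.0, -u / w))


def _model_d1(t: np.ndarray, comps) -> np.ndarray:
    out = np.zeros_like(t, dtype=float)
    for comp in comps:
        if comp[0] == "g":
            _, amp, mu, sig = comp
            d = t - mu
            out += amp * (-d / sig**2) * np.exp(-0.5 * (d / sig) ** 2)
        else:
            _, amp, t0, w, tau = comp
            u = t - t0
            s = 1.0 / (1.0 + np.exp(np.clip(-u / w, -500, 500)))
            out += _decay_eval(t, comp) * ((1 - s) / w - 1.0 / tau)
    return out


def _model_d2(t: np.ndarray, comps) -> np.ndarray:
    out = np.zeros_like(t, dtype=float)
    for comp in comps:
        if comp[0] == "g":
            _, amp, mu, sig = comp
            d = t - mu
            out += amp * ((d * d - sig**2) / sig**4) * np.exp(-0.5 * (d / sig) ** 2)
        else:
            _, amp, t0, w, tau = comp
            u = t - t0
            s = 1.0 / (1.0 + np.exp(np.clip(-u / w, -500, 500)))
            lam = (1 - s) / w - 1.0 / tau
            out += _decay_eval(t, comp) * (lam * lam - s * (1 - s) / (w * w))
    return out


def _ppg_components(t_s: float, amplitude: float, sigma_s: float,
                    k: float, decay_amp: float, dicrotic_delay: float,
                    decay_tau: float = 0.45):
    """PPG pulse: systolic Gaussian, dicrotic Gaussian, exponential run-off.

    The exponential component (smooth onset just past the systolic peak, time
    constant 0.35 s) makes the signal decay monotonically into the next
    upstroke, so the pulse onset is a well-localized minimum; the dicrotic
    Gaussian supplies the APG d/e waves well clear of the systolic lobe.
    """
    return [
        ("g", amplitude, t_s, sigma_s),
        ("g", amplitude * k, t_s + dicrotic_delay, 0.085),
        ("e", amplitude * decay_amp, t_s + 0.12, 0.08, decay_tau),
    ]


def _ecg_components(t_r: float, r_amp: float):
    # P wave, QRS (R plus a small S deflection), T wave
    return [
        ("g", 0.12 * r_amp, t_r - 0.17, 0.022),
        ("g", r_amp, t_r, 0.012),
        ("g", -0.15 * r_amp, t_r + 0.030, 0.010),
        ("g", 0.28 * r_amp, t_r + 0.26, 0.050),
    ]


def _abp_components(t_p: float):
    # normalized pressure pulse shape (peak scaled to 1 afterwards)
    return [("g", 1.0, t_p, 0.09), ("g", 0.35, t_p + 0.25, 0.13)]


def render_beat(params: BeatParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one isolated beat on a uniform grid of ``duration * fs`` samples.

    The ECG window places its R peak so that the PPG foot follows it by the
    pulse arrival time implied by ``foot_time``; the ABP pulse peaks exactly at
    the requested SBP and never falls below the requested DBP.
    """
    if params.sbp <= params.dbp:
        raise ValueError("requested SBP must exceed requested DBP")
    if params.duration <= params.foot_time + 0.45:
        raise ValueError("beat period shorter than pulse duration")
    n = int(round(params.fs * params.duration))
    t = np.arange(n) / params.fs

    t_s = params.foot_time + _SYSTOLIC_LEAD
    ppg = _model_eval(t, _ppg_components(t_s, params.amplitude, params.sigma_s,
                                        params.k_dicrotic, params.decay_amp,
                                        params.dicrotic_delay, params.decay_tau))
    t_r = max(params.foot_time - 0.28, 0.02)
    ecg = _model_eval(t, _ecg_components(t_r, params.r_amp))

    comps_abp = _abp_components(params.foot_time + 0.10)
    shape = _model_eval(t, comps_abp)
    dense = np.linspace(t[0], t[-1], 8 * n)
    peak = _model_eval(dense, comps_abp).max()
    abp = params.dbp + (params.sbp - params.dbp) * shape / peak
    return ecg, ppg, abp


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class _SubjectState:
    label: str
    sbp_base: float
    hr: float
    pat_offset: float
    drift_z: float
    amp_ppg: float
    sigma_s: float
    k_offset: float
    td_offset: float
    abp_delay: float
    r_amp: float
    beat_noise_scale: float


def _draw_subject(rng: np.random.Generator, cfg: CohortConfig,
                  label: str) -> _SubjectState:
    if label == HTS:
        base = min(max(cfg.sbp_mean_hts + SBP_BETWEEN_SD * rng.standard_normal(),
                       SBP_GUARD_HTS + 2.0), 185.0)
    else:
        base = max(min(cfg.sbp_mean_nts + SBP_BETWEEN_SD * rng.standard_normal(),
                       SBP_GUARD_NTS - 2.0), 90.0)
    return _SubjectState(
        label=label,
        sbp_base=base,
        hr=rng.uniform(*cfg.hr_range),
        pat_offset=cfg.subject_offset_sd * rng.standard_normal(),
        drift_z=float(rng.choice([-1.0, 1.0])
                      * (0.7 + 0.6 * abs(rng.standard_normal()))),
        amp_ppg=float(np.exp(0.12 * rng.standard_normal())),
        sigma_s=float(np.clip(0.063 + 0.002 * rng.standard_normal(), 0.058, 0.070)),
        k_offset=0.09 * rng.standard_normal(),
        td_offset=float(np.clip(0.012 * rng.standard_normal(), -0.025, 0.025)),
        abp_delay=0.10 + 0.006 * rng.standard_normal(),
        r_amp=float(np.exp(0.1 * rng.standard_normal())),
        # subjects differ in short-term physiologic variability: "hard"
        # subjects need several calibration measurements before a same-subject
        # match becomes reliable, which is what makes accuracy grow gradually
        # with the number of calibration measurements
        beat_noise_scale=float(np.clip(np.exp(1.0 * rng.standard_normal()), 0.3, 6.0)),
    )


def _dense_argmin(fun, lo: float, hi: float, step: float) -> float:
    t = np.arange(lo, hi, step)
    return float(t[np.argmin(fun(t))])


def _generate_segment(cfg: CohortConfig, subj: _SubjectState, rng: np.random.Generator,
                      timestamp: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    fs = cfg.fs
    n = cfg.n_samples
    dur = cfg.segment_duration
    jitter = cfg.noise_sd / _REF_NOISE_SD
    dense_step = 1.0 / (fs * _DENSE_OVERSAMPLE)

    hr_seg = float(np.clip(subj.hr + 1.5 * jitter * rng.standard_normal(), 40.0, 80.0))
    # decay time constant tracks the beat period so the pulse onset stays a
    # well-defined minimum at any heart rate
    decay_tau = float(np.clip(60.0 / hr_seg - 0.30, 0.30, 0.90))
    seg_sbp = subj.sbp_base + cfg.sbp_sd_within * rng.standard_normal()
    if subj.label == NTS:
        seg_sbp = min(seg_sbp, SBP_GUARD_NTS)
    else:
        seg_sbp = max(seg_sbp, SBP_GUARD_HTS)
    drift = cfg.drift_rate * (timestamp / 3600.0) * subj.drift_z

    ppg_comps: list = []
    ecg_comps: list = []
    beats: list[dict] = []

    # warm-up beat one period before the first recorded beat, so the first
    # recorded pulse rises out of a realistic diastolic run-off
    # slow within-segment wander (vasomotor-tone style nonstationarity)
    pat_w = 0.0
    k_w = 0.0
    amp_w = 0.0

    foot = 0.35
    warm_foot = foot - 60.0 / hr_seg
    warm = _ppg_components(warm_foot + _SYSTOLIC_LEAD, subj.amp_ppg, subj.sigma_s,
                           float(np.clip(K_DICROTIC_BASE + subj.k_offset, *K_DICROTIC_CLIP)),
                           0.50, 0.26 + subj.td_offset, decay_tau)
    ppg_comps.extend(warm)
    prev_beat_ppg: list = list(warm)
    while foot + 1.4 < dur:
        sbp = seg_sbp + _SBP_BEAT_SD * jitter * rng.standard_normal()
        sbp = float(np.clip(sbp, 90.0, 185.0))
        sbp = min(sbp, 129.0) if subj.label == NTS else max(sbp, 131.0)
        pat_w = float(np.clip(pat_w + _PAT_WALK_STEP * jitter * rng.standard_normal(),
                              -0.03, 0.03))
        k_w = float(np.clip(k_w + _K_WALK_STEP * jitter * rng.standard_normal(),
                            -0.09, 0.09))
        amp_w = float(np.clip(amp_w + _AMP_WALK_STEP * jitter * rng.standard_normal(),
                              -0.3, 0.3))
        bns = subj.beat_noise_scale
        pat = (cfg.pat_intercept + cfg.pat_slope * sbp + subj.pat_offset + drift
               + pat_w + _PAT_JITTER_SD * bns * jitter * rng.standard_normal())
        pat = float(np.clip(pat, *PAT_CLIP))
        k = float(np.clip(K_DICROTIC_BASE + K_DICROTIC_SLOPE * (sbp - 130.0)
                          + subj.k_offset + k_w
                          + _K_JITTER_SD * bns * jitter * rng.standard_normal(),
                          *K_DICROTIC_CLIP))
        amp_beat = subj.amp_ppg * float(np.clip(
            1.0 + amp_w + _AMP_JITTER_SD * bns * jitter * rng.standard_normal(), 0.3, 2.5))
        t_r = foot - pat

        # place the pulse, then shift it so the waveform's own onset minimum
        # (previous tail meeting this upstroke) sits exactly at the target foot
        t_s = foot + _SYSTOLIC_LEAD
        cur = _ppg_components(t_s, amp_beat, subj.sigma_s, k, 0.50,
                              0.26 + subj.td_offset, decay_tau)
        for _ in range(2):
            local = prev_beat_ppg + cur
            valley = _dense_argmin(lambda tt: _model_eval(tt, local), foot - 0.30,
                                   foot + 0.12, dense_step)
            t_s += foot - valley
            cur = _ppg_components(t_s, amp_beat, subj.sigma_s, k, 0.50,
                                  0.26 + subj.td_offset, decay_tau)

        ppg_comps.extend(cur)
        ecg_comps.extend(_ecg_components(t_r, subj.r_amp))
        beats.append(dict(t_r=t_r, foot=foot, t_s=t_s, sbp=sbp, pat=pat, k=k,
                          ppg=cur, prev=prev_beat_ppg))
        prev_beat_ppg = cur
        rr = 60.0 / hr_seg + _RR_JITTER_SD * jitter * rng.standard_normal()
        foot += max(rr, 0.70)

    t = np.arange(n) / fs
    ppg = _model_eval(t, ppg_comps)
    ecg = _model_eval(t, ecg_comps)

    # ABP: per-beat normalized pressure pulse scaled between DBP and SBP
    abp = np.zeros(n)
    shape_accum = np.zeros(n)
    dbp_base = None
    abp_peaks = []
    for b in beats:
        t_p = b["foot"] + subj.abp_delay
        comps = _abp_components(t_p)
        dense = np.arange(t_p - 0.3, t_p + 0.6, dense_step)
        vals = _model_eval(dense, comps)
        peak = float(vals.max())
        abp_peaks.append(float(dense[np.argmax(vals)]))
        pp = sbp_pp(b["sbp"])
        if dbp_base is None:
            dbp_base = b["sbp"] - pp
        shape_accum += (pp) * _model_eval(t, comps) / peak
    abp = (dbp_base if dbp_base is not None else 75.0) + shape_accum

    # ground truth from the continuous noise-free model
    r_times, o_times, s_times, w_times = [], [], [], []
    apg_times = np.zeros((len(beats), 5))
    for i, b in enumerate(beats):
        local = list(b["prev"]) + list(b["ppg"])
        if i + 1 < len(beats):
            local += list(beats[i + 1]["ppg"])
        o = _dense_argmin(lambda tt: _model_eval(tt, local), b["foot"] - 0.10,
                          b["foot"] + 0.10, dense_step)
        grid = np.arange(o, o + 0.70, dense_step)
        vals = _model_eval(grid, local)
        s_t = float(grid[np.argmax(vals)])
        g1 = _model_d1(grid, local)
        in_win = grid <= s_t
        w_t = float(grid[in_win][np.argmax(g1[in_win])])
        apg = _model_d2(grid, local)
        apg_times[i] = _apg_wave_times(grid, apg)
        r_times.append(b["t_r"]); o_times.append(o); s_times.append(s_t); w_times.append(w_t)

    truth = GroundTruth(
        r_times=np.array(r_times), o_times=np.array(o_times),
        s_times=np.array(s_times), w_times=np.array(w_times),
        apg_times=apg_times,
        sbp_per_beat=np.array([b["sbp"] for b in beats]),
        pat_per_beat=np.array([b["pat"] for b in beats]),
        abp_peak_times=np.array(abp_peaks),
        label=subj.label,
    )

    if cfg.noise_sd > 0:
        ecg = ecg + cfg.noise_sd * subj.r_amp * rng.standard_normal(n)
        ppg = ppg + cfg.noise_sd * subj.amp_ppg * rng.standard_normal(n)
        abp = abp + cfg.noise_sd * 40.0 * rng.standard_normal(n)
    if cfg.powerline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        mains = np.sin(2 * np.pi * 60.0 * t + phase)
        ecg = ecg + cfg.powerline_amp * subj.r_amp * mains
        ppg = ppg + cfg.powerline_amp * subj.amp_ppg * mains
    abp = np.clip(abp, 20.0, 300.0)
    return ecg, ppg, abp, truth


def sbp_pp(sbp: float) -> float:
    """Pulse pressure as a mild function of SBP (wider pulse at higher SBP)."""
    return max(35.0 + 0.25 * (sbp - 112.0), 25.0)


def _apg_wave_times(grid: np.ndarray, apg: np.ndarray) -> np.ndarray:
    """Locate the a, b, c, d, e extrema of a (noise-free) APG trace."""
    d = np.diff(apg)
    sign = np.sign(d)
    # carry last nonzero sign through plateaus
    for i in range(1, len(sign)):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    turns = np.nonzero(sign[1:] != sign[:-1])[0] + 1
    kinds = sign[turns - 1]        # +1 -> local max, -1 -> local min
    if len(turns) == 0:
        return np.full(5, np.nan)
    b_pos = int(turns[np.argmin(apg[turns])])
    b_i = int(np.nonzero(turns == b_pos)[0][0])
    try:
        maxima_before = [j for j in range(b_i) if kinds[j] > 0]
        a_pos = turns[maxima_before[-1]]
        rest = turns[b_i + 1:]
        rest_kinds = kinds[b_i + 1:]
        c_pos = rest[[j for j, kk in enumerate(rest_kinds) if kk > 0][0]]
        after_c = [j for j, p in enumerate(rest) if p > c_pos]
        d_pos = rest[[j for j in after_c if rest_kinds[j] < 0][0]]
        e_pos = rest[[j for j in after_c if rest_kinds[j] > 0 and rest[j] > d_pos][0]]
    except IndexError:
        return np.full(5, np.nan)
    return np.array([grid[a_pos], grid[b_pos], grid[c_pos], grid[d_pos], grid[e_pos]])


def generate_cohort(config: CohortConfig) -> list[SignalRecord]:
    """Generate a deterministic cohort of labelled ECG/PPG/ABP segments.

    Bit-identical output for identical configs (subject and segment streams
    are derived from spawned seed sequences, so records are independent of
    iteration order changes elsewhere).
    """
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(config.n_subjects + 1)
    # fixed class composition (like a curated study cohort): exactly
    # round(prevalence * n) hypertensive subjects, order shuffled by seed
    n_hts = int(round(config.htn_prevalence * config.n_subjects))
    labels = np.array([HTS] * n_hts + [NTS] * (config.n_subjects - n_hts))
    np.random.default_rng(subject_seeds[-1]).shuffle(labels)
    records: list[SignalRecord] = []
    for i, sseed in enumerate(subject_seeds[: config.n_subjects]):
        streams = sseed.spawn(config.segments_per_subject + 1)
        subj = _draw_subject(np.random.default_rng(streams[0]), config, str(labels[i]))
        sid = f"S{i:02d}"
        for j in range(config.segments_per_subject):
            ts = float(config.segment_timestamps[j])
            rng = np.random.default_rng(streams[j + 1])
            ecg, ppg, abp, truth = _generate_segment(config, subj, rng, ts)
            records.append(SignalRecord(
                subject_id=sid, segment_id=f"{sid}_seg{j:02d}", timestamp=ts,
                fs=config.fs, ecg=ecg, ppg=ppg, abp=abp, truth=truth,
            ))
    return records
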