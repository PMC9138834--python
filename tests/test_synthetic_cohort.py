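"""Generator contracts: determinism, coupling laws, label stability, beat anatomy."""

import numpy as np
import pytest

from pulsecal.synthetic_cohort import (BeatParams, CohortConfig, generate_cohort,
                                       render_beat)


def test_sample_count_follows_fs_and_duration(clean_record):
    assert len(clean_record.ppg) == 125 * 120
    assert len(clean_record.ecg) == len(clean_record.abp) == 15000


def test_identical_seeds_give_bit_identical_cohorts():
    cfg = CohortConfig(n_subjects=2, segments_per_subject=1, seed=7)
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    for ra, rb in zip(a, b):
        assert np.array_equal(ra.ppg, rb.ppg)
        assert np.array_equal(ra.ecg, rb.ecg)
        assert np.array_equal(ra.abp, rb.abp)
        assert np.array_equal(ra.truth.sbp_per_beat, rb.truth.sbp_per_beat)


def test_pat_is_exactly_linear_in_sbp_without_noise():
    """With all stochastic terms off, PAT = intercept + slope*SBP exactly,
    so a 30 mmHg SBP difference maps to exactly 0.030 s of PAT."""
    cfg = CohortConfig(n_subjects=6, segments_per_subject=2,
                       segment_timestamps=(0.0, 1800.0),
                       pat_slope=-0.001, noise_sd=0.0, powerline_amp=0.0,
                       subject_offset_sd=0.0, drift_rate=0.0, seed=2)
    pats, sbps = [], []
    for rec in generate_cohort(cfg):
        pats.extend(rec.truth.pat_per_beat)
        sbps.extend(rec.truth.sbp_per_beat)
    pats, sbps = np.array(pats), np.array(sbps)
    assert np.ptp(sbps) > 20           # both classes present
    resid = pats - (cfg.pat_intercept + cfg.pat_slope * sbps)
    assert np.abs(resid).max() < 1e-12
    # the stated example: 30 mmHg apart -> 0.030 s shorter
    interp = np.interp([120.0, 150.0], np.sort(sbps),
                       cfg.pat_intercept + cfg.pat_slope * np.sort(sbps))
    assert interp[0] - interp[1] == pytest.approx(0.030, abs=1e-12)


def test_pat_strictly_decreasing_in_sbp_with_noise_off():
    cfg = CohortConfig(n_subjects=8, segments_per_subject=2,
                       segment_timestamps=(0.0, 1800.0),
                       noise_sd=0.0, powerline_amp=0.0,
                       subject_offset_sd=0.0, drift_rate=0.0, seed=9)
    pats, sbps = [], []
    for rec in generate_cohort(cfg):
        pats.append(rec.truth.pat_per_beat[0])
        sbps.append(rec.truth.sbp_per_beat[0])
    order = np.argsort(sbps)
    d_sbp = np.diff(np.array(sbps)[order])
    d_pat = np.diff(np.array(pats)[order])
    assert np.all(d_pat[d_sbp > 0] < 0)


def test_labels_stable_across_all_segments_per_subject():
    cfg = CohortConfig(n_subjects=100, segments_per_subject=2,
                       segment_duration=10.0, segment_timestamps=(0.0, 3600.0),
                       seed=17)
    by_subject = {}
    for rec in generate_cohort(cfg):
        by_subject.setdefault(rec.subject_id, set()).add(rec.truth.label)
        # every beat's SBP stays on the label's side of 130 mmHg
        if rec.truth.label == "NTS":
            assert rec.truth.sbp_per_beat.max() < 130
        else:
            assert rec.truth.sbp_per_beat.min() > 130
    assert len(by_subject) == 100
    assert all(len(labels) == 1 for labels in by_subject.values())


def test_ground_truth_orderings_and_ranges(clean_cohort):
    for rec in clean_cohort:
        tr = rec.truth
        assert np.all(tr.r_times < tr.o_times)
        assert np.all(tr.o_times < tr.w_times)
        assert np.all(tr.w_times < tr.s_times)
        a, b, c, d, e = tr.apg_times.T
        assert np.all((a < b) & (b < c) & (c < d) & (d < e))
        assert rec.abp.min() >= 20 and rec.abp.max() <= 300


def test_sampling_rate_changes_counts_not_truth_times():
    base = dict(n_subjects=2, segments_per_subject=1, noise_sd=0.0,
                powerline_amp=0.0, seed=21)
    lo = generate_cohort(CohortConfig(fs=125.0, **base))
    hi = generate_cohort(CohortConfig(fs=250.0, **base))
    for a, b in zip(lo, hi):
        assert len(b.ppg) == 2 * len(a.ppg)
        n = min(len(a.truth.o_times), len(b.truth.o_times))
        assert np.abs(a.truth.o_times[:n] - b.truth.o_times[:n]).max() <= 1 / 125.0
        assert np.abs(a.truth.s_times[:n] - b.truth.s_times[:n]).max() <= 1 / 125.0


class TestRenderBeat:
    def test_single_gaussian_peaks_at_center(self):
        p = BeatParams(k_dicrotic=0.0, decay_amp=0.0, duration=1.2)
        _, ppg, _ = render_beat(p)
        t_peak = np.argmax(ppg) / p.fs
        assert t_peak == pytest.approx(p.foot_time + 0.20, abs=1.5 / p.fs)

    def test_abp_peak_equals_sbp_and_floor_above_dbp(self):
        p = BeatParams(sbp=140.0, dbp=80.0, duration=1.2)
        _, _, abp = render_beat(p)
        assert abp.max() == pytest.approx(140.0, abs=0.1)
        assert abp.min() >= 80.0 - 1e-9

    def test_apg_has_five_alternating_extrema(self):
        p = BeatParams(duration=1.4)
        _, ppg, _ = render_beat(p)
        apg = np.diff(ppg, 2)
        lo = int((p.foot_time - 0.02) * p.fs)
        hi = int((p.foot_time + 0.75) * p.fs)
        seg = apg[lo:hi]
        sign = np.sign(np.diff(seg))
        sign = sign[sign != 0]
        turns = int(np.sum(sign[1:] != sign[:-1]))
        assert turns >= 5

    def test_rejects_sbp_below_dbp(self):
        with pytest.raises(ValueError, match="SBP"):
            render_beat(BeatParams(sbp=70.0, dbp=80.0))

    def test_rejects_period_shorter_than_pulse(self):
        with pytest.raises(ValueError, match="period"):
            render_beat(BeatParams(duration=0.5, foot_time=0.35))


class TestConfigValidation:
    def test_prevalence_out_of_range(self):
        with pytest.raises(ValueError, match="prevalence"):
            CohortConfig(htn_prevalence=1.2)

    def test_non_integer_sample_count(self):
        with pytest.raises(ValueError, match="integer sample count"):
            CohortConfig(fs=125.0, segment_duration=100.0001)

    def test_positive_pat_slope_rejected(self):
        with pytest.raises(ValueError, match="pat_slope"):
            CohortConfig(pat_slope=0.001)

    def test_too_fast_heart_rate_rejected(self):
        with pytest.raises(ValueError, match="beat period"):
            CohortConfig(hr_range=(90.0, 120.0))
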