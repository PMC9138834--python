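"""The three calibration studies: none, close-in-time, and distant.

*Uncalibrated* -- leave-subject-out: a new subject's segments are classified
by a model trained exclusively on other subjects.

*Sequential (close-in-time)* -- each 120 s segment is split into twelve 10 s
sub-segments.  Training starts from all other subjects' sub-segments plus
the subject's first sub-segment (the calibration measurement); the next
sub-segment is classified, then joins the training set, and so on through
the segment, giving eleven evaluation points indexed by the number of prior
same-subject sub-segments.  The calibration pool resets at each new segment.

*Distant* -- calibration segments are grouped by their time distance to the
test segment (<1 h, 1-6 h, 6-24 h, >24 h); within a bucket, earlier segments
of the subject are added one at a time (oldest first) to the cross-subject
training set, mirroring the sequential protocol at segment granularity.

Every protocol is expressed as a fold generator yielding disjoint train/test
index sets, so leakage is auditable directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .classify_eval import ModelSpec, train_classifier
from .feature_select import zscore_fit_apply

#: calibration-to-test distance buckets, seconds: [lo, hi)
DEFAULT_BUCKETS = {
    "<1h": (0.0, 3600.0),
    "1-6h": (3600.0, 21600.0),
    "6-24h": (21600.0, 86400.0),
    ">24h": (86400.0, float("inf")),
}


@dataclass
class CalibrationCurve:
    """Accuracy distribution per number of prior same-subject measurements."""

    table: pd.DataFrame        # bucket, n_calibration, mean, median, p15, p85, n_units
    raw: pd.DataFrame          # subject_id, segment_id, bucket, n_calibration, correct


def subsegment_bounds(fs: float, duration: float = 120.0,
                      window: float = 10.0) -> list[tuple[int, int]]:
    """Contiguous non-overlapping sample windows; 120 s at 125 Hz -> 12 x 1250."""
    n_win = duration / window
    if abs(n_win - round(n_win)) > 1e-9:
        raise ValueError("segment duration must be a multiple of the window length")
    step = fs * window
    if abs(step - round(step)) > 1e-9:
        raise ValueError("window length must map to an integer sample count")
    step = int(round(step))
    return [(i * step, (i + 1) * step) for i in range(int(round(n_win)))]


def split_subsegments(beats: pd.DataFrame, fs: float, duration: float = 120.0,
                      window: float = 10.0) -> pd.DataFrame:
    """Assign each beat row to the 10 s window containing its R peak."""
    bounds = subsegment_bounds(fs, duration, window)
    step = bounds[0][1]
    out = beats.copy()
    out["subsegment"] = (out["r_index"] // step).astype(int)
    out = out[out["subsegment"] < len(bounds)]
    return out


def _predict_fold(df: pd.DataFrame, train_idx: np.ndarray, test_idx: np.ndarray,
                  spec: ModelSpec, feature_cols: list[str]) -> np.ndarray:
    assert not set(test_idx) & set(train_idx), "leakage: test unit present in training"
    X_tr, params = zscore_fit_apply(df.loc[train_idx, feature_cols])
    X_te, _ = zscore_fit_apply(df.loc[test_idx, feature_cols], params)
    model = train_classifier(X_tr.to_numpy(), df.loc[train_idx, "label"].to_numpy(), spec)
    return model.predict(X_te.to_numpy())


def uncalibrated_folds(df: pd.DataFrame) -> Iterator[tuple[np.ndarray, np.ndarray, str]]:
    for subject in sorted(df["subject_id"].unique()):
        test = df.index[df["subject_id"] == subject].to_numpy()
        train = df.index[df["subject_id"] != subject].to_numpy()
        yield train, test, subject


def eval_uncalibrated(df: pd.DataFrame, spec: ModelSpec,
                      feature_cols: list[str]) -> tuple[float, pd.Series, pd.DataFrame]:
    """Leave-subject-out accuracy: overall (unit-weighted) and per subject."""
    if df["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    rows = []
    for train, test, subject in uncalibrated_folds(df):
        if df.loc[train, "label"].nunique() < 2:
            raise ValueError(f"training side single-class for subject {subject}")
        pred = _predict_fold(df, train, test, spec, feature_cols)
        truth = df.loc[test, "label"].to_numpy()
        for unit, t, p in zip(test, truth, pred):
            rows.append((subject, unit, t, p, t == p))
    raw = pd.DataFrame(rows, columns=["subject_id", "unit", "truth", "prediction",
                                      "correct"])
    per_subject = raw.groupby("subject_id")["correct"].mean()
    return float(raw["correct"].mean()), per_subject, raw


def sequential_folds(df: pd.DataFrame, reset_per_segment: bool = True,
                     self_calibration: bool = True
                     ) -> Iterator[tuple[np.ndarray, np.ndarray, dict]]:
    """Folds of the close-in-time protocol over a sub-segment feature table.

    With ``self_calibration=False`` the subject's own sub-segments never enter
    the training set, and every sub-segment is tested: the protocol then
    degenerates to the uncalibrated leave-subject-out evaluation.
    """
    for subject in sorted(df["subject_id"].unique()):
        others = df.index[df["subject_id"] != subject].to_numpy()
        own = df[df["subject_id"] == subject]
        carried: list[int] = []
        for segment in sorted(own["segment_id"].unique()):
            seg = own[own["segment_id"] == segment].sort_values("subsegment")
            idx = seg.index.to_numpy()
            if not self_calibration:
                for j in range(len(idx)):
                    yield others, np.array([idx[j]]), {
                        "subject_id": subject, "segment_id": segment,
                        "n_calibration": 0,
                    }
                continue
            if len(idx) < 2:
                continue
            pool = [] if reset_per_segment else list(carried)
            for j in range(len(idx) - 1):
                pool_now = pool + list(idx[: j + 1])
                train = np.concatenate([others, np.array(pool_now, dtype=others.dtype)])
                yield train, np.array([idx[j + 1]]), {
                    "subject_id": subject, "segment_id": segment,
                    "n_calibration": j + 1 + len(pool),
                }
            carried.extend(idx)


def _summarize(raw: pd.DataFrame) -> pd.DataFrame:
    """Fig-style box summary: mean/median and 15th/85th percentiles over subjects."""
    per_subj = (raw.groupby(["bucket", "n_calibration", "subject_id"])["correct"]
                .mean().reset_index())
    rows = []
    for (bucket, n), grp in per_subj.groupby(["bucket", "n_calibration"]):
        acc = grp["correct"].to_numpy()
        rows.append((bucket, int(n), float(acc.mean()), float(np.median(acc)),
                     float(np.percentile(acc, 15)), float(np.percentile(acc, 85)),
                     len(acc)))
    return pd.DataFrame(rows, columns=["bucket", "n_calibration", "mean", "median",
                                       "p15", "p85", "n_units"])


def eval_sequential_calibration(df: pd.DataFrame, spec: ModelSpec,
                                feature_cols: list[str],
                                reset_per_segment: bool = True) -> CalibrationCurve:
    """Accuracy as a function of prior close-in-time sub-segments (bucket 'none')."""
    if df.groupby("segment_id")["subsegment"].count().max() < 2:
        raise ValueError("need at least 2 sub-segments per segment")
    rows = []
    for train, test, meta in sequential_folds(df, reset_per_segment):
        pred = _predict_fold(df, train, test, spec, feature_cols)
        truth = df.loc[test[0], "label"]
        rows.append((meta["subject_id"], meta["segment_id"], "none",
                     meta["n_calibration"], truth == pred[0]))
    raw = pd.DataFrame(rows, columns=["subject_id", "segment_id", "bucket",
                                      "n_calibration", "correct"])
    return CalibrationCurve(table=_summarize(raw), raw=raw)


def distant_folds(df: pd.DataFrame, buckets: dict[str, tuple[float, float]]
                  ) -> Iterator[tuple[np.ndarray, np.ndarray, dict]]:
    """Folds of the distant-calibration protocol over a segment feature table."""
    for subject in sorted(df["subject_id"].unique()):
        others = df.index[df["subject_id"] != subject].to_numpy()
        own = df[df["subject_id"] == subject].sort_values("timestamp")
        idx = own.index.to_numpy()
        ts = own["timestamp"].to_numpy()
        for t_pos in range(1, len(idx)):
            for bucket, (lo, hi) in buckets.items():
                dist = ts[t_pos] - ts[:t_pos]
                cands = idx[:t_pos][(dist >= lo) & (dist < hi)]
                for m in range(1, len(cands) + 1):
                    train = np.concatenate([others, cands[:m]])
                    yield train, np.array([idx[t_pos]]), {
                        "subject_id": subject, "segment_id": own.loc[idx[t_pos],
                                                                     "segment_id"],
                        "bucket": bucket, "n_calibration": m,
                    }


def eval_distant_calibration(df: pd.DataFrame, spec: ModelSpec,
                             feature_cols: list[str],
                             buckets: dict[str, tuple[float, float]] | None = None
                             ) -> CalibrationCurve:
    """Per-bucket calibration curves at segment granularity."""
    buckets = dict(buckets or DEFAULT_BUCKETS)
    rows = []
    for train, test, meta in distant_folds(df, buckets):
        pred = _predict_fold(df, train, test, spec, feature_cols)
        truth = df.loc[test[0], "label"]
        rows.append((meta["subject_id"], meta["segment_id"], meta["bucket"],
                     meta["n_calibration"], truth == pred[0]))
    raw = pd.DataFrame(rows, columns=["subject_id", "segment_id", "bucket",
                                      "n_calibration", "correct"])
    for bucket in buckets:
        if bucket not in set(raw["bucket"]):
            warnings.warn(f"bucket {bucket!r} has no segment pairs; curve omitted",
                          stacklevel=2)
    return CalibrationCurve(table=_summarize(raw), raw=raw)
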