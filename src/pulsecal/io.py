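"""Reading and writing signal records as plain CSV plus a JSON sidecar.

A record is stored as ``<name>.csv`` with columns t, ecg, ppg, abp and a
sidecar ``<name>.json`` carrying subject id, timestamp, sampling rate and --
for synthetic records -- the full ground truth.  The ABP column may be
absent (cuff-less scenario); such records load in degraded mode with
transit-time features disabled downstream.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synthetic_cohort import GroundTruth, SignalRecord


def write_record_csv(record: SignalRecord, path: str | Path) -> Path:
    path = Path(path)
    t = np.arange(len(record.ppg)) / record.fs
    cols = {"t": t, "ecg": record.ecg, "ppg": record.ppg}
    if record.abp is not None:
        cols["abp"] = record.abp
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")
    meta = {
        "subject_id": record.subject_id,
        "segment_id": record.segment_id,
        "timestamp": record.timestamp,
        "fs": record.fs,
    }
    if record.truth is not None:
        tr = record.truth
        meta["truth"] = {
            "r_times": tr.r_times.tolist(), "o_times": tr.o_times.tolist(),
            "s_times": tr.s_times.tolist(), "w_times": tr.w_times.tolist(),
            "apg_times": tr.apg_times.tolist(),
            "sbp_per_beat": tr.sbp_per_beat.tolist(),
            "pat_per_beat": tr.pat_per_beat.tolist(),
            "abp_peak_times": tr.abp_peak_times.tolist(),
            "label": tr.label,
        }
    path.with_suffix(".json").write_text(json.dumps(meta))
    return path


def read_record(path: str | Path, format: str = "csv",
                target_fs: float | None = None,
                allow_resample: bool = False) -> SignalRecord:
    """Load a record; only the CSV layout is supported as an on-disk format."""
    if format != "csv":
        raise ValueError(f"unsupported record format {format!r}; use 'csv'")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    for col in ("t", "ecg", "ppg"):
        if col not in df.columns:
            raise ValueError(f"record is missing required signal column {col!r}")
    dt = np.diff(df["t"].to_numpy())
    if len(dt) < 1 or np.ptp(dt) > 1e-6:
        raise ValueError("unparseable time base: non-uniform sampling")
    fs = 1.0 / float(np.mean(dt))

    meta = {}
    side = path.with_suffix(".json")
    if side.exists():
        meta = json.loads(side.read_text())
        fs = float(meta.get("fs", fs))

    ecg = df["ecg"].to_numpy(dtype=float)
    ppg = df["ppg"].to_numpy(dtype=float)
    abp = df["abp"].to_numpy(dtype=float) if "abp" in df.columns else None
    if abp is None:
        warnings.warn("record has no ABP channel; transit-time features disabled",
                      stacklevel=2)

    if target_fs is not None and abs(fs - target_fs) > 1e-6:
        if not allow_resample:
            raise ValueError(f"record sampled at {fs:g} Hz, expected {target_fs:g} Hz "
                             "(resampling disabled)")
        up, down = (np.round([target_fs, fs]) .astype(int))
        ecg = sps.resample_poly(ecg, up, down)
        ppg = sps.resample_poly(ppg, up, down)
        abp = sps.resample_poly(abp, up, down) if abp is not None else None
        fs = float(target_fs)

    truth = None
    if "truth" in meta:
        tr = meta["truth"]
        truth = GroundTruth(
            r_times=np.array(tr["r_times"]), o_times=np.array(tr["o_times"]),
            s_times=np.array(tr["s_times"]), w_times=np.array(tr["w_times"]),
            apg_times=np.array(tr["apg_times"]),
            sbp_per_beat=np.array(tr["sbp_per_beat"]),
            pat_per_beat=np.array(tr["pat_per_beat"]),
            abp_peak_times=np.array(tr["abp_peak_times"]),
            label=tr["label"],
        )
    return SignalRecord(
        subject_id=str(meta.get("subject_id", path.stem)),
        segment_id=str(meta.get("segment_id", path.stem)),
        timestamp=float(meta.get("timestamp", 0.0)),
        fs=fs, ecg=ecg, ppg=ppg, abp=abp, truth=truth,
    )
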