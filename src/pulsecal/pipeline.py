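"""End-to-end orchestration: simulate -> preprocess -> fiducials -> features
-> select -> evaluate -> calibration curves.

`ExperimentConfig` is the declarative description of a full experiment; it
round-trips losslessly through YAML and rejects unknown keys.  Stage outputs
are written under an output directory together with a manifest keyed by the
config hash, so a stale mix of outputs from different configs is detected
rather than silently reused.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration_protocols as calib
from .classify_eval import ModelSpec, loo_segment_cv
from .feature_extract import (FEATURE_NAMES, SegmentRejected, aggregate_features,
                              beats_to_frame)
from .feature_select import (correlation_screen, relieff_rank, select_features,
                             zscore_fit_apply)
from .fiducial_detect import detect_ppg_fiducials, detect_r_peaks, label_segment
from .signal_preprocess import preprocess_record, quality_gate
from .synthetic_cohort import CohortConfig, SignalRecord, generate_cohort

log = logging.getLogger("pulsecal")


class StaleCacheError(RuntimeError):
    """Upstream stage output was produced under a different configuration."""


@dataclass
class ExperimentConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    include_ptt: bool = True
    relieff_k: int = 10
    corr_threshold: float = 0.95
    policy: str = "paper_fixed"          # paper_fixed | data_driven
    leaky_selection: bool = False
    model: ModelSpec = field(default_factory=ModelSpec)
    compare_models: tuple[str, ...] = ("knn", "svm", "bagging")
    run_sequential: bool = True
    run_distant: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["segment_timestamps"] = list(self.cohort.segment_timestamps)
        d["cohort"]["hr_range"] = list(self.cohort.hr_range)
        d["compare_models"] = list(self.compare_models)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cohort" in d and isinstance(d["cohort"], dict):
            ck = {f.name for f in dataclasses.fields(CohortConfig)}
            bad = set(d["cohort"]) - ck
            if bad:
                raise ValueError(f"unknown cohort keys: {sorted(bad)}")
            c = dict(d["cohort"])
            if "segment_timestamps" in c:
                c["segment_timestamps"] = tuple(c["segment_timestamps"])
            if "hr_range" in c:
                c["hr_range"] = tuple(c["hr_range"])
            d["cohort"] = CohortConfig(**c)
        if "model" in d and isinstance(d["model"], dict):
            d["model"] = ModelSpec(**d["model"])
        if "compare_models" in d:
            d["compare_models"] = tuple(d["compare_models"])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def selected_feature_columns(config: ExperimentConfig) -> list[str]:
    names = list(FEATURE_NAMES)
    if not config.include_ptt:
        names.remove("ptt")
    return names


def extract_features(records: list[SignalRecord], include_ptt: bool = True,
                     subsegment: bool = False, min_beats: int = 3,
                     skip_quality: bool = False) -> pd.DataFrame:
    """Run the signal pipeline on each record and build the feature matrix.

    One row per segment (or per 10 s sub-segment).  Records failing the
    quality gate and (sub-)segments with too few usable beats are skipped
    and logged.
    """
    rows = []
    for rec in records:
        proc = preprocess_record(rec)
        if not skip_quality:
            ok, reasons = quality_gate(rec, proc)
            if not ok:
                log.warning("record %s rejected: %s", rec.segment_id, reasons)
                continue
        r_peaks = detect_r_peaks(proc.ecg_f, rec.fs)
        if len(r_peaks) < 3:
            log.warning("record %s: too few R peaks", rec.segment_id)
            continue
        try:
            fid = detect_ppg_fiducials(proc, r_peaks)
        except ValueError as exc:
            log.warning("record %s: %s", rec.segment_id, exc)
            continue
        beats = beats_to_frame(proc, fid, include_ptt=include_ptt)
        lab = label_segment(fid.sbp[np.isfinite(fid.sbp)]) if np.isfinite(fid.sbp).any() else None
        base = {
            "subject_id": rec.subject_id, "segment_id": rec.segment_id,
            "timestamp": rec.timestamp,
            "label": lab.label if lab is not None else (rec.truth.label if rec.truth else None),
            "sbp_summary": lab.sbp_summary if lab is not None else np.nan,
        }
        if not subsegment:
            try:
                agg, n_used = aggregate_features(beats, min_beats)
            except SegmentRejected as exc:
                log.warning("segment %s rejected: %s", rec.segment_id, exc)
                continue
            rows.append(base | agg | {"n_beats": n_used})
        else:
            tagged = calib.split_subsegments(beats, rec.fs, rec.duration)
            for wi, grp in tagged.groupby("subsegment"):
                try:
                    agg, n_used = aggregate_features(grp, min_beats)
                except SegmentRejected:
                    log.warning("sub-segment %s/%d rejected", rec.segment_id, wi)
                    continue
                sub_lab = label_segment(grp["sbp_beat"].dropna()) if grp["sbp_beat"].notna().any() else None
                rows.append(base | agg | {
                    "subsegment": int(wi),
                    "timestamp": rec.timestamp + wi * 10.0,
                    "label": sub_lab.label if sub_lab is not None else base["label"],
                    "n_beats": n_used,
                })
    df = pd.DataFrame(rows)
    if len(df):
        if not include_ptt and "ptt" in df.columns:
            df = df.drop(columns=["ptt"])
        present = [c for c in FEATURE_NAMES if c in df.columns]
        bad = df[present].isna().any(axis=1)
        if bad.any():
            log.warning("dropping %d (sub-)segments with incomplete features",
                        int(bad.sum()))
            df = df[~bad]
        df = df.reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# staged runner with config-hash manifests
# ---------------------------------------------------------------------------

def _write_manifest(outdir: Path, stage: str, cfg_hash: str) -> None:
    (outdir / f"{stage}.manifest.json").write_text(
        json.dumps({"stage": stage, "config_hash": cfg_hash}))


def check_manifest(outdir: Path, stage: str, cfg_hash: str) -> None:
    p = outdir / f"{stage}.manifest.json"
    if not p.exists():
        raise StaleCacheError(f"stage {stage!r} has not been run for this config")
    found = json.loads(p.read_text())["config_hash"]
    if found != cfg_hash:
        raise StaleCacheError(
            f"stage {stage!r} output was produced under config {found}, "
            f"current config is {cfg_hash}; re-run the stage")


def run(config: ExperimentConfig, outdir: str | Path) -> dict:
    """Run the full experiment and write every declared output file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    config.to_yaml(outdir / "config.yaml")
    bundle: dict = {"config_hash": h}

    log.info("[%s] simulate: %d subjects x %d segments", h,
             config.cohort.n_subjects, config.cohort.segments_per_subject)
    records = generate_cohort(config.cohort)

    seg_df = extract_features(records, include_ptt=config.include_ptt)
    sub_df = extract_features(records, include_ptt=config.include_ptt, subsegment=True)
    seg_df.to_csv(outdir / "features_segments.csv", index=False)
    sub_df.to_csv(outdir / "features_subsegments.csv", index=False)
    _write_manifest(outdir, "features", h)

    feature_cols = selected_feature_columns(config)
    Xn, _ = zscore_fit_apply(seg_df[feature_cols])
    weights = relieff_rank(Xn, seg_df["label"].to_numpy(),
                           k=min(config.relieff_k,
                                 seg_df["label"].value_counts().min() - 1))
    corr = correlation_screen(Xn)
    report = select_features(weights, corr, policy=config.policy,
                             corr_threshold=config.corr_threshold,
                             feature_names=feature_cols)
    (outdir / "selection.json").write_text(json.dumps(report.to_dict(), indent=2,
                                                      sort_keys=True))
    corr.to_csv(outdir / "correlation.csv")
    _write_manifest(outdir, "select", h)
    kept = report.kept
    bundle["selection"] = report

    metrics = {}
    for kind in config.compare_models:
        spec = dataclasses.replace(config.model, kind=kind, seed=config.seed)
        m, preds, counts = loo_segment_cv(seg_df, spec, kept,
                                          leaky_normalization=config.leaky_selection)
        metrics[kind] = {"acc": m.acc, "se": m.se, "sp": m.sp, "f1": m.f1,
                         "tp": counts.tp, "tn": counts.tn, "fp": counts.fp,
                         "fn": counts.fn}
        preds.to_csv(outdir / f"predictions_{kind}.csv", index=False)
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    _write_manifest(outdir, "evaluate", h)
    bundle["metrics"] = metrics

    spec = dataclasses.replace(config.model, seed=config.seed)
    overall, per_subject, raw = calib.eval_uncalibrated(seg_df, spec, kept)
    per_subject.to_csv(outdir / "uncalibrated_per_subject.csv")
    bundle["uncalibrated_accuracy"] = overall

    if config.run_sequential:
        curve = calib.eval_sequential_calibration(sub_df, spec, kept)
        curve.table.to_csv(outdir / "calibration_sequential.csv", index=False)
        bundle["sequential"] = curve
    if config.run_distant:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dcurve = calib.eval_distant_calibration(seg_df, spec, kept)
        dcurve.table.to_csv(outdir / "calibration_distant.csv", index=False)
        bundle["distant"] = dcurve
    _write_manifest(outdir, "calibrate", h)

    summary = {
        "config_hash": h,
        "n_segments": int(len(seg_df)),
        "n_subsegments": int(len(sub_df)),
        "uncalibrated_accuracy": overall,
        "metrics": metrics,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    bundle["summary"] = summary
    return bundle
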