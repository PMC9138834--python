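import logging
import warnings

import numpy as np
import pytest

from pulsecal.synthetic_cohort import CohortConfig, generate_cohort
from pulsecal.signal_preprocess import preprocess_record

logging.getLogger("pulsecal").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def clean_cohort():
    """Small noise-free cohort with full ground truth (4 subjects x 1 segment)."""
    cfg = CohortConfig(n_subjects=4, segments_per_subject=1,
                       noise_sd=0.0, powerline_amp=0.0, seed=3)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_record(clean_cohort):
    return clean_cohort[0]


@pytest.fixture(scope="session")
def clean_processed(clean_record):
    return preprocess_record(clean_record)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default-condition cohort at reduced scale (6 subjects x 2 segments)."""
    cfg = CohortConfig(n_subjects=6, segments_per_subject=2,
                       segment_timestamps=(0.0, 1800.0), seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def segment_features(noisy_cohort):
    from pulsecal.pipeline import extract_features

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return extract_features(noisy_cohort)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_feature_table(n_subjects=6, segments=2, subsegs=12, n_features=3,
                       timestamps=(0.0, 1800.0), seed=0, separation=3.0):
    """Random sub-segment-level feature table for protocol tests (no signals)."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        label = "HTS" if i % 2 else "NTS"
        center = rng.normal(0, 1, n_features) + (separation if label == "HTS" else 0.0)
        for j in range(segments):
            for w in range(subsegs):
                feats = center + 0.3 * rng.normal(0, 1, n_features)
                rows.append({
                    "subject_id": f"S{i:02d}", "segment_id": f"S{i:02d}_seg{j:02d}",
                    "subsegment": w, "timestamp": timestamps[j % len(timestamps)] + 10.0 * w,
                    "label": label,
                    **{f"f{k}": feats[k] for k in range(n_features)},
                })
    return pd.DataFrame(rows)
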