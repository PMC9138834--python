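"""Metric formulas (with independent recount oracle), models, segment-wise LOO."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import accuracy_score, f1_score, recall_score

from pulsecal.classify_eval import (ConfusionCounts, ModelSpec, confusion_metrics,
                                    counts_from_predictions, implied_f1,
                                    loo_segment_cv, train_classifier)


class TestConfusionMetrics:
    def test_symmetric_counts_give_half_everywhere(self):
        m = confusion_metrics(ConfusionCounts(tp=25, tn=25, fp=25, fn=25))
        assert (m.acc, m.se, m.sp, m.f1) == (0.5, 0.5, 0.5, 0.5)

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(tp=50, tn=50))
        assert (m.acc, m.se, m.sp, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_worked_example(self):
        m = confusion_metrics(ConfusionCounts(tp=240, fn=20, tn=480, fp=30))
        assert m.acc == pytest.approx(0.9351, abs=5e-5)
        assert m.se == pytest.approx(0.9231, abs=5e-5)
        assert m.sp == pytest.approx(0.9412, abs=5e-5)
        assert m.f1 == pytest.approx(0.9057, abs=5e-5)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionCounts())

    def test_matches_recount_oracle_on_random_pairs(self, rng):
        labels = np.array(["NTS", "HTS"])
        for _ in range(200):
            y_true = labels[rng.integers(0, 2, 40)]
            y_pred = labels[rng.integers(0, 2, 40)]
            m = confusion_metrics(counts_from_predictions(y_true, y_pred))
            assert m.acc == pytest.approx(accuracy_score(y_true, y_pred))
            assert m.se == pytest.approx(
                recall_score(y_true, y_pred, pos_label="HTS", zero_division=np.nan),
                nan_ok=True)
            assert m.sp == pytest.approx(
                recall_score(y_true, y_pred, pos_label="NTS", zero_division=np.nan),
                nan_ok=True)
            assert m.f1 == pytest.approx(
                f1_score(y_true, y_pred, pos_label="HTS", zero_division=np.nan),
                nan_ok=True)


class TestImpliedF1:
    def test_consistency_with_count_based_f1(self, rng):
        """Count-form F1 equals the harmonic mean of precision and recall
        reconstructed from (Acc, Se, Sp) wherever prevalence is identified."""
        for _ in range(300):
            c = ConfusionCounts(*rng.integers(1, 200, 4))
            m = confusion_metrics(c)
            if abs(m.se - m.sp) < 1e-9:
                continue
            pi, precision, f1 = implied_f1(m.acc, m.se, m.sp)
            assert pi == pytest.approx((c.tp + c.fn) / c.total, rel=1e-9)
            assert f1 == pytest.approx(m.f1, rel=1e-9)

    def test_published_style_row(self):
        _, _, f1 = implied_f1(0.9069, 0.8297, 0.9581)
        assert f1 == pytest.approx(0.8768, abs=1e-3)

    def test_perfect_inputs(self):
        pi, precision, f1 = implied_f1(1.0, 1.0, 1.0)
        assert np.isnan(pi) and precision == 1.0 and f1 == 1.0

    def test_se_equals_sp_rejected(self):
        with pytest.raises(ValueError, match="indeterminate"):
            implied_f1(0.8, 0.7, 0.7)

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(ValueError, match="prevalence"):
            implied_f1(0.99, 0.5, 0.6)


def _clouds(rng, n=200, d=17, sep=3.0):
    # per-dimension center separation of `sep` standard deviations
    y = np.array(["NTS", "HTS"])[rng.integers(0, 2, n)]
    X = rng.standard_normal((n, d))
    X[y == "HTS"] += sep
    return X, y


class TestTrainClassifier:
    def test_knn_k1_memorizes_training_rows(self, rng):
        X, y = _clouds(rng, n=40)
        model = train_classifier(X, y, ModelSpec(kind="knn", k=1))
        assert (model.predict(X) == y).all()

    @pytest.mark.parametrize("kind", ["knn", "svm", "bagging"])
    def test_separated_clouds_classified_above_99pct(self, kind):
        rng = np.random.default_rng(7)
        X, y = _clouds(rng, n=400)
        model = train_classifier(X[:200], y[:200], ModelSpec(kind=kind, seed=1))
        assert np.mean(model.predict(X[200:]) == y[200:]) >= 0.99

    def test_bagging_deterministic_given_seed(self, rng):
        X, y = _clouds(rng, n=100, sep=1.0)
        spec = ModelSpec(kind="bagging", seed=5)
        p1 = train_classifier(X, y, spec).predict(X)
        p2 = train_classifier(X, y, spec).predict(X)
        assert (p1 == p2).all()

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            train_classifier(np.zeros((5, 2)), np.array(["NTS"] * 5),
                             ModelSpec(kind="knn"))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(kind="forest")


def _frame(features, labels, subjects=None):
    n = len(labels)
    return pd.DataFrame({
        "segment_id": [f"seg{i}" for i in range(n)],
        "subject_id": subjects or [f"P{i}" for i in range(n)],
        "label": labels,
        "x": features,
    })


class TestLooSegmentCV:
    def test_label_copy_feature_gives_perfect_accuracy(self):
        labels = ["NTS", "HTS"] * 6
        df = _frame([0.0 if l == "NTS" else 1.0 for l in labels], labels)
        m, preds, counts = loo_segment_cv(df, ModelSpec(kind="knn", k=1), ["x"])
        assert m.acc == 1.0
        assert len(preds) == len(df)

    def test_four_segment_nearest_neighbor_case(self):
        df = _frame([0.0, 0.1, 1.0, 1.1], ["NTS", "NTS", "HTS", "HTS"])
        m, preds, _ = loo_segment_cv(df, ModelSpec(kind="knn", k=1), ["x"])
        assert m.acc == 1.0           # each fold's nearest neighbor shares its class

    def test_balanced_shuffled_labels_score_near_chance(self, segment_features):
        df = segment_features.copy().reset_index(drop=True)
        rng = np.random.default_rng(3)
        half = len(df) // 2
        labels = np.array(["NTS"] * half + ["HTS"] * (len(df) - half))
        rng.shuffle(labels)
        df["label"] = labels
        from pulsecal.feature_select import PAPER_DROP_CORRELATION, PAPER_DROP_RANK
        from pulsecal.feature_extract import FEATURE_NAMES
        kept = [f for f in FEATURE_NAMES
                if f not in PAPER_DROP_CORRELATION + PAPER_DROP_RANK]
        m, _, _ = loo_segment_cv(df, ModelSpec(kind="knn", k=1), kept)
        assert 0.3 <= m.acc <= 0.7

    def test_fold_count_equals_segments(self, segment_features):
        from pulsecal.feature_select import PAPER_DROP_CORRELATION, PAPER_DROP_RANK
        from pulsecal.feature_extract import FEATURE_NAMES
        kept = [f for f in FEATURE_NAMES
                if f not in PAPER_DROP_CORRELATION + PAPER_DROP_RANK]
        m, preds, _ = loo_segment_cv(segment_features, ModelSpec(kind="knn"), kept)
        assert len(preds) + len(preds.attrs["skipped_folds"]) == len(segment_features)

    def test_too_few_segments_rejected(self):
        df = _frame([0.0], ["NTS"])
        with pytest.raises(ValueError):
            loo_segment_cv(df, ModelSpec(), ["x"])
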