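"""Classifiers, the segment-wise leave-one-out evaluation and its metrics.

Three model families are supported: k-nearest neighbors (default k = 1 --
nearest-neighbor memorization, the behavior that makes per-subject
calibration effective), an RBF support vector machine with the kernel
bandwidth set by the median pairwise-distance heuristic, and a bagged
ensemble of 30 decision trees.  HTS (hypertensive) is the positive class
throughout; KNN voting ties resolve toward NTS, the non-alarm class.

Metrics follow the usual confusion-count definitions: Acc = (TP+TN)/total,
Se = TP/(TP+FN), Sp = TN/(TN+FP), F1 = 2TP/(2TP+FP+FN).  ``implied_f1``
inverts (Acc, Se, Sp) into the prevalence and precision they jointly imply,
a consistency check for published metric tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .feature_select import zscore_fit_apply

NTS = "NTS"
HTS = "HTS"


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass
class MetricSet:
    acc: float
    se: float
    sp: float
    f1: float


@dataclass
class ModelSpec:
    kind: str = "knn"                  # knn | svm | bagging
    k: int = 1
    metric: str = "euclidean"
    C: float = 1.0
    n_estimators: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("knn", "svm", "bagging"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")


def counts_from_predictions(y_true, y_pred) -> ConfusionCounts:
    c = ConfusionCounts()
    for t, p in zip(y_true, y_pred):
        if t == HTS:
            if p == HTS:
                c.tp += 1
            else:
                c.fn += 1
        else:
            if p == NTS:
                c.tn += 1
            else:
                c.fp += 1
    return c


def confusion_metrics(c: ConfusionCounts) -> MetricSet:
    """Acc/Se/Sp/F1 from counts; undefined ratios are NaN."""
    if c.total <= 0:
        raise ValueError("empty confusion counts")

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return MetricSet(
        acc=ratio(c.tp + c.tn, c.total),
        se=ratio(c.tp, c.tp + c.fn),
        sp=ratio(c.tn, c.tn + c.fp),
        f1=ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    )


def implied_f1(acc: float, se: float, sp: float,
               tol: float = 1e-9) -> tuple[float, float, float]:
    """Prevalence, precision and F1 implied by (Acc, Se, Sp).

    Solves acc = pi*se + (1-pi)*sp for the positive-class prevalence pi, then
    precision = pi*se / (pi*se + (1-pi)*(1-sp)) and F1 as the harmonic mean
    of precision and sensitivity.  With se = sp the prevalence is
    indeterminate; the perfect case (se = sp = acc = 1) still yields
    precision 1 and F1 1 with prevalence NaN.
    """
    if abs(se - sp) < tol:
        if abs(sp - 1.0) < tol and abs(acc - 1.0) < tol:
            return (float("nan"), 1.0, 2.0 * se / (se + 1.0))
        raise ValueError("prevalence indeterminate: se = sp")
    pi = (acc - sp) / (se - sp)
    if pi < -tol or pi > 1.0 + tol:
        raise ValueError(f"inconsistent inputs: implied prevalence {pi:.4f} outside [0, 1]")
    pi = min(max(pi, 0.0), 1.0)
    den = pi * se + (1.0 - pi) * (1.0 - sp)
    precision = pi * se / den if den > 0 else float("nan")
    f1 = (2.0 * precision * se / (precision + se)
          if np.isfinite(precision) and precision + se > 0 else float("nan"))
    return (pi, precision, f1)


class _TieAwareKNN:
    """KNN that resolves voting ties toward the non-alarm (NTS) class."""

    def __init__(self, k: int, metric: str):
        self._knn = KNeighborsClassifier(n_neighbors=k, metric=metric)
        self.ties_ = 0

    def fit(self, X, y):
        self._knn.fit(np.asarray(X, dtype=float), np.asarray(y))
        return self

    def predict(self, X):
        proba = self._knn.predict_proba(np.asarray(X, dtype=float))
        classes = list(self._knn.classes_)
        i_hts = classes.index(HTS) if HTS in classes else None
        if i_hts is None:
            return self._knn.predict(np.asarray(X, dtype=float))
        p_hts = proba[:, i_hts]
        self.ties_ += int(np.sum(p_hts == 0.5))
        return np.where(p_hts > 0.5, HTS, NTS)


def _median_heuristic_gamma(X: np.ndarray, seed: int, max_rows: int = 400) -> float:
    rng = np.random.default_rng(seed)
    if len(X) > max_rows:
        X = X[rng.choice(len(X), max_rows, replace=False)]
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    med = float(np.median(np.sqrt(d2[np.triu_indices(len(X), k=1)])))
    if med <= 0:
        return 1.0
    return 1.0 / (2.0 * med * med)


def train_classifier(X, y, spec: ModelSpec):
    """Fit the model named by ``spec``; deterministic given ``spec.seed``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    if spec.kind == "knn":
        return _TieAwareKNN(spec.k, spec.metric).fit(X, y)
    if spec.kind == "svm":
        gamma = _median_heuristic_gamma(X, spec.seed)
        return SVC(kernel="rbf", C=spec.C, gamma=gamma, random_state=spec.seed).fit(X, y)
    return BaggingClassifier(
        estimator=DecisionTreeClassifier(random_state=spec.seed),
        n_estimators=spec.n_estimators, random_state=spec.seed,
    ).fit(X, y)


def loo_segment_cv(dataset: pd.DataFrame, spec: ModelSpec,
                   feature_cols: list[str],
                   leaky_normalization: bool = False
                   ) -> tuple[MetricSet, pd.DataFrame, ConfusionCounts]:
    """Leave-one-segment-out cross-validation (calibrated regime).

    One fold per row; the training set contains every other segment,
    including the test subject's own other segments -- the regime in which
    nearest-neighbor memorization of a subject's prior measurements pays off.
    Normalization statistics are refit on each training fold unless
    ``leaky_normalization`` reuses whole-dataset statistics.
    """
    if len(dataset) < 2:
        raise ValueError("need at least 2 segments")
    X = dataset[feature_cols]
    y = dataset["label"].to_numpy()
    global_params = zscore_fit_apply(X)[1] if leaky_normalization else None

    preds = []
    skipped = []
    for pos in range(len(dataset)):
        mask = np.ones(len(dataset), dtype=bool)
        mask[pos] = False
        y_tr = y[mask]
        if len(np.unique(y_tr)) < 2:
            skipped.append(pos)
            continue
        if global_params is not None:
            params = global_params
            X_tr, _ = zscore_fit_apply(X.iloc[mask], params)
        else:
            X_tr, params = zscore_fit_apply(X.iloc[mask])
        X_te, _ = zscore_fit_apply(X.iloc[[pos]], params)
        model = train_classifier(X_tr.to_numpy(), y_tr, spec)
        preds.append((pos, y[pos], model.predict(X_te.to_numpy())[0]))

    pred_df = pd.DataFrame(
        [(dataset.iloc[p]["segment_id"], dataset.iloc[p]["subject_id"], t, pr)
         for p, t, pr in preds],
        columns=["segment_id", "subject_id", "truth", "prediction"],
    )
    counts = counts_from_predictions(pred_df["truth"], pred_df["prediction"])
    metrics = confusion_metrics(counts)
    pred_df.attrs["skipped_folds"] = skipped
    return metrics, pred_df, counts
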