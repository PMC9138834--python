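"""Feature normalization, ReliefF ranking, correlation screening, selection.

Normalization is the usual z-score, z = (x - mean) / sd, with the sample
(n-1) standard deviation; statistics are fit on training data and re-applied
to held-out data.  ReliefF weights each feature by how well it separates near
neighbors of different classes: for every instance, the k nearest same-class
hits and k nearest other-class misses contribute (diff to misses - diff to
hits) / (m * k), with per-feature differences scaled to [0, 1] by the feature
range.  Pearson correlation between feature pairs flags redundancy.

The default selection policy removes a fixed set of six features -- three of
the composite APG ratios, (b-c-d-e)/a, (b-e)/a and (c+d-b)/a, which are
nearly collinear with the simple ratios, plus the three lowest-ranked
features TPP, TPI and pulse area -- leaving 17 of the 23.  A data-driven
policy (drop the lower-weighted member of any pair with |r| above a
threshold, then the three lowest-ranked) is available for new datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_extract import FEATURE_NAMES

PAPER_DROP_CORRELATION = ["r_bcde_a", "r_be_a", "r_cdb_a"]
PAPER_DROP_RANK = ["tpp", "tpi", "pulse_area"]


@dataclass
class NormalizationParams:
    mean: pd.Series
    sd: pd.Series
    columns: list[str]
    dropped: list[str] = field(default_factory=list)


@dataclass
class SelectionReport:
    relieff_weights: pd.Series | None
    correlation: pd.DataFrame | None
    removed_by_correlation: list[str]
    removed_by_rank: list[str]
    kept: list[str]
    policy: str

    def to_dict(self) -> dict:
        return {
            "policy": self.policy,
            "kept": self.kept,
            "removed_by_correlation": self.removed_by_correlation,
            "removed_by_rank": self.removed_by_rank,
            "relieff_weights": (None if self.relieff_weights is None
                                else {k: float(v) for k, v in self.relieff_weights.items()}),
        }


def zscore_fit_apply(X: pd.DataFrame,
                     params: NormalizationParams | None = None
                     ) -> tuple[pd.DataFrame, NormalizationParams]:
    """Fit column means/sds (unless given) and return the standardized frame.

    Zero-variance columns are dropped with a warning when fitting.
    """
    if params is None:
        if len(X) < 2:
            raise ValueError("need at least 2 rows to fit normalization")
        mean = X.mean()
        sd = X.std(ddof=1)
        dead = [c for c in X.columns if not np.isfinite(sd[c]) or sd[c] == 0.0]
        if dead:
            warnings.warn(f"dropping zero-variance columns: {dead}", stacklevel=2)
        cols = [c for c in X.columns if c not in dead]
        params = NormalizationParams(mean=mean[cols], sd=sd[cols], columns=cols,
                                     dropped=dead)
    Xn = (X[params.columns] - params.mean) / params.sd
    return Xn, params


def zscore_invert(Xn: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    return Xn[params.columns] * params.sd + params.mean


def relieff_rank(X, y, k: int = 10) -> pd.Series:
    """Binary ReliefF weights over all instances, deterministic given the data.

    Neighbors are found by Manhattan distance on range-scaled features; ties
    in distance are broken by instance order.  Requires both classes to have
    more than ``k`` members.
    """
    if isinstance(X, pd.DataFrame):
        cols = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        cols = [f"f{j}" for j in range(Xa.shape[1])]
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("ReliefF needs two classes")
    if len(classes) > 2:
        raise ValueError("binary ReliefF only")
    if k >= counts.min():
        raise ValueError(f"k={k} must be smaller than the smallest class ({counts.min()})")

    rng_span = Xa.max(axis=0) - Xa.min(axis=0)
    rng_span[rng_span == 0] = 1.0          # constant feature: all diffs zero
    Xs = Xa / rng_span
    m, p = Xs.shape
    w = np.zeros(p)
    for i in range(m):
        diffs = np.abs(Xs - Xs[i])
        dist = diffs.sum(axis=1)
        order = np.argsort(dist, kind="stable")
        hits, misses = [], []
        for j in order:
            if j == i:
                continue
            if y[j] == y[i]:
                if len(hits) < k:
                    hits.append(j)
            elif len(misses) < k:
                misses.append(j)
            if len(hits) == k and len(misses) == k:
                break
        w += diffs[misses].sum(axis=0) - diffs[hits].sum(axis=0)
    return pd.Series(w / (m * k), index=cols)


def correlation_screen(X: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix; constant columns yield 0 (flagged in attrs)."""
    if len(X) < 3:
        raise ValueError("need at least 3 rows for a correlation screen")
    sd = X.std(ddof=1)
    constant = [c for c in X.columns if not np.isfinite(sd[c]) or sd[c] == 0.0]
    corr = X.corr(method="pearson")
    corr = corr.fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    corr.attrs["constant_columns"] = constant
    return corr


def select_features(weights: pd.Series | None, correlation: pd.DataFrame | None,
                    policy: str = "paper_fixed", corr_threshold: float = 0.95,
                    n_rank_drop: int = 3,
                    feature_names: list[str] | None = None) -> SelectionReport:
    """Produce the kept/removed feature partition under the chosen policy."""
    names = list(feature_names or FEATURE_NAMES)
    if policy == "paper_fixed":
        for f in PAPER_DROP_CORRELATION + PAPER_DROP_RANK:
            if f not in names:
                raise ValueError(f"policy drops unknown feature {f!r}")
        kept = [f for f in names if f not in PAPER_DROP_CORRELATION + PAPER_DROP_RANK]
        return SelectionReport(weights, correlation, list(PAPER_DROP_CORRELATION),
                               list(PAPER_DROP_RANK), kept, policy)
    if policy != "data_driven":
        raise ValueError(f"unknown policy {policy!r}")
    if weights is None or correlation is None:
        raise ValueError("data_driven policy needs weights and a correlation matrix")

    alive = list(names)
    removed_corr: list[str] = []
    while True:
        best = None
        for ii, fa in enumerate(alive):
            for fb in alive[ii + 1:]:
                r = abs(float(correlation.loc[fa, fb]))
                if r >= corr_threshold and (best is None or r > best[0]):
                    best = (r, fa, fb)
        if best is None:
            break
        _, fa, fb = best
        drop = fa if weights[fa] <= weights[fb] else fb
        alive.remove(drop)
        removed_corr.append(drop)
    ranked = sorted(alive, key=lambda f: float(weights[f]))
    removed_rank = ranked[:n_rank_drop]
    kept = [f for f in alive if f not in removed_rank]
    return SelectionReport(weights, correlation, removed_corr, removed_rank, kept,
                           policy)
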