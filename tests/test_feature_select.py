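"""Normalization, ReliefF (with brute-force oracle), correlation screen, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from pulsecal.feature_extract import FEATURE_NAMES
from pulsecal.feature_select import (PAPER_DROP_CORRELATION, PAPER_DROP_RANK,
                                     correlation_screen, relieff_rank,
                                     select_features, zscore_fit_apply,
                                     zscore_invert)


class TestZscore:
    def test_direct_evaluation(self):
        X = pd.DataFrame({"a": [2.0, 4.0, 6.0]})
        Xn, params = zscore_fit_apply(X)
        assert params.mean["a"] == 4.0
        assert params.sd["a"] == pytest.approx(2.0)     # sample sd, n-1
        assert Xn["a"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_identity_with_unit_params(self):
        X = pd.DataFrame({"a": [-1.2, 0.5, 0.7]})
        _, params = zscore_fit_apply(pd.DataFrame({"a": [0.0, 1.0, -1.0, 0.0]}))
        params.mean["a"], params.sd["a"] = 0.0, 1.0
        Xn, _ = zscore_fit_apply(X, params)
        assert np.allclose(Xn["a"], X["a"])

    def test_constant_column_dropped_with_warning(self):
        X = pd.DataFrame({"a": [5.0, 5.0, 5.0], "b": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            Xn, params = zscore_fit_apply(X)
        assert params.dropped == ["a"]
        assert list(Xn.columns) == ["b"]

    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=30, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, values):
        # subnormal-scale lists can underflow to zero variance and be dropped
        assume(float(np.std(values, ddof=1)) > 0.0)
        X = pd.DataFrame({"a": values})
        Xn, params = zscore_fit_apply(X)
        back = zscore_invert(Xn, params)
        scale = max(1.0, np.abs(values).max())
        assert np.abs(back["a"].to_numpy() - np.asarray(values)).max() < 1e-9 * scale


def brute_force_relieff(X, y, k):
    """Independent ReliefF oracle by exhaustive neighbor enumeration."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    m, p = X.shape
    w = np.zeros(p)
    for i in range(m):
        dists = []
        for j in range(m):
            if j == i:
                continue
            d = sum(abs(X[i, f] - X[j, f]) / span[f] for f in range(p))
            dists.append((d, j))
        dists.sort(key=lambda t: (t[0], t[1]))
        hits = [j for _, j in dists if y[j] == y[i]][:k]
        misses = [j for _, j in dists if y[j] != y[i]][:k]
        for f in range(p):
            for j in misses:
                w[f] += abs(X[i, f] - X[j, f]) / span[f] / (m * k)
            for j in hits:
                w[f] -= abs(X[i, f] - X[j, f]) / span[f] / (m * k)
    return w


class TestReliefF:
    def test_label_copy_feature_dominates_noise(self, rng):
        n = 100
        y = rng.integers(0, 2, n)
        X = pd.DataFrame({"copy": y.astype(float),
                          "noise": rng.standard_normal(n)})
        w = relieff_rank(X, y, k=5)
        assert w["copy"] == w.max()
        assert w["copy"] > w["noise"]

    def test_constant_feature_has_zero_weight(self, rng):
        n = 40
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame({"const": np.full(n, 3.3),
                          "f": rng.standard_normal(n)})
        w = relieff_rank(X, y, k=3)
        assert w["const"] == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_agreement_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 11))
        p = int(rng.integers(2, 5))
        X = rng.standard_normal((n, p))
        y = np.array([0, 0, 1, 1] + list(rng.integers(0, 2, n - 4)))
        k = int(min(2, np.bincount(y).min() - 1))
        if k < 1:
            pytest.skip("degenerate class draw")
        got = relieff_rank(X, y, k=k).to_numpy()
        want = brute_force_relieff(X, y, k)
        assert np.allclose(got, want, atol=1e-12)

    def test_informative_feature_ranks_first_in_19_of_20_replicates(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            n = 60
            y = np.repeat([0, 1], n // 2)
            X = rng.standard_normal((n, 23))
            X[:, 0] += 3.0 * y                  # single separating feature
            w = relieff_rank(X, y, k=5)
            wins += int(np.argmax(w.to_numpy()) == 0)
        assert wins >= 19

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            relieff_rank(np.zeros((5, 2)), np.zeros(5), k=1)

    def test_k_larger_than_class_rejected(self):
        y = np.array([0, 0, 0, 1, 1])
        with pytest.raises(ValueError, match="k="):
            relieff_rank(np.zeros((5, 2)), y, k=2)


class TestCorrelationScreen:
    def test_duplicate_and_negated_columns(self, rng):
        x = rng.standard_normal(50)
        X = pd.DataFrame({"a": x, "b": x.copy(), "neg": -x})
        corr = correlation_screen(X)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "neg"] == pytest.approx(-1.0)
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)

    def test_independent_noise_weakly_correlated(self, rng):
        X = pd.DataFrame(rng.standard_normal((1000, 2)), columns=["a", "b"])
        corr = correlation_screen(X)
        assert abs(corr.loc["a", "b"]) < 0.1

    def test_constant_column_flagged_as_zero(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": [7.0, 7.0, 7.0]})
        corr = correlation_screen(X)
        assert corr.loc["a", "c"] == 0.0
        assert corr.attrs["constant_columns"] == ["c"]

    def test_needs_three_rows(self):
        with pytest.raises(ValueError):
            correlation_screen(pd.DataFrame({"a": [1.0, 2.0]}))


class TestSelectFeatures:
    def test_fixed_policy_keeps_17_excluding_the_six(self):
        report = select_features(None, None, policy="paper_fixed")
        assert len(report.kept) == 17
        dropped = set(PAPER_DROP_CORRELATION) | set(PAPER_DROP_RANK)
        assert dropped == {"r_bcde_a", "r_be_a", "r_cdb_a", "tpp", "tpi",
                           "pulse_area"}
        assert not dropped & set(report.kept)
        assert set(report.kept) | dropped == set(FEATURE_NAMES)

    def test_fixed_policy_with_unknown_feature_rejected(self):
        with pytest.raises(ValueError, match="unknown feature"):
            select_features(None, None, policy="paper_fixed",
                            feature_names=["x", "y"])

    def test_data_driven_drops_one_of_a_duplicated_pair(self, rng):
        x = rng.standard_normal(100)
        X = pd.DataFrame({"dup1": x, "dup2": x + 1e-9 * rng.standard_normal(100),
                          **{f"n{i}": rng.standard_normal(100) for i in range(5)}})
        y = rng.integers(0, 2, 100)
        w = relieff_rank(X, y, k=5)
        corr = correlation_screen(X)
        report = select_features(w, corr, policy="data_driven",
                                 corr_threshold=0.95, n_rank_drop=1,
                                 feature_names=list(X.columns))
        assert len(set(report.removed_by_correlation) & {"dup1", "dup2"}) == 1

    def test_unattainable_threshold_drops_nothing_by_correlation(self, rng):
        X = pd.DataFrame(rng.standard_normal((50, 4)),
                         columns=["a", "b", "c", "d"])
        y = rng.integers(0, 2, 50)
        w = relieff_rank(X, y, k=3)
        corr = correlation_screen(X)
        report = select_features(w, corr, policy="data_driven",
                                 corr_threshold=1.01, n_rank_drop=1,
                                 feature_names=list(X.columns))
        assert report.removed_by_correlation == []
        assert len(report.removed_by_rank) == 1
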