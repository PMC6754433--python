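"""Greedy ±1 selection, permutation null, stability selection, consensus."""

import itertools

import numpy as np
import pandas as pd
import pytest

from methylmark import (DesignError, consensus_markers, greedy_fit,
                        permutation_test, stability_selection)
from methylmark.calf import (StabilityResult, _greedy_batch_pearson, _zscore)
from methylmark.errors import ConfigurationError


def signed_metric(x, y):
    """|Pearson r| of a single signed feature against the labels."""
    return abs(np.corrcoef(x, y)[0, 1])


def separated_data(n_case=15, n_control=15, n_features=50, n_planted=10,
                   delta=0.10, noise_sd=0.03, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0.5, noise_sd, size=(n_case + n_control, n_features))
    X[:n_case, :n_planted] += delta
    y = np.r_[np.ones(n_case), np.zeros(n_control)]
    return X, y


class TestGreedyFit:
    def test_perfect_single_predictor(self):
        y = np.r_[np.ones(6), np.zeros(6)]
        X = np.column_stack([y, np.tile([0.2, 0.8], 6)])
        model = greedy_fit(X, y)
        assert model.features[0] == ("f0", 1)
        assert model.final_metric == pytest.approx(1.0)
        assert len(model.features) == 1          # no further improvement possible

    def test_first_step_matches_exhaustive_signed_search(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, size=(20, 6))
        y = rng.integers(0, 2, 20).astype(float)
        y[0], y[1] = 1, 0                         # both classes guaranteed
        model = greedy_fit(X, y, limit=1)
        xz, _ = _zscore(X)
        best = max(
            ((signed_metric(s * xz[:, j], y), -j, s) for j, s in
             itertools.product(range(6), (1, -1))),
        )
        assert model.features[0][0] == f"f{-best[1]}"
        assert model.final_metric == pytest.approx(best[0])

    @pytest.mark.parametrize("seed", range(8))
    def test_limit_one_equals_best_subset(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(2, 12))
        X = rng.normal(0, 1, size=(16, p))
        y = np.r_[np.ones(8), np.zeros(8)]
        model = greedy_fit(X, y, limit=1)
        xz, _ = _zscore(X)
        exhaustive = max(signed_metric(s * xz[:, j], y)
                         for j in range(p) for s in (1, -1))
        assert model.final_metric == pytest.approx(exhaustive)

    @pytest.mark.parametrize("seed", range(5))
    def test_limit_two_never_beats_best_pair(self, seed):
        rng = np.random.default_rng(100 + seed)
        X = rng.normal(0, 1, size=(14, 8))
        y = np.r_[np.ones(7), np.zeros(7)]
        model = greedy_fit(X, y, limit=2)
        xz, _ = _zscore(X)
        best_pair = max(
            signed_metric(sa * xz[:, a] + sb * xz[:, b], y)
            for a, b in itertools.combinations(range(8), 2)
            for sa in (1, -1) for sb in (1, -1)
        )
        best_single = max(signed_metric(s * xz[:, j], y)
                          for j in range(8) for s in (1, -1))
        assert model.final_metric <= max(best_pair, best_single) + 1e-12

    def test_trajectory_strictly_increasing(self):
        X, y = separated_data(seed=5)
        model = greedy_fit(X, y)
        assert np.all(np.diff(model.trajectory) > 0)
        assert len({f for f, _ in model.features}) == len(model.features)
        assert all(w in (1, -1) for _, w in model.features)
        assert len(model.features) <= model.limit

    def test_constant_feature_skipped_with_log(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        X = np.column_stack([np.full(10, 0.5), y + np.arange(10) * 0.01])
        model = greedy_fit(X, y)
        assert any("f0" in line for line in model.log)
        assert all(f != "f0" for f, _ in model.features)

    def test_single_class_rejected(self):
        with pytest.raises(DesignError):
            greedy_fit(np.random.default_rng(0).normal(size=(6, 3)), np.ones(6))

    def test_auc_metric_selects_separating_feature(self):
        X, y = separated_data(n_planted=1, n_features=5, delta=0.2, seed=6)
        model = greedy_fit(X, y, metric="auc")
        assert model.features[0][0] == "f0"
        assert model.final_metric > 0.9

    def test_dataframe_columns_used_as_names(self):
        X, y = separated_data(n_features=4, n_planted=1, seed=7)
        df = pd.DataFrame(X, columns=["cgA", "cgB", "cgC", "cgD"])
        model = greedy_fit(df, y)
        assert model.features[0][0] == "cgA"


class TestPermutationTest:
    def test_batch_engine_matches_scalar_greedy(self):
        """The vectorized many-permutation engine reproduces the scalar greedy
        result for each label vector (up to BLAS summation-order rounding)."""
        X, y = separated_data(n_case=10, n_control=10, n_features=12,
                              n_planted=2, delta=0.06, seed=8)
        rng = np.random.default_rng(9)
        perms = np.stack([rng.permutation(y) for _ in range(20)])
        xz, valid = _zscore(X)
        batch, _ = _greedy_batch_pearson(xz, valid, perms, limit=10)
        scalar = [greedy_fit(X, perms[i], limit=10).final_metric for i in range(20)]
        np.testing.assert_allclose(batch, scalar, rtol=1e-12)

    def test_floor_reached_on_separated_data(self):
        X, y = separated_data(seed=0)
        res = permutation_test(X, y, n_perm=2000, seed=1)
        assert res.p == pytest.approx(5.0e-4)
        assert (res.permuted < res.observed).all()

    def test_worst_case_p_is_one(self):
        """A feature exactly uncorrelated with the labels scores 0; every
        permutation scores >= 0, so the empirical p is 1."""
        X = np.array([[0.0], [0.0], [1.0], [1.0], [2.0], [2.0]])
        y = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        res = permutation_test(X, y, limit=1, n_perm=200, seed=2)
        assert res.observed == pytest.approx(0.0, abs=1e-12)
        assert res.p == 1.0

    def test_add_one_estimator(self):
        X, y = separated_data(seed=0)
        res = permutation_test(X, y, n_perm=500, seed=3, estimator="add-one")
        assert res.p == pytest.approx(1 / 501)

    def test_small_n_perm_warns(self):
        X, y = separated_data(n_features=5, seed=4)
        with pytest.warns(UserWarning, match="resolution"):
            permutation_test(X, y, n_perm=50, seed=5)

    def test_deterministic_given_seed(self):
        X, y = separated_data(n_features=10, seed=6)
        r1 = permutation_test(X, y, n_perm=100, seed=11)
        r2 = permutation_test(X, y, n_perm=100, seed=11)
        np.testing.assert_array_equal(r1.permuted, r2.permuted)
        assert r1.p == r2.p

    def test_null_p_values_roughly_uniform(self):
        """With labels independent of features, p <= 0.05 in ~5% of replicates."""
        rng = np.random.default_rng(12)
        hits = 0
        reps = 200
        for _ in range(reps):
            X = rng.normal(size=(16, 8))
            y = np.r_[np.ones(8), np.zeros(8)]
            rng.shuffle(y)
            res = permutation_test(X, y, limit=3, n_perm=200,
                                   seed=int(rng.integers(2 ** 31)))
            hits += res.p <= 0.05
        assert 0.01 <= hits / reps <= 0.09


class TestStabilitySelection:
    def test_dominant_marker_nearly_always_selected(self):
        X, y = separated_data(n_case=20, n_control=30, n_features=50,
                              n_planted=1, delta=0.15, seed=0)
        res = stability_selection(X, y, n_trials=2000, seed=1)
        assert res.counts.iloc[0] >= 1900

    def test_counts_accounting(self):
        X, y = separated_data(n_case=8, n_control=8, n_features=6,
                              n_planted=2, delta=0.05, seed=2)
        res = stability_selection(X, y, limit=4, n_trials=100, seed=3)
        assert (res.counts <= 100).all()
        assert res.counts.sum() <= 100 * 4

    def test_default_threshold_flags_750(self):
        counts = pd.Series({"a": 800, "b": 750, "c": 749, "d": 10})
        res = StabilityResult(counts=counts, n_trials=2000, fraction=0.8,
                              min_count=750, seed=None)
        assert res.selected() == ["a", "b"]

    def test_fraction_out_of_range_rejected(self):
        X, y = separated_data(n_features=4, seed=4)
        with pytest.raises(ConfigurationError):
            stability_selection(X, y, fraction=1.5)

    def test_deterministic_given_seed(self):
        X, y = separated_data(n_features=8, seed=5)
        r1 = stability_selection(X, y, n_trials=50, seed=6)
        r2 = stability_selection(X, y, n_trials=50, seed=6)
        pd.testing.assert_series_equal(r1.counts, r2.counts)


class TestConsensus:
    def _model(self, names):
        from methylmark.calf import CalfModel
        return CalfModel(features=[(n, 1) for n in names], metric_name="pearson",
                         trajectory=list(np.linspace(0.5, 0.9, len(names))),
                         final_metric=0.9, limit=10)

    def _stability(self, counts):
        return StabilityResult(counts=pd.Series(counts), n_trials=2000,
                               fraction=0.8, min_count=750, seed=None)

    def test_intersection(self):
        stab = self._stability({"a": 1900, "b": 1800, "c": 1700, "d": 100})
        assert consensus_markers(self._model(["b", "c", "d"]), stab) == ["b", "c"]

    def test_empty_stable_set(self):
        stab = self._stability({"a": 10, "b": 5})
        assert consensus_markers(self._model(["a", "b"]), stab) == []

    def test_identical_sets_in_count_order(self):
        stab = self._stability({"a": 1500, "b": 1900, "c": 1600})
        assert consensus_markers(self._model(["a", "b", "c"]), stab) == ["b", "c", "a"]

    def test_count_ties_broken_by_selection_order(self):
        stab = self._stability({"a": 1500, "b": 1500})
        assert consensus_markers(self._model(["b", "a"]), stab) == ["b", "a"]
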