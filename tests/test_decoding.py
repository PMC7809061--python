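"""Victor-Purpura distance, feature builders, and the PCA+KNN harness."""

import functools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tactilesnn.decoding import (
    SpikeRaster,
    biomimetic_decode,
    correlation_features,
    expanding_windows,
    pca_knn_classify,
    performance_curve,
    spike_counts,
    vp_distance,
    vpd_features,
    wta_result,
)


# ---------------------------------------------------------------------------
# independent VPd oracle: exhaustive recursion with memoization
# ---------------------------------------------------------------------------


def vp_reference(a, b, q):
    """Recursive edit-distance definition, independent of the DP in the
    package: match or delete the last spike of either train."""
    a = tuple(sorted(a))
    b = tuple(sorted(b))

    @functools.lru_cache(maxsize=None)
    def rec(i, j):
        if i == 0:
            return float(j)
        if j == 0:
            return float(i)
        return min(
            rec(i - 1, j) + 1.0,
            rec(i, j - 1) + 1.0,
            rec(i - 1, j - 1) + q * abs(a[i - 1] - b[j - 1]),
        )

    return rec(len(a), len(b))


spike_train = st.lists(
    st.floats(min_value=0.0, max_value=200.0, allow_nan=False), min_size=0, max_size=8
)


class TestVPDistance:
    def test_identical_trains(self):
        t = np.array([1.0, 5.0, 9.0])
        assert vp_distance(t, t, q=1.0) == 0.0

    def test_empty_vs_n_spikes(self):
        assert vp_distance(np.array([]), np.array([1.0, 2.0, 3.0]), q=1.0) == 3.0
        assert vp_distance(np.array([]), np.array([]), q=1.0) == 0.0

    def test_two_single_spikes(self):
        # shifting costs q*dt when cheaper than delete+insert
        assert vp_distance([5.0], [5.5], q=1.0) == pytest.approx(0.5)
        assert vp_distance([5.0], [9.0], q=1.0) == pytest.approx(2.0)  # min(2, 4)

    def test_q_zero_reduces_to_count_difference(self):
        a = np.array([1.0, 2.0, 50.0])
        b = np.array([100.0])
        assert vp_distance(a, b, q=0.0) == pytest.approx(abs(len(a) - len(b)))

    def test_large_q_counts_all_spikes_of_disjoint_trains(self):
        a = np.array([1.0, 2.0])
        b = np.array([100.0, 150.0, 190.0])
        assert vp_distance(a, b, q=1e6) == pytest.approx(len(a) + len(b))

    def test_negative_q_rejected(self):
        with pytest.raises(ValueError):
            vp_distance([1.0], [2.0], q=-1.0)

    @settings(max_examples=60, deadline=None)
    @given(spike_train, spike_train, st.sampled_from([0.0, 0.1, 1.0, 10.0]))
    def test_matches_recursive_oracle(self, a, b, q):
        assert vp_distance(a, b, q) == pytest.approx(vp_reference(a, b, q))

    @settings(max_examples=40, deadline=None)
    @given(spike_train, spike_train, spike_train)
    def test_metric_axioms(self, a, b, c):
        q = 1.0
        dab = vp_distance(a, b, q)
        dba = vp_distance(b, a, q)
        assert dab >= 0.0
        assert dab == pytest.approx(dba)
        if sorted(a) == sorted(b):
            assert dab == pytest.approx(0.0)
        dac = vp_distance(a, c, q)
        dcb = vp_distance(c, b, q)
        assert dab <= dac + dcb + 1e-9

    def test_pairwise_matrix(self):
        trains = [np.array([1.0]), np.array([2.0]), np.array([])]
        D = vpd_features(trains, q=1.0)
        assert D.shape == (3, 3)
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 0.0)
        assert D[0, 1] == pytest.approx(1.0)
        assert D[0, 2] == pytest.approx(1.0)


class TestRasterAndCounts:
    def _raster(self):
        units = np.array([0, 0, 0, 2])
        times = np.array([10.0, 20.0, 190.0, 5.0])
        order = np.argsort(times)
        return SpikeRaster(units[order], times[order], 3, 200.0)

    def test_window_counting(self):
        r = self._raster()
        assert spike_counts(r, 180.0).tolist() == [2, 0, 1]
        assert spike_counts(r, 0.0).tolist() == [0, 0, 0]
        assert r.counts().tolist() == [3, 0, 1]

    def test_empty_raster(self):
        r = SpikeRaster(np.array([], int), np.array([]), 4, 100.0)
        assert spike_counts(r, 50.0).tolist() == [0, 0, 0, 0]

    def test_matrix_roundtrip(self):
        spikes = np.zeros((100, 3), dtype=bool)
        spikes[10, 0] = spikes[50, 2] = True
        r = SpikeRaster.from_matrix(spikes, 0.1)
        assert r.counts().tolist() == [1, 0, 1]
        assert np.allclose(r.unit_train(0), [1.0])


class TestBiomimeticDecoder:
    def test_argmax_group(self):
        group_of = np.repeat(np.arange(3), 2)
        units = np.array([2, 2, 3, 0])
        r = SpikeRaster(units, np.array([1.0, 2.0, 3.0, 4.0]), 6, 10.0)
        # group counts: [1, 3, 0]
        assert biomimetic_decode(r, group_of, [10.0, 20.0, 30.0]) == 20.0

    def test_tie_breaks_to_smallest_orientation(self):
        group_of = np.repeat(np.arange(2), 1)
        r = SpikeRaster(np.array([0, 1]), np.array([1.0, 2.0]), 2, 10.0)
        assert biomimetic_decode(r, group_of, [10.0, 20.0]) == 10.0

    def test_silent_raster_is_no_detection(self):
        group_of = np.zeros(2, dtype=int)
        r = SpikeRaster(np.array([], int), np.array([]), 2, 10.0)
        assert biomimetic_decode(r, group_of, [10.0]) is None

    def test_window_restricts_counts(self):
        group_of = np.array([0, 1])
        r = SpikeRaster(np.array([0, 1, 1]), np.array([1.0, 50.0, 60.0]), 2, 100.0)
        assert biomimetic_decode(r, group_of, [10.0, 20.0], window_ms=40.0) == 10.0
        assert biomimetic_decode(r, group_of, [10.0, 20.0]) == 20.0


class TestCorrelationFeatures:
    def test_identical_trace_scores_one(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(50,))
        traces = np.stack([base, base, base + rng.normal(0, 0.01, 50), -base])
        labels = np.array([0, 0, 0, 1])
        X, kept = correlation_features(traces, labels)
        assert X.shape == (4, 2)
        # trial 0's class-0 template is the mean of trials 1 and 2: r ~ 1
        assert X[0, 0] > 0.99
        assert X[3, 1] == pytest.approx(0.0, abs=1e-9) or X.shape[1] == 2

    def test_own_class_scores_highest_in_noiseless_limit(self):
        rng = np.random.default_rng(1)
        protos = rng.normal(size=(3, 40))
        traces = np.repeat(protos, 4, axis=0)
        labels = np.repeat([0, 1, 2], 4)
        X, kept = correlation_features(traces, labels)
        assert np.all(X.argmax(axis=1) == labels)

    def test_zero_variance_trials_dropped(self):
        traces = np.vstack([np.zeros(20), np.random.default_rng(2).normal(size=(3, 20))])
        labels = np.array([0, 0, 1, 1])
        X, kept = correlation_features(traces, labels)
        assert 0 not in kept
        assert X.shape[0] == 3


class TestPcaKnn:
    def test_separated_clusters_perfect(self, rng):
        centers = np.eye(4) * 50
        X = np.vstack([c + rng.normal(0, 0.5, size=(10, 4)) for c in centers])
        y = np.repeat(np.arange(4), 10)
        res = pca_knn_classify(X, y, z=3, k=5, rng=0)
        assert res.accuracy == 1.0
        assert np.trace(res.confusion) == 40

    def test_shuffled_labels_near_chance(self, rng):
        # 16 classes, informative features, labels permuted: chance = 1/16
        n_per = 12
        X = np.vstack([
            rng.normal(3 * k, 1.0, size=(n_per, 5)) for k in range(16)
        ])
        y = rng.permutation(np.repeat(np.arange(16), n_per))
        res = pca_knn_classify(X, y, z=3, k=5, rng=0)
        p = 1 / 16
        sd = np.sqrt(p * (1 - p) / len(y))
        assert abs(res.accuracy - p) < 4 * sd

    def test_confusion_row_sums_are_trials_per_class(self, rng):
        X = rng.normal(size=(30, 6))
        y = np.repeat(np.arange(3), 10)
        res = pca_knn_classify(X, y, rng=1)
        assert res.confusion.sum() == 30
        assert np.all(res.confusion.sum(axis=1) == 10)

    def test_z_capped_at_feature_dimension(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.repeat([0, 1], 10)
        res = pca_knn_classify(X, y, z=50, rng=2)  # must not raise
        assert 0.0 <= res.accuracy <= 1.0

    def test_pca_fit_on_training_folds_only(self, rng):
        """Deliberately leaking the test rows into the PCA fit changes the
        projection; the harness must match the no-leak construction."""
        from sklearn.decomposition import PCA
        from sklearn.model_selection import StratifiedKFold
        from sklearn.neighbors import KNeighborsClassifier

        X = rng.normal(size=(40, 8))
        y = np.repeat(np.arange(4), 10)
        res = pca_knn_classify(X, y, z=3, k=5, folds=5, rng=123)
        # replicate exactly with an explicit no-leak loop and the same seed
        seed = int(np.random.default_rng(123).integers(2**31 - 1))
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        preds = np.empty_like(y)
        for train, test in skf.split(X, y):
            pca = PCA(n_components=3).fit(X[train])
            knn = KNeighborsClassifier(n_neighbors=5).fit(pca.transform(X[train]), y[train])
            preds[test] = knn.predict(pca.transform(X[test]))
        assert np.array_equal(res.predictions, preds)


class TestPerformanceCurve:
    def test_windows_and_monotone_trend(self):
        windows = expanding_windows(180.0, 60)
        assert len(windows) == 60
        assert windows[-1] == 180.0
        # synthetic decoder whose accuracy saturates with window length
        acc, results = performance_curve(windows, lambda w: wta_result(
            [1.0], [1.0 if w > 30 else 2.0], [1.0, 2.0], w))
        assert acc[0] == 0.0 and acc[-1] == 1.0
        assert np.all(np.diff(acc) >= 0)

    def test_unsorted_windows_rejected(self):
        with pytest.raises(ValueError):
            performance_curve([10.0, 5.0], lambda w: None)
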