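"""Weight clustering unit: oracles, closed-form memory updates, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from accn.clustering import (
    CentroidState,
    assign_pseudolabels,
    confidence_pseudolabels,
    soft_weighted_centroids,
    update_memory,
)


def centroid_oracle(features, probs):
    """Scalar-loop weighted mean, independent of the vectorized path."""
    n, d = features.shape
    n_c = probs.shape[1]
    out = np.zeros((n_c, d))
    for k in range(n_c):
        num = np.zeros(d)
        den = 0.0
        for i in range(n):
            num += probs[i, k] * features[i]
            den += probs[i, k]
        out[k] = num / den
    return out


def assignment_oracle(features, centroids):
    """Exhaustive distance scan with smallest-index tie-break."""
    labels = []
    for f in features:
        dists = [np.sqrt(((f - c) ** 2).sum()) for c in centroids]
        labels.append(int(np.argmin(dists)))
    return np.array(labels)


class TestSoftWeightedCentroids:
    def test_worked_example(self):
        feats = np.array([[1.0, 0.0], [0.0, 1.0]])
        probs = np.array([[0.9, 0.1], [0.1, 0.9]])
        cents, valid = soft_weighted_centroids(feats, probs)
        np.testing.assert_allclose(cents[0], [0.9, 0.1])
        np.testing.assert_allclose(cents[1], [0.1, 0.9])
        assert valid.all()

    def test_one_hot_degenerates_to_class_means(self, rng):
        feats = rng.normal(size=(12, 5))
        labels = rng.integers(0, 3, 12)
        probs = np.eye(3)[labels]
        cents, _ = soft_weighted_centroids(feats, probs)
        for k in range(3):
            np.testing.assert_allclose(cents[k], feats[labels == k].mean(axis=0))

    def test_uniform_probs_give_global_mean(self, rng):
        feats = rng.normal(size=(9, 4))
        probs = np.full((9, 3), 1 / 3)
        cents, _ = soft_weighted_centroids(feats, probs)
        for k in range(3):
            np.testing.assert_allclose(cents[k], feats.mean(axis=0))

    def test_empty_class_flagged_and_backfilled(self, rng):
        feats = rng.normal(size=(4, 3))
        probs = np.column_stack([np.ones(4), np.zeros(4)])  # class 1 empty
        memory = np.arange(6, dtype=float).reshape(2, 3)
        cents, valid = soft_weighted_centroids(feats, probs, memory=memory)
        assert valid.tolist() == [True, False]
        np.testing.assert_array_equal(cents[1], memory[1])

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            soft_weighted_centroids(np.zeros((0, 2)), np.zeros((0, 2)))

    def test_matches_loop_oracle_on_random_instances(self, rng):
        for _ in range(30):
            n, d, n_c = rng.integers(1, 20), rng.integers(1, 8), rng.integers(2, 5)
            feats = rng.normal(size=(n, d))
            probs = rng.dirichlet(np.ones(n_c), size=n)
            cents, valid = soft_weighted_centroids(feats, probs)
            expected = centroid_oracle(feats, probs)
            np.testing.assert_allclose(cents[valid], expected[valid], atol=1e-9)


class TestAssignment:
    def test_exact_centroid_match(self):
        cents = np.array([[0.0, 0.0], [5.0, 5.0]])
        assert assign_pseudolabels(np.array([[5.0, 5.0]]), cents)[0] == 1

    def test_tie_breaks_toward_smallest_index(self):
        cents = np.array([[-1.0, 0.0], [1.0, 0.0]])
        assert assign_pseudolabels(np.array([[0.0, 7.3]]), cents)[0] == 0

    def test_matches_exhaustive_oracle(self, rng):
        feats = rng.normal(size=(50, 4))
        cents = rng.normal(size=(3, 4))
        got = assign_pseudolabels(feats, cents)
        np.testing.assert_array_equal(got, assignment_oracle(feats, cents))

    def test_permutation_equivariance(self, rng):
        feats = rng.normal(size=(20, 3))
        cents = rng.normal(size=(4, 3))
        perm = rng.permutation(20)
        a = assign_pseudolabels(feats, cents)[perm]
        b = assign_pseudolabels(feats[perm], cents)
        np.testing.assert_array_equal(a, b)

    def test_nonfinite_unflagged_centroid_rejected(self):
        cents = np.array([[0.0, 0.0], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="non-finite"):
            assign_pseudolabels(np.zeros((1, 2)), cents)

    def test_invalid_rows_excluded_from_argmin(self):
        cents = np.array([[np.inf, np.inf], [1.0, 1.0]])
        valid = np.array([False, True])
        got = assign_pseudolabels(np.zeros((3, 2)), cents, valid)
        assert (got == 1).all()


class TestMemoryUpdate:
    def init_state(self, memory, counts):
        return CentroidState(memory=np.asarray(memory, float),
                             counts=np.asarray(counts, np.int64),
                             initialized=True)

    def test_count_zero_fully_replaces(self):
        state = self.init_state([[0.0, 0.0]], [0])
        new = update_memory(state, [[3.0, -2.0]], [1])
        np.testing.assert_array_equal(new.memory, [[3.0, -2.0]])

    def test_count_one_blends_with_e_minus_one(self):
        state = self.init_state([[0.0, 0.0]], [1])
        new = update_memory(state, [[1.0, 1.0]], [1])
        np.testing.assert_allclose(new.memory, np.exp(-1.0) * np.ones((1, 2)))
        assert new.memory[0, 0] == pytest.approx(0.36788, abs=5e-6)

    def test_count_five_blends_with_e_minus_five(self):
        state = self.init_state([[2.0]], [5])
        new = update_memory(state, [[4.0]], [3])
        eta = np.exp(-5.0)
        assert new.memory[0, 0] == pytest.approx((1 - eta) * 2.0 + eta * 4.0, rel=1e-12)
        assert new.counts.tolist() == [3]

    def test_equal_local_and_memory_is_fixed_point(self, rng):
        mem = rng.normal(size=(3, 4))
        for t in (0, 1, 7):
            state = self.init_state(mem, [t] * 3)
            new = update_memory(state, mem.copy(), [t] * 3)
            np.testing.assert_allclose(new.memory, mem, atol=1e-12)

    def test_first_update_seeds_memory(self):
        state = CentroidState.zeros(2, 3)
        assert not state.initialized
        local = np.arange(6, dtype=float).reshape(2, 3)
        new = update_memory(state, local, [4, 4])
        assert new.initialized
        np.testing.assert_array_equal(new.memory, local)

    def test_flagged_empty_class_keeps_memory(self):
        state = self.init_state([[1.0], [2.0]], [0, 0])
        new = update_memory(state, [[9.0], [9.0]], [1, 0],
                            valid=np.array([True, False]))
        np.testing.assert_array_equal(new.memory, [[9.0], [2.0]])

    def test_negative_counts_rejected(self):
        state = self.init_state([[0.0]], [0])
        with pytest.raises(ValueError, match="non-negative"):
            update_memory(state, [[1.0]], [-1])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(t=st.integers(0, 30),
           m=st.floats(-50, 50), c=st.floats(-50, 50))
    def test_update_is_convex_combination(self, t, m, c):
        """M' lies between M and c, and never moves away from c."""
        state = self.init_state([[m]], [t])
        new = update_memory(state, [[c]], [t])
        lo, hi = min(m, c), max(m, c)
        assert lo - 1e-9 <= new.memory[0, 0] <= hi + 1e-9
        assert abs(new.memory[0, 0] - c) <= abs(m - c) + 1e-9

    def test_update_rate_strictly_decreasing_in_count(self):
        state = CentroidState(memory=np.zeros((5, 1)),
                              counts=np.arange(5), initialized=True)
        rates = state.update_rates
        assert (np.diff(rates) < 0).all()
        assert rates[0] == 1.0 and rates.min() > 0.0


class TestConfidencePseudolabels:
    def test_kept_above_threshold(self):
        labels, keep = confidence_pseudolabels([[0.96, 0.04]], 0.95)
        assert labels[0] == 0 and keep[0]

    def test_dropped_below_threshold(self):
        labels, keep = confidence_pseudolabels([[0.6, 0.4]], 0.95)
        assert labels[0] == 0 and not keep[0]

    def test_uniform_rows_dropped_for_any_nontrivial_threshold(self):
        probs = np.full((5, 4), 0.25)
        _, keep = confidence_pseudolabels(probs, 0.3)
        assert not keep.any()

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_threshold_outside_open_interval_rejected(self, bad):
        with pytest.raises(ValueError, match="threshold"):
            confidence_pseudolabels(np.full((1, 2), 0.5), bad)


class TestParameterRecovery:
    def test_one_clustering_round_beats_weak_classifier(self):
        """Soft centroids + nearest-centroid assignment denoise a 70%-accurate
        classifier on 3 well-separated Gaussian clusters (5 seeds)."""
        improved = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n_per, n_c, d = 100, 3, 8
            centers = rng.normal(size=(n_c, d))
            centers = centers / np.linalg.norm(centers, axis=1, keepdims=True) * 6.0
            truth = np.repeat(np.arange(n_c), n_per)
            feats = centers[truth] + rng.normal(size=(n_per * n_c, d))
            # weak classifier: correct label w.p. 0.7, else a random other class
            noisy = truth.copy()
            flip = rng.random(len(truth)) > 0.7
            noisy[flip] = (truth[flip] + rng.integers(1, n_c, flip.sum())) % n_c
            probs = np.full((len(truth), n_c), 0.1 / (n_c - 1))
            probs[np.arange(len(truth)), noisy] = 0.9
            input_acc = (noisy == truth).mean()
            cents, valid = soft_weighted_centroids(feats, probs)
            out = assign_pseudolabels(feats, cents, valid)
            if (out == truth).mean() > input_acc:
                improved += 1
        assert improved == 5
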