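import numpy as np
import pytest

from soundstates import decoding
from soundstates.errors import InvalidInputError
from soundstates.responses import ResponseTensor

WINDOW = (-0.03, 0.1)  # 13 bins at 10 ms; onset bin 3


def make_tensor(values, unit_offset=0):
    v = np.asarray(values, dtype=np.float32)
    return ResponseTensor(
        v,
        list(range(unit_offset, unit_offset + v.shape[0])),
        list(range(v.shape[1])),
        0.01,
        WINDOW,
    )


def pattern_tensor(n_units, n_sounds, n_trials, noise_sd, seed, patterns=None):
    """Distinct per-sound mean patterns plus iid trial noise."""
    rng = np.random.default_rng(seed)
    if patterns is None:
        patterns = rng.normal(0, 1, (n_units, n_sounds, 1, 13))
    values = patterns + rng.normal(0, noise_sd, (n_units, n_sounds, n_trials, 13))
    return make_tensor(values), patterns


class TestAssemblePseudopopulation:
    def test_single_recording_identity_up_to_trial_permutation(self):
        t, _ = pattern_tensor(4, 6, 8, 0.5, 0)
        pooled = decoding.assemble_pseudopopulation([t], seed=1)
        assert pooled.values.shape == t.values.shape
        for j in range(6):
            assert np.allclose(
                np.sort(pooled.values[:, j], axis=1), np.sort(t.values[:, j], axis=1)
            )

    def test_neuron_counts_add(self):
        a, _ = pattern_tensor(3, 5, 4, 0.5, 2)
        b, _ = pattern_tensor(7, 5, 4, 0.5, 3)
        b.unit_ids = list(range(100, 107))
        pooled = decoding.assemble_pseudopopulation([a, b], seed=0)
        assert pooled.n_units == 10
        assert pooled.unit_ids == a.unit_ids + b.unit_ids

    def test_mismatched_sounds_rejected(self):
        a, _ = pattern_tensor(3, 5, 4, 0.5, 2)
        b, _ = pattern_tensor(3, 6, 4, 0.5, 3)
        with pytest.raises(InvalidInputError):
            decoding.assemble_pseudopopulation([a, b])

    def test_pooling_helps_on_average(self):
        # more informative neurons -> pooled accuracy >= best single recording
        accs_single, accs_pooled = [], []
        for seed in range(5):
            a, _ = pattern_tensor(3, 12, 8, 2.0, seed * 10)
            b, _ = pattern_tensor(3, 12, 8, 2.0, seed * 10 + 1)
            pooled = decoding.assemble_pseudopopulation([a, b], seed=seed)
            kw = dict(mode="time_course", n_splits=8, seed=seed)
            accs_single.append(
                max(
                    decoding.nn_classify(a, a, **kw).mean_accuracy,
                    decoding.nn_classify(b, b, **kw).mean_accuracy,
                )
            )
            accs_pooled.append(decoding.nn_classify(pooled, pooled, **kw).mean_accuracy)
        assert np.mean(accs_pooled) >= np.mean(accs_single)


class TestNnClassify:
    def test_noiseless_perfect_both_modes(self):
        t, _ = pattern_tensor(4, 8, 6, 0.0, 0)
        for mode in ("time_course", "time_averaged"):
            res = decoding.nn_classify(t, t, mode=mode, n_splits=5, seed=1)
            assert res.mean_accuracy == 1.0
            assert np.all(np.diag(res.confusion_matrix) == 5)

    def test_pure_noise_chance_level(self):
        # chance oracle: 307 sounds -> accuracy ~ 1/307
        accs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            t = make_tensor(rng.normal(0, 1, (20, 307, 12, 13)))
            res = decoding.nn_classify(t, t, mode="time_course", n_splits=20, seed=seed)
            accs.append(res.mean_accuracy)
        assert np.mean(accs) == pytest.approx(1 / 307, abs=0.0025)

    def test_bruteforce_oracle_equivalence(self):
        # exhaustive nearest-correlation assignment on a tiny instance
        t, _ = pattern_tensor(2, 5, 4, 1.0, 7)
        n_splits = 6
        res = decoding.nn_classify(t, t, mode="time_course", n_splits=n_splits, seed=3)
        confusion = np.zeros((5, 5), dtype=int)
        for tr, te in decoding.split_indices(4, n_splits, 3):
            train = t.values[:, :, tr, :].mean(axis=2)[:, :, 3:]
            test = t.values[:, :, te, :].mean(axis=2)[:, :, 3:]
            for s in range(5):
                best, best_corr = 0, -np.inf
                for c in range(5):
                    r = np.corrcoef(test[:, s].ravel(), train[:, c].ravel())[0, 1]
                    if r > best_corr:
                        best, best_corr = c, r
                confusion[s, best] += 1
        assert np.array_equal(res.confusion_matrix, confusion)

    def test_scaling_invariance(self):
        t, _ = pattern_tensor(4, 10, 6, 1.0, 11)
        scaled = make_tensor(t.values * 37.5)
        a = decoding.nn_classify(t, t, n_splits=10, seed=0)
        b = decoding.nn_classify(scaled, scaled, n_splits=10, seed=0)
        assert np.array_equal(a.confusion_matrix, b.confusion_matrix)

    def test_noise_ladder_monotone(self):
        patterns = np.random.default_rng(0).normal(0, 1, (4, 10, 1, 13))
        accs = []
        for noise in (0.5, 2.0, 8.0):
            t, _ = pattern_tensor(4, 10, 8, noise, 5, patterns=patterns)
            accs.append(decoding.nn_classify(t, t, n_splits=20, seed=1).mean_accuracy)
        assert accs[0] > accs[1] > accs[2]

    def test_zero_variance_guard(self):
        v = np.zeros((2, 4, 6, 13), dtype=np.float32)
        v[:, 1:] = np.random.default_rng(0).normal(0, 1, (2, 3, 6, 13))
        t = make_tensor(v)
        res = decoding.nn_classify(t, t, n_splits=3, seed=0)
        assert np.isfinite(res.mean_accuracy)

    def test_sem_over_sounds(self):
        t, _ = pattern_tensor(3, 8, 6, 1.5, 13)
        res = decoding.nn_classify(t, t, n_splits=10, seed=0)
        s = res.per_sound_accuracy
        assert res.sem_accuracy == pytest.approx(s.std(ddof=1) / np.sqrt(8))

    def test_confusion_rows_sum_to_splits(self):
        t, _ = pattern_tensor(3, 6, 6, 1.0, 17)
        res = decoding.nn_classify(t, t, n_splits=9, seed=0)
        assert np.all(res.confusion_matrix.sum(axis=1) == 9)


class TestCrossState:
    def test_identical_tensors_match_same_state(self):
        t, _ = pattern_tensor(4, 8, 6, 1.0, 0)
        same = decoding.nn_classify(t, t, n_splits=10, seed=5)
        cross = decoding.cross_state_design(t, t, n_splits=10, seed=5)
        assert cross.wake_to_anes.mean_accuracy == same.mean_accuracy

    def test_neuron_permutation_collapses_to_chance(self):
        t, patterns = pattern_tensor(12, 20, 8, 0.3, 1)
        perm = np.random.default_rng(2).permutation(12)
        t2 = make_tensor(t.values[perm])
        t2.unit_ids = t.unit_ids  # identity destroyed but labels aligned
        cross = decoding.cross_state_design(t, t2, n_splits=10, seed=3)
        same = decoding.nn_classify(t, t, n_splits=10, seed=3)
        assert same.mean_accuracy > 0.9
        assert cross.mean_accuracy < 0.2

    def test_unit_mismatch_rejected(self):
        a, _ = pattern_tensor(3, 5, 4, 1.0, 0)
        b, _ = pattern_tensor(3, 5, 4, 1.0, 1)
        b.unit_ids = [9, 10, 11]
        with pytest.raises(InvalidInputError):
            decoding.cross_state_design(a, b)

    def test_no_change_fraction_monotone(self):
        # as the shared (no-change) neuron fraction grows, cross-state
        # accuracy approaches same-state accuracy
        rng = np.random.default_rng(4)
        patterns = rng.normal(0, 1, (12, 15, 1, 13))
        other = rng.normal(0, 1, (12, 15, 1, 13))
        gaps = []
        for n_shared in (2, 6, 12):
            mixed = np.concatenate([patterns[:n_shared], other[n_shared:]], axis=0)
            t1, _ = pattern_tensor(12, 15, 8, 0.5, 5, patterns=patterns)
            t2, _ = pattern_tensor(12, 15, 8, 0.5, 6, patterns=mixed)
            same = decoding.nn_classify(t1, t1, n_splits=10, seed=7).mean_accuracy
            cross = decoding.cross_state_design(t1, t2, n_splits=10, seed=7).mean_accuracy
            gaps.append(same - cross)
        assert gaps[0] > gaps[-1]
        assert gaps[-1] == pytest.approx(0.0, abs=0.1)


class TestCategoryAccuracy:
    def test_perfect_classifier(self):
        t, _ = pattern_tensor(4, 8, 6, 0.0, 0)
        res = decoding.nn_classify(t, t, n_splits=5, seed=1)
        cmap = {i: "a" if i < 4 else "b" for i in range(8)}
        assert decoding.category_accuracy(res, cmap) == {"a": 1.0, "b": 1.0}

    def test_unmapped_sound_rejected(self):
        t, _ = pattern_tensor(2, 4, 4, 1.0, 0)
        res = decoding.nn_classify(t, t, n_splits=2, seed=0)
        with pytest.raises(InvalidInputError):
            decoding.category_accuracy(res, {0: "a"})

    def test_category_sizes_match_battery(self, stimulus_set):
        counts = stimulus_set.category_counts
        assert counts == {
            "pure_tone": 28,
            "ramp": 26,
            "chord": 48,
            "chirp": 20,
            "white_noise": 30,
            "am": 48,
            "complex": 60,
            "decomposition": 47,
        }


class TestBootstrap:
    def test_identical_tensors_centered_on_zero(self):
        t, _ = pattern_tensor(8, 10, 8, 3.5, 0)
        cmap = {i: "a" if i < 5 else "b" for i in range(10)}
        out = decoding.bootstrap_category_difference(
            t, t, cmap, n_boot=30, n_splits=5, seed=1
        )
        for r in out.values():
            assert abs(r.mean) < 0.15
            assert 0.1 <= r.p_value <= 0.9

    def test_degenerate_single_boot(self):
        t, _ = pattern_tensor(4, 6, 6, 1.0, 2)
        cmap = {i: "x" for i in range(6)}
        with pytest.warns(UserWarning):
            out = decoding.bootstrap_category_difference(
                t, t, cmap, n_boot=1, n_splits=3, seed=0
            )
        assert out["x"].p_value in (0.0, 1.0)

    def test_degraded_state_detected(self):
        # category coded well in "wake" but noise-drowned in "anesthesia"
        rng = np.random.default_rng(3)
        patterns = rng.normal(0, 1, (10, 12, 1, 13))
        weak = patterns.copy()
        weak[:, :6] *= 0.05  # category "a" nearly erased in the second state
        t1, _ = pattern_tensor(10, 12, 8, 0.6, 4, patterns=patterns)
        t2, _ = pattern_tensor(10, 12, 8, 0.6, 5, patterns=weak)
        cmap = {i: "a" if i < 6 else "b" for i in range(12)}
        out = decoding.bootstrap_category_difference(
            t1, t2, cmap, n_boot=40, n_splits=5, seed=6
        )
        assert out["a"].mean > 0
        assert out["a"].p_value < 0.05
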