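"""Network forward pass, backprop gradients, batch training and map
prediction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import infarctnet as inf
from infarctnet.mlp import _forward_batch, _gradients
from infarctnet.phantom import CHRONIC


def mse_loss(weights, X, t):
    y, _, _ = _forward_batch(weights, X)
    return np.mean((y - t) ** 2)


def finite_difference_gradients(weights, X, t, h=1e-6):
    """Central-difference oracle for the MSE gradient, one weight at a time."""
    grads = []
    for li, mat in enumerate(weights.matrices):
        g = np.zeros_like(mat)
        for idx in np.ndindex(mat.shape):
            w = weights.copy()
            w.matrices[li][idx] += h
            up = mse_loss(w, X, t)
            w.matrices[li][idx] -= 2 * h
            down = mse_loss(w, X, t)
            g[idx] = (up - down) / (2 * h)
        grads.append(g)
    return grads


def relative_gradient_error(weights, X, t):
    analytic, _ = _gradients(weights, X, t)
    numeric = finite_difference_gradients(weights, X, t)
    num = np.concatenate([a.ravel() for a in analytic])
    ref = np.concatenate([g.ravel() for g in numeric])
    return np.max(np.abs(num - ref)) / max(np.max(np.abs(ref)), 1e-12)


class TestInitWeights:
    def test_parameter_count_4331(self):
        arch = inf.NetworkArchitecture((4, 3, 3, 1))
        assert arch.n_parameters == 31
        assert inf.init_weights(arch, seed=0).n_parameters == 31

    def test_seed_reproducibility(self):
        arch = inf.NetworkArchitecture()
        a = inf.init_weights(arch, seed=3)
        b = inf.init_weights(arch, seed=3)
        for ma, mb in zip(a.matrices, b.matrices):
            np.testing.assert_array_equal(ma, mb)

    def test_scale_bound(self):
        w = inf.init_weights(inf.NetworkArchitecture(), seed=1, scale=0.5)
        assert all(np.abs(m).max() <= 0.5 for m in w.matrices)


class TestForward:
    def test_zero_weights_give_output_midpoint(self):
        arch = inf.NetworkArchitecture()
        w = inf.WeightSet(arch, inf.init_weights(arch, 0).zeros_like())
        y, _ = inf.forward(w, np.ones(4))
        assert y == pytest.approx(1.5)

    def test_toy_network_matches_hand_composition(self):
        # 1:1:1 net, every weight and bias 0.5, input 1.0
        arch = inf.NetworkArchitecture((1, 1, 1))
        w = inf.WeightSet(arch, [np.array([[0.5, 0.5]]), np.array([[0.5, 0.5]])])
        h = np.tanh(0.5 * 1.0 + 0.5)
        expected = 1.5 * (np.tanh(0.5 * h + 0.5) + 1)
        y, _ = inf.forward(w, np.array([1.0]))
        assert y == pytest.approx(expected, abs=1e-12)

    @given(seed=st.integers(0, 1000))
    def test_output_strictly_inside_range(self, seed):
        rng = np.random.default_rng(seed)
        arch = inf.NetworkArchitecture()
        w = inf.init_weights(arch, seed, scale=2.0)
        y, _ = inf.forward(w, rng.uniform(-3, 3, size=(10, 4)))
        assert np.all((y > 0) & (y < 3))

    def test_non_finite_input_rejected(self):
        w = inf.init_weights(inf.NetworkArchitecture(), 0)
        with pytest.raises(ValueError):
            inf.forward(w, np.array([1.0, np.nan, 0.0, 0.0]))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        w = inf.init_weights(inf.NetworkArchitecture(), seed=0)
        X = rng.uniform(0, 2, (10, 4))
        t = rng.uniform(0.3, 2.7, 10)
        assert relative_gradient_error(w, X, t) < 1e-5

    def test_zero_rate_leaves_weights_unchanged(self):
        rng = np.random.default_rng(1)
        w = inf.init_weights(inf.NetworkArchitecture(), seed=1)
        cfg = inf.TrainingConfig(learning_rate=0.0, momentum=0.0)
        X, t = rng.uniform(0, 2, (6, 4)), rng.uniform(0, 3, 6)
        new, mse, _ = inf.batch_epoch(w, X, t, cfg)
        for a, b in zip(new.matrices, w.matrices):
            np.testing.assert_array_equal(a, b)
        assert mse == pytest.approx(mse_loss(w, X, t))

    def test_duplicated_samples_give_identical_update(self):
        rng = np.random.default_rng(2)
        w = inf.init_weights(inf.NetworkArchitecture(), seed=2)
        cfg = inf.TrainingConfig()
        X, t = rng.uniform(0, 2, (5, 4)), rng.uniform(0, 3, 5)
        _, _, u1 = inf.batch_epoch(w, X, t, cfg)
        _, _, u2 = inf.batch_epoch(w, np.tile(X, (2, 1)), np.tile(t, 2), cfg)
        for a, b in zip(u1, u2):
            np.testing.assert_allclose(a, b, atol=1e-14)

    def test_momentum_accumulates_previous_update(self):
        rng = np.random.default_rng(3)
        w = inf.init_weights(inf.NetworkArchitecture(), seed=3)
        cfg = inf.TrainingConfig(momentum=0.9)
        X, t = rng.uniform(0, 2, (5, 4)), rng.uniform(0, 3, 5)
        prev = [np.ones_like(m) for m in w.matrices]
        grads, _ = _gradients(w, X, t)
        _, _, update = inf.batch_epoch(w, X, t, cfg, previous_update=prev)
        for u, g, p in zip(update, grads, prev):
            np.testing.assert_allclose(u, -cfg.learning_rate * g + 0.9 * p)


class TestTrain:
    def test_constant_midpoint_target_is_already_optimal(self):
        arch = inf.NetworkArchitecture()
        zero = inf.WeightSet(arch, inf.init_weights(arch, 0).zeros_like())
        X = np.random.default_rng(0).uniform(0, 2, (20, 4))
        t = np.full(20, 1.5)
        _, trace = inf.train((X, t), arch, inf.TrainingConfig(), initial=zero)
        assert trace.mse[-1] < 1e-4 and trace.converged

    def test_descent_reduces_mse_on_separable_classes(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0.6, 0.05, (40, 4)), rng.normal(1.6, 0.05, (40, 4))])
        t = np.concatenate([np.full(40, 0.5), np.full(40, 2.5)])
        _, trace = inf.train(
            (X, t), config=inf.TrainingConfig(seed=1), n_epochs=200, stop_mse=None
        )
        assert trace.mse[-1] < trace.mse[0]

    def test_deterministic_given_seed(self, small_samples):
        cfg = inf.TrainingConfig(seed=5)
        w1, t1 = inf.train(small_samples, config=cfg, n_epochs=20, stop_mse=None)
        w2, t2 = inf.train(small_samples, config=cfg, n_epochs=20, stop_mse=None)
        np.testing.assert_array_equal(t1.mse, t2.mse)
        for a, b in zip(w1.matrices, w2.matrices):
            np.testing.assert_array_equal(a, b)

    def test_small_rate_mse_non_increasing(self):
        rng = np.random.default_rng(5)
        X, t = rng.uniform(0, 2, (30, 4)), rng.uniform(0.5, 2.5, 30)
        _, trace = inf.train(
            (X, t),
            config=inf.TrainingConfig(learning_rate=1e-4, momentum=0.0, seed=2),
            n_epochs=50, stop_mse=None,
        )
        assert np.all(np.diff(trace.mse) <= 1e-12)

    def test_non_convergence_warns_not_raises(self, caplog):
        rng = np.random.default_rng(6)
        X, t = rng.uniform(0, 2, (20, 4)), rng.uniform(0, 3, 20)
        _, trace = inf.train(
            (X, t), config=inf.TrainingConfig(max_epochs=3, termination_mse=1e-9)
        )
        assert not trace.converged

    def test_json_round_trip(self, tmp_path):
        w = inf.init_weights(inf.NetworkArchitecture(), 7)
        p = tmp_path / "model.json"
        w.to_json(p)
        back = inf.WeightSet.from_json(p)
        for a, b in zip(w.matrices, back.matrices):
            np.testing.assert_array_equal(a, b)


class TestPredictMap:
    def _normalized_study(self, seed=7):
        study = inf.generate_study(seed)
        smoothed = inf.smooth_study(study)
        mask = inf.brain_mask(smoothed)
        return inf.normalize_study(smoothed, mask), mask

    def test_values_match_per_voxel_forward(self):
        study, mask = self._normalized_study()
        w = inf.init_weights(inf.NetworkArchitecture(), 1)
        pred = inf.predict_map(w, study, mask)
        sl, rows, cols = np.nonzero(mask)
        for i in np.linspace(0, len(sl) - 1, 25).astype(int):
            x = [study.images[ch][sl[i], rows[i], cols[i]] for ch in inf.CHANNELS]
            y, _ = inf.forward(w, np.asarray(x))
            assert pred[sl[i], rows[i], cols[i]] == pytest.approx(y, abs=1e-12)

    def test_range_and_background(self):
        study, mask = self._normalized_study()
        w = inf.init_weights(inf.NetworkArchitecture(), 2)
        pred = inf.predict_map(w, study, mask)
        assert np.all(pred[~mask] == 0)
        assert np.all((pred[mask] > 0) & (pred[mask] < 3))

    def test_unnormalized_study_rejected(self):
        study = inf.generate_study(9)
        smoothed = inf.smooth_study(study)
        mask = inf.brain_mask(smoothed)
        w = inf.init_weights(inf.NetworkArchitecture(), 3)
        with pytest.raises(ValueError, match="not normalized"):
            inf.predict_map(w, smoothed, mask)
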