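"""Model assembly: sharing operation, forward contracts, identity reduction,
joint loss, gradient correctness, checkpoint round-trip."""

import numpy as np
import pytest

from neurostitch import ModelConfig, MultiTaskModel, joint_loss, share_features


class TestShareFeatures:
    def test_identity_returns_inputs_exactly(self, rng):
        feats = [rng.standard_normal((4, 3)) for _ in range(3)]
        out = share_features(feats, np.eye(3))
        for o, f in zip(out, feats):
            assert np.array_equal(o, f)

    def test_swap_matrix_swaps_columns(self, rng):
        a, b = rng.standard_normal((5, 2)), rng.standard_normal((5, 2))
        out = share_features([a, b], np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert np.array_equal(out[0], b)
        assert np.array_equal(out[1], a)

    def test_matches_scalar_weighted_sum_oracle(self, rng):
        for _ in range(50):
            d = int(rng.integers(2, 5))
            feats = [rng.standard_normal((3, 4)) for _ in range(d)]
            m = rng.standard_normal((d, d))
            out = share_features(feats, m)
            for k in range(d):
                expected = sum(m[j, k] * feats[j] for j in range(d))
                assert np.allclose(out[k], expected, atol=1e-12)

    def test_zero_entry_removes_cross_task_path(self, rng):
        feats = [rng.standard_normal((2, 2)), rng.standard_normal((2, 2))]
        m = np.array([[1.0, 0.0], [0.0, 1.0]])
        m[0, 1] = 0.0  # no path from task 0 into task 1
        out = share_features(feats, m)
        assert np.array_equal(out[1], feats[1])

    def test_shape_validation(self, rng):
        feats = [rng.standard_normal((2, 2)), rng.standard_normal((2, 2))]
        with pytest.raises(ValueError):
            share_features(feats, np.eye(3))
        with pytest.raises(ValueError):
            share_features([feats[0], rng.standard_normal((3, 2))], np.eye(2))


class TestForward:
    def test_outputs_are_probability_vectors(self, tiny_model, rng):
        x = rng.standard_normal((5, 6, 4))
        for p in tiny_model.forward(x):
            assert p.shape == (5, 2)
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
            assert np.all(p > 0) and np.all(p < 1)

    def test_zero_head_weights_give_uniform_prediction(self, tiny_config, rng):
        model = MultiTaskModel(tiny_config, rng=0)
        for k in list(model.params):
            if k.startswith("head"):
                model.params[k] = np.zeros_like(model.params[k])
        p = model.forward(rng.standard_normal((6, 4)))
        for task_p in p:
            assert np.allclose(task_p, [0.5, 0.5])

    def test_unharmonized_input_rejected(self, tiny_model, rng):
        with pytest.raises(ValueError, match="harmonize"):
            tiny_model.forward(rng.standard_normal((9, 4)))

    def test_tie_predicts_control_class(self, tiny_config, rng):
        model = MultiTaskModel(tiny_config, rng=0)
        for k in list(model.params):
            if k.startswith("head"):
                model.params[k] = np.zeros_like(model.params[k])
        assert model.predict(rng.standard_normal((6, 4)), task=0)[0] == 0


class TestIdentityReduction:
    """With every sharing matrix = I the multi-task forward equals the
    single-column forward with identical weights — the exactness guarantee
    behind the single-task ablation arm."""

    def test_frozen_identity_equals_single_column_bitwise(self, tiny_config, rng):
        model = MultiTaskModel(tiny_config, rng=3, freeze_sharing=True)
        x = rng.standard_normal((4, 6, 4))
        multi = model.forward(x)
        for d in range(tiny_config.D):
            single = model.forward_single_column(x, d)
            assert np.array_equal(multi[d], single)

    def test_near_identity_init_differs_from_single_column(self, tiny_config, rng):
        model = MultiTaskModel(tiny_config, rng=3)  # 0.9/0.1 mixing
        x = rng.standard_normal((6, 4))
        assert not np.allclose(model.forward(x)[0], model.forward_single_column(x, 0))

    def test_manually_set_identity_matrices_reduce_too(self, tiny_config, rng):
        model = MultiTaskModel(tiny_config, rng=5)
        for layer in range(tiny_config.L):
            model.params[f"M{layer}"] = np.eye(tiny_config.D)
        x = rng.standard_normal((3, 6, 4))
        multi = model.forward(x)
        for d in range(tiny_config.D):
            assert np.array_equal(multi[d], model.forward_single_column(x, d))


class TestJointLoss:
    def test_perfect_one_hot_is_zero(self):
        preds = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert joint_loss(preds, np.array([0, 1])) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_predictions_give_m_ln2(self):
        for m in (1, 5, 64):
            preds = np.full((m, 2), 0.5)
            labels = np.arange(m) % 2
            assert joint_loss(preds, labels) == pytest.approx(m * np.log(2), rel=1e-12)

    def test_strictly_increases_as_true_class_probability_drops(self):
        labels = np.array([1, 0, 1])
        base = np.array([[0.2, 0.8], [0.7, 0.3], [0.4, 0.6]])
        prev = joint_loss(base, labels)
        for p1 in (0.5, 0.3, 0.1):
            worse = base.copy()
            worse[0] = [1 - p1, p1]
            cur = joint_loss(worse, labels)
            assert cur > prev
            prev = cur

    def test_clamped_never_infinite(self):
        preds = np.array([[1.0, 0.0]])
        assert np.isfinite(joint_loss(preds, np.array([1])))

    def test_bad_labels_rejected(self):
        with pytest.raises(ValueError):
            joint_loss(np.array([[0.5, 0.5]]), np.array([2]))


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self, tiny_config, rng):
        model = MultiTaskModel(tiny_config, rng=1)
        batches = {
            0: (rng.standard_normal((3, 6, 4)), np.array([0, 1, 1])),
            1: (rng.standard_normal((2, 6, 4)), np.array([1, 0])),
        }
        _, grads, _ = model.loss_and_grads(batches)

        def loss():
            l, _, _ = model.loss_and_grads(batches)
            return l

        eps = 1e-6
        check_rng = np.random.default_rng(9)
        names = list(model.params)
        for _ in range(10):  # random 10-parameter subset
            name = names[check_rng.integers(len(names))]
            arr = model.params[name]
            idx = tuple(int(check_rng.integers(0, s)) for s in arr.shape)
            old = arr[idx]
            arr[idx] = old + eps
            lp = loss()
            arr[idx] = old - eps
            lm = loss()
            arr[idx] = old
            fd = (lp - lm) / (2 * eps)
            an = grads[name][idx]
            assert an == pytest.approx(fd, rel=1e-4, abs=1e-7), name

    def test_frozen_sharing_excluded_from_trainables(self, tiny_config):
        frozen = MultiTaskModel(tiny_config, rng=0, freeze_sharing=True)
        free = MultiTaskModel(tiny_config, rng=0)
        assert not any(k.startswith("M") for k in frozen.trainable_names())
        assert any(k.startswith("M") for k in free.trainable_names())


class TestCheckpoint:
    def test_round_trip_identical_predictions(self, tiny_config, rng, tmp_path):
        model = MultiTaskModel(tiny_config, rng=7)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        loaded = MultiTaskModel.load(path)
        assert loaded.config == model.config
        x = rng.standard_normal((4, 6, 4))
        for a, b in zip(model.forward(x), loaded.forward(x)):
            assert np.array_equal(a, b)
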