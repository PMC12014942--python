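"""CNN regressor: architecture contract, loss arithmetic, backprop
correctness, dataset assembly and small-scale learning."""
import numpy as np
import pytest

from sfdiskin.network import (DEFAULT_TV_WEIGHTS, NetworkConfig,
                              NormalizationSpec, SFDINet, TrainingConfig,
                              _loss_grad, _normalize_inputs,
                              assemble_training_set, build_network, loss,
                              predict, r_squared, total_variation, train)
from sfdiskin.optics import InvalidInputError, param_bounds_arrays


class TestArchitecture:
    def test_shape_and_range_contract(self):
        net = build_network(NetworkConfig(seed=0), n=128)
        y = net.forward(np.zeros((1, 128, 128, 6)))
        assert y.shape == (1, 128, 128, 7)
        assert y.min() >= -1.0 and y.max() <= 1.0

    def test_divisibility_required(self):
        with pytest.raises(InvalidInputError):
            build_network(n=66)
        net = build_network(n=64)
        with pytest.raises(InvalidInputError):
            net.forward(np.zeros((1, 66, 66, 6)))

    def test_seeded_initialization_is_reproducible(self):
        a = SFDINet(NetworkConfig(seed=11))
        b = SFDINet(NetworkConfig(seed=11))
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)
        c = SFDINet(NetworkConfig(seed=12))
        assert any(not np.array_equal(a.params[k], c.params[k])
                   for k in a.params)

    def test_parameter_count_stable(self):
        assert (SFDINet(NetworkConfig(seed=0)).n_parameters
                == SFDINet(NetworkConfig(seed=5)).n_parameters)

    def test_save_load_round_trip(self, tmp_path):
        net = SFDINet(NetworkConfig(seed=3))
        norm = NormalizationSpec()
        prefix = str(tmp_path / "model")
        net.save(prefix, norm=norm)
        net2, norm2 = SFDINet.load(prefix)
        x = np.random.default_rng(0).uniform(0, 1, (1, 16, 16, 6))
        np.testing.assert_array_equal(net.forward(x), net2.forward(x))
        np.testing.assert_array_equal(norm.lower, norm2.lower)


class TestLoss:
    def test_zero_for_exact_constant_prediction(self):
        y = np.full((4, 4, 7), 0.3)
        assert loss(y, y, DEFAULT_TV_WEIGHTS) == 0.0

    def test_hand_value_single_channel_pattern(self):
        """n=2, one channel [[0,1],[0,1]] with weight w: MSE=0, horizontal
        TV |1-0| twice, so loss = 2w / (7*4)."""
        y = np.zeros((2, 2, 7))
        y[..., 0] = [[0, 1], [0, 1]]
        w = np.zeros(7)
        w[0] = 0.35
        assert loss(y, y, w) == pytest.approx(2 * 0.35 / (7 * 4))

    def test_zero_weights_reduce_to_mse(self, rng):
        yhat = rng.uniform(-1, 1, (4, 4, 7))
        y = rng.uniform(-1, 1, (4, 4, 7))
        mse = ((yhat - y) ** 2).mean()
        assert loss(yhat, y, np.zeros(7)) == pytest.approx(mse)
        assert loss(yhat, y, None) == pytest.approx(mse)

    def test_decomposition_and_tv_independence_of_target(self, rng):
        yhat = rng.uniform(-1, 1, (8, 8, 7))
        y1 = rng.uniform(-1, 1, (8, 8, 7))
        y2 = rng.uniform(-1, 1, (8, 8, 7))
        w = np.asarray(DEFAULT_TV_WEIGHTS) * 1e3
        tv1 = loss(yhat, y1, w) - loss(yhat, y1, None)
        tv2 = loss(yhat, y2, w) - loss(yhat, y2, None)
        assert tv1 == pytest.approx(tv2, rel=1e-10)
        assert tv1 == pytest.approx(total_variation(yhat, w), rel=1e-10)

    def test_tv_translation_invariance(self, rng):
        yhat = rng.uniform(-0.5, 0.5, (6, 6, 7))
        w = np.ones(7)
        assert total_variation(yhat + 0.3, w) == pytest.approx(
            total_variation(yhat, w), rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            loss(np.zeros((4, 4, 7)), np.zeros((4, 8, 7)))


class TestBackprop:
    def test_gradients_match_finite_differences(self, rng):
        cfg = NetworkConfig(enc_channels=(3, 4, 5), dec_channels=(4, 3),
                            kernel_size=3, seed=0)
        net = SFDINet(cfg)
        net.params = {k: v.astype(np.float64) for k, v in net.params.items()}
        x = rng.uniform(0, 1, (2, 8, 8, 6))
        y = rng.uniform(-0.5, 0.5, (2, 8, 8, 7))
        w = np.full(7, 1e-3)
        yhat, cache = net.forward(x, want_cache=True)
        grads = net.backward(cache, _loss_grad(yhat, y, w))
        eps = 1e-6
        for name in ("enc1a_W", "bota_W", "up1_W", "dec2b_W", "out_W",
                     "out_b"):
            p = net.params[name]
            it = np.ndindex(*p.shape)
            for _ in range(2):
                idx = next(it)
                orig = p[idx]
                p[idx] = orig + eps
                lp = loss(net.forward(x), y, w)
                p[idx] = orig - eps
                lm = loss(net.forward(x), y, w)
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[name][idx] == pytest.approx(num, rel=1e-4,
                                                         abs=1e-10)


class TestRSquared:
    def test_perfect_prediction(self):
        y = np.arange(12.0).reshape(4, 3)
        assert r_squared(y, y) == 1.0

    def test_mean_prediction_scores_zero(self):
        y = np.arange(12.0).reshape(-1, 1)
        yhat = np.full_like(y, y.mean())
        assert r_squared(y, yhat) == pytest.approx(0.0)

    def test_hand_value(self):
        y = np.array([[1.0], [2.0], [3.0]])
        yhat = np.array([[1.0], [2.0], [4.0]])
        assert r_squared(y, yhat) == pytest.approx(0.5)

    def test_constant_truth_rejected(self):
        with pytest.raises(InvalidInputError):
            r_squared(np.ones((4, 1)), np.zeros((4, 1)))


class TestNormalization:
    def test_round_trip(self, rng):
        spec = NormalizationSpec()
        lo, hi = param_bounds_arrays()
        x = rng.uniform(lo, hi, (5, 5, 7))
        np.testing.assert_allclose(spec.denormalize(spec.normalize(x)), x,
                                   atol=1e-12)

    def test_bounds_map_to_unit_interval(self):
        spec = NormalizationSpec()
        np.testing.assert_allclose(spec.normalize(spec.lower), -1.0)
        np.testing.assert_allclose(spec.normalize(spec.upper), 1.0)


class TestAssembleTrainingSet:
    def _pairs(self, rng, n_pairs, n=8):
        lo, hi = param_bounds_arrays()
        out = []
        for i in range(n_pairs):
            m = rng.uniform(0.1, 0.7, (n, n, 6)) + i % 4  # 4 separated groups
            p = rng.uniform(lo, hi, (n, n, 7))
            out.append((m, p))
        return out

    def test_balanced_sampling_from_identical_groups(self, rng):
        pairs = self._pairs(rng, 20)
        X, Y, idx, flags = assemble_training_set(pairs, k=4, per_cluster=3,
                                                 seed=0)
        assert X.shape == (12, 8, 8, 6) and Y.shape == (12, 8, 8, 7)
        # three draws from each of the four separated groups
        groups = [i % 4 for i in idx]
        assert sorted(set(groups)) == [0, 1, 2, 3]
        assert all(groups.count(g) == 3 for g in range(4))

    def test_small_cluster_sampled_with_replacement_and_flagged(self, rng):
        pairs = self._pairs(rng, 8)
        X, Y, idx, flags = assemble_training_set(pairs, k=4, per_cluster=5,
                                                 seed=0)
        assert X.shape[0] == 20
        assert flags.all()  # every cluster has 2 < 5 members

    def test_requires_enough_pairs(self, rng):
        with pytest.raises(InvalidInputError):
            assemble_training_set(self._pairs(rng, 3), k=5)


class TestTraining:
    def _tiny_dataset(self, rng, n_pairs=12, n=16):
        lo, hi = param_bounds_arrays()
        X = rng.uniform(0.05, 0.7, (n_pairs, n, n, 6))
        # a learnable linear-ish relation: targets derived from inputs
        Y = lo + (X.mean(axis=-1, keepdims=True)
                  * np.linspace(0.5, 1.4, 7)) % 1.0 * (hi - lo)
        return X.astype(np.float32), Y

    def test_loss_decreases_on_learnable_data(self, rng):
        X, Y = self._tiny_dataset(rng)
        net = SFDINet(NetworkConfig(seed=0))
        net, hist = train(net, (X, Y),
                          TrainingConfig(epochs=15, seed=0,
                                         tv_weights=(0.0,) * 7))
        assert hist["train_loss"][-1] < hist["train_loss"][0]
        assert len(hist["val_loss"]) == 15

    def test_single_pair_memorization(self, rng):
        X, Y = self._tiny_dataset(rng, n_pairs=1)
        net = SFDINet(NetworkConfig(seed=0))
        norm = NormalizationSpec()
        net, hist = train(net, (X, Y),
                          TrainingConfig(epochs=60, seed=0,
                                         tv_weights=(0.0,) * 7), norm)
        yhat = net.forward(_normalize_inputs(X))
        mse = float(((yhat - norm.normalize(Y)) ** 2).mean())
        assert mse < 0.05  # near-memorization of one example

    def test_same_seed_identical_history(self, rng):
        X, Y = self._tiny_dataset(rng, n_pairs=8, n=8)
        h = []
        for _ in range(2):
            net = SFDINet(NetworkConfig(seed=4))
            _, hist = train(net, (X, Y), TrainingConfig(epochs=5, seed=4))
            h.append(hist["train_loss"])
        assert h[0] == h[1]


class TestKFold:
    def test_returns_one_score_per_fold_and_is_seeded(self, rng):
        lo, hi = param_bounds_arrays()
        X = rng.uniform(0.05, 0.7, (9, 8, 8, 6)).astype(np.float32)
        Y = np.broadcast_to(lo + 0.5 * (hi - lo), (9, 8, 8, 7)).copy()
        Y += rng.uniform(-0.05, 0.05, Y.shape) * (hi - lo)
        from sfdiskin.network import kfold_validate
        tcfg = TrainingConfig(epochs=2, seed=0, tv_weights=(0.0,) * 7)
        s1 = kfold_validate((X, Y), k=3, tcfg=tcfg)
        s2 = kfold_validate((X, Y), k=3, tcfg=tcfg)
        assert len(s1) == 3
        assert s1 == s2

    def test_invalid_k_rejected(self, rng):
        X = rng.uniform(0, 1, (4, 8, 8, 6))
        Y = rng.uniform(0, 1, (4, 8, 8, 7))
        from sfdiskin.network import kfold_validate
        with pytest.raises(InvalidInputError):
            kfold_validate((X, Y), k=1)


class TestPredict:
    def test_outputs_inside_physical_bounds(self, rng):
        net = SFDINet(NetworkConfig(seed=0))
        lo, hi = param_bounds_arrays()
        maps = predict(net, rng.uniform(0, 1, (16, 16, 6)))
        assert np.all(maps.data >= lo) and np.all(maps.data <= hi)

    def test_deterministic_inference(self, rng):
        net = SFDINet(NetworkConfig(seed=0))
        x = rng.uniform(0, 1, (16, 16, 6))
        np.testing.assert_array_equal(predict(net, x).data,
                                      predict(net, x).data)
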