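"""Residual U-Net: autodiff gradients, loss algebra, training behaviour."""

import numpy as np
import pytest

from snapmosaic import (
    CalibrationMatrix,
    Hypercube,
    LossConfig,
    NetworkConfig,
    TrainConfig,
    TrainingBatch,
    build_network,
    infer,
    total_loss,
    train,
)
from snapmosaic.phantom import PhantomSpec, make_dataset
from snapmosaic.superres import (
    PerceptualFeatures,
    Tensor,
    _augment,
    apply_matrix,
    avgpool2,
    concat,
    conv2d,
    leaky_relu,
    mean_abs,
    mean_sq,
    sub,
    upsample2,
)


class TestAutodiff:
    def _check(self, forward, tensors, eps=1e-2, tol=5e-2):
        """Central finite differences against backpropagated gradients."""
        loss = forward()
        loss.backward()
        rng = np.random.default_rng(0)
        for t in tensors:
            g = t.grad.copy()
            for _ in range(5):
                ix = tuple(rng.integers(0, s) for s in t.data.shape)
                orig = t.data[ix]
                t.data[ix] = orig + eps
                lp = float(forward().data)
                t.data[ix] = orig - eps
                lm = float(forward().data)
                t.data[ix] = orig
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - g[ix]) <= tol * (abs(fd) + abs(g[ix])) + 1e-4

    def test_conv_chain_gradients(self):
        rng = np.random.default_rng(1)
        x = Tensor(rng.normal(size=(2, 3, 8, 8)), requires_grad=True)
        w = Tensor(rng.normal(size=(4, 3, 3, 3)) * 0.3, requires_grad=True)
        b = Tensor(rng.normal(size=4) * 0.1, requires_grad=True)
        cmat = rng.normal(size=(2, 4))
        y = rng.normal(size=(2, 2, 4, 4)).astype(np.float32)

        def forward():
            h = leaky_relu(conv2d(x, w, b))
            h = avgpool2(h)
            return mean_sq(sub(Tensor(y), apply_matrix(cmat, h)))

        self._check(forward, [x, w, b])

    def test_upsample_concat_gradients(self):
        rng = np.random.default_rng(2)
        x = Tensor(rng.normal(size=(1, 2, 4, 4)), requires_grad=True)
        y = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)

        def forward():
            up = upsample2(x)
            both = concat(up, up)
            return mean_abs(sub(Tensor(y), both))

        self._check(forward, [x])

    def test_unet_parameter_gradients_flow(self):
        cfg = NetworkConfig(channels=3, depth=1, res_blocks=1, base_width=4, seed=0)
        net = build_network(cfg)
        rng = np.random.default_rng(3)
        x = Tensor(rng.normal(size=(1, 3, 8, 8)))
        tgt = rng.normal(size=(1, 3, 8, 8)).astype(np.float32)
        loss = mean_sq(sub(Tensor(tgt), net.forward(x)))
        loss.backward()
        grads = [p.grad for p in net.params]
        assert all(g is not None for g in grads)
        # the head is zero-initialised, but its own gradient must be live
        assert any(np.abs(g).max() > 0 for g in grads)


class TestNetwork:
    def test_output_shape_matches_input(self):
        cfg = NetworkConfig(channels=16, depth=2, res_blocks=1, base_width=8, seed=0)
        net = build_network(cfg)
        x = Tensor(np.random.default_rng(4).random((1, 16, 64, 64)))
        assert net.forward(x).data.shape == (1, 16, 64, 64)

    def test_same_seed_same_parameters(self):
        cfg = NetworkConfig(channels=4, depth=2, res_blocks=2, base_width=8, seed=11)
        a, b = build_network(cfg), build_network(cfg)
        assert a.parameter_count() == b.parameter_count()
        for pa, pb in zip(a.params, b.params):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_untrained_network_is_identity(self):
        # zero-initialised head: the fresh network reproduces its input
        cfg = NetworkConfig(channels=4, depth=2, res_blocks=1, base_width=8, seed=0)
        net = build_network(cfg)
        x = np.random.default_rng(5).random((1, 4, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(net.forward(Tensor(x)).data, x)

    def test_depth_4_bottleneck_is_16x_smaller(self):
        cfg = NetworkConfig(channels=2, depth=4, res_blocks=1, base_width=2, seed=0)
        net = build_network(cfg)
        captured = {}
        import snapmosaic.superres as sr

        orig = sr.avgpool2

        def spy(x):
            out = orig(x)
            captured["smallest"] = min(
                captured.get("smallest", 1e9), out.data.shape[2]
            )
            return out

        sr.avgpool2 = spy
        try:
            net.forward(Tensor(np.zeros((1, 2, 32, 32), np.float32)))
        finally:
            sr.avgpool2 = orig
        assert captured["smallest"] == 32 // 16

    def test_indivisible_dims_rejected(self):
        cfg = NetworkConfig(channels=2, depth=2, res_blocks=1, base_width=4, seed=0)
        net = build_network(cfg)
        with pytest.raises(ValueError):
            net.forward(Tensor(np.zeros((1, 2, 10, 12), np.float32)))


class TestLoss:
    def _toy_batch(self, yhat, ys, yi, c):
        return TrainingBatch(Tensor(yhat), ys, yi, CalibrationMatrix(c))

    def test_zero_when_targets_met(self):
        ys = np.ones((1, 2, 2, 2), np.float32)
        c = np.array([[0.5, 0.5]])
        yi = np.ones((1, 1, 2, 2), np.float32)
        batch = self._toy_batch(ys.copy(), ys, yi, c)
        assert float(total_loss(batch, LossConfig(mode="l1")).data) == 0.0

    def test_gamma_zero_is_main_term_only(self):
        rng = np.random.default_rng(6)
        yhat = rng.random((1, 2, 4, 4)).astype(np.float32)
        ys = rng.random((1, 2, 4, 4)).astype(np.float32)
        yi = rng.random((1, 1, 4, 4)).astype(np.float32)
        c = np.array([[0.3, 0.7]])
        batch = self._toy_batch(yhat, ys, yi, c)
        main = np.mean(np.abs(yi - np.einsum("oc,nchw->nohw", c, yhat)))
        got = float(total_loss(batch, LossConfig(mode="l1", gamma=0.0)).data)
        assert got == pytest.approx(main, rel=1e-6)

    def test_hand_computed_toy_value(self):
        # yi=[1], C=[[0.5, 0.5]], yhat=[0,0], ys=yhat -> loss = |1 - 0| = 1
        yhat = np.zeros((1, 2, 1, 1), np.float32)
        yi = np.ones((1, 1, 1, 1), np.float32)
        batch = self._toy_batch(yhat, yhat.copy(), yi, np.array([[0.5, 0.5]]))
        assert float(total_loss(batch, LossConfig(mode="l1")).data) == 1.0

    def test_perceptual_decomposition_identity(self):
        rng = np.random.default_rng(7)
        yhat = rng.random((1, 3, 8, 8)).astype(np.float32)
        ys = rng.random((1, 3, 8, 8)).astype(np.float32)
        yi = rng.random((1, 2, 8, 8)).astype(np.float32)
        c = rng.random((2, 3))
        phi = PerceptualFeatures(width=4, seed=3)
        gamma = 0.25
        batch = self._toy_batch(yhat, ys, yi, c)
        full = float(total_loss(
            batch, LossConfig("perceptual", gamma, phi)).data)
        main = float(total_loss(
            batch, LossConfig("perceptual", 0.0, phi)).data)
        unit = float(total_loss(
            batch, LossConfig("perceptual", 1.0, phi)).data)
        feature_term = unit - main
        assert full - main == pytest.approx(gamma * feature_term, rel=1e-4)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(gamma=-0.1)


@pytest.fixture(scope="module")
def tiny_dataset(sensor):
    spec = PhantomSpec(shape=(32, 32), n_bands=80, seed=21)
    splits, _ = make_dataset(spec, sensor, 4, split=(0.5, 0.25, 0.25))
    return splits


class TestTraining:
    def test_overfit_descent(self, sensor, tiny_dataset):
        cfg = NetworkConfig(channels=16, depth=2, res_blocks=1, base_width=8, seed=0)
        tc = TrainConfig(patch=32, batch=2, lr=1e-3, iterations=200,
                         eval_every=100, augment=False, seed=0)
        model = train(tiny_dataset["train"], tiny_dataset["val"], cfg,
                      LossConfig(gamma=0.0), tc, calibration=sensor.calibration)
        h = model.history["train_loss"]
        assert np.mean(h[-10:]) < h[0]

    def test_reproducible_given_seed(self, sensor, tiny_dataset):
        cfg = NetworkConfig(channels=16, depth=2, res_blocks=1, base_width=4, seed=1)
        tc = TrainConfig(patch=32, batch=1, lr=1e-3, iterations=6,
                         eval_every=3, augment=False, seed=5)
        runs = [
            train(tiny_dataset["train"], tiny_dataset["val"], cfg,
                  LossConfig(), tc, calibration=sensor.calibration)
            for _ in range(2)
        ]
        assert runs[0].history["train_loss"] == runs[1].history["train_loss"]

    def test_empty_dataset_rejected(self, sensor, tiny_dataset):
        cfg = NetworkConfig(channels=16, depth=1, res_blocks=1, base_width=4, seed=0)
        with pytest.raises(ValueError):
            train([], tiny_dataset["val"], cfg)

    def test_best_checkpoint_selected(self, sensor, tiny_dataset):
        cfg = NetworkConfig(channels=16, depth=1, res_blocks=1, base_width=4, seed=0)
        tc = TrainConfig(patch=32, batch=1, lr=1e-3, iterations=10,
                         eval_every=5, augment=False, seed=0)
        model = train(tiny_dataset["train"], tiny_dataset["val"], cfg,
                      LossConfig(), tc, calibration=sensor.calibration)
        assert model.history["best_val_loss"] == min(model.history["val_loss"])


class TestInfer:
    def test_shape_and_padding(self, sensor, tiny_dataset):
        from snapmosaic import bilinear_demosaick

        cfg = NetworkConfig(channels=16, depth=2, res_blocks=1, base_width=4, seed=0)
        tc = TrainConfig(patch=32, batch=1, lr=1e-3, iterations=2,
                         eval_every=1, augment=False, seed=0)
        model = train(tiny_dataset["train"], tiny_dataset["val"], cfg,
                      LossConfig(), tc, calibration=sensor.calibration)
        sample = tiny_dataset["test"][0]
        interp = bilinear_demosaick(sample.snapshot)
        interp = Hypercube(interp.data[:30, :27],
                           sensor.measured.band_centers(), "intermediate")
        out = infer(model, interp, sensor.calibration,
                    sensor.ideal.band_centers())
        assert out.shape == (30, 27, 13)

    def test_deterministic(self, sensor, tiny_dataset):
        from snapmosaic import bilinear_demosaick

        cfg = NetworkConfig(channels=16, depth=2, res_blocks=1, base_width=4, seed=0)
        tc = TrainConfig(patch=32, batch=1, lr=1e-3, iterations=2,
                         eval_every=1, augment=False, seed=0)
        model = train(tiny_dataset["train"], tiny_dataset["val"], cfg,
                      LossConfig(), tc, calibration=sensor.calibration)
        sample = tiny_dataset["test"][0]
        interp = bilinear_demosaick(sample.snapshot)
        interp = Hypercube(interp.data, sensor.measured.band_centers(),
                           "intermediate")
        a = infer(model, interp, sensor.calibration)
        b = infer(model, interp, sensor.calibration)
        np.testing.assert_array_equal(a.data, b.data)

    def test_fresh_network_reduces_to_linear_pipeline(self, sensor, tiny_dataset):
        # untrained (identity) network + C == the linear baseline
        from snapmosaic import bilinear_demosaick, linear_pipeline
        from snapmosaic.superres import TrainedModel

        cfg = NetworkConfig(channels=16, depth=2, res_blocks=1, base_width=4, seed=0)
        model = TrainedModel(build_network(cfg), 1.0, sensor.calibration)
        sample = tiny_dataset["test"][0]
        interp = bilinear_demosaick(sample.snapshot)
        interp = Hypercube(interp.data, sensor.measured.band_centers(),
                           "intermediate")
        out = infer(model, interp, sensor.calibration,
                    sensor.ideal.band_centers())
        baseline = linear_pipeline(sample.snapshot, sensor)
        np.testing.assert_allclose(out.data, baseline.data, atol=1e-5)


class TestAugmentation:
    def test_rotation_preserves_per_band_histograms(self):
        rng = np.random.default_rng(8)
        arrs = [rng.random((5, 12, 12)).astype(np.float32) for _ in range(3)]
        out = _augment(arrs, np.random.default_rng(3))
        for a, b in zip(arrs, out):
            assert b.shape == a.shape
            for band in range(a.shape[0]):
                np.testing.assert_array_equal(
                    np.sort(a[band].ravel()), np.sort(b[band].ravel())
                )
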