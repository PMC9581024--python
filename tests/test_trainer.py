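import logging

import numpy as np
import pytest

from smlmfit.geometry import normalise_cloud
from smlmfit.renderer import RenderConfig
from smlmfit.simulator import NoiseConfig, make_dataset, make_parametric_model
from smlmfit.trainer import (
    NetworkSpec,
    PoseNet,
    SigmaSchedule,
    TrainConfig,
    masked_l1,
    masked_l1_with_grad,
    predict,
    train,
    train_direct,
)
from smlmfit.trainer.layers import Adam, Conv2d, Flatten, LeakyReLU, Linear
from smlmfit.trainer.train import _sample_loss_and_grads, evaluate_loss


@pytest.fixture(scope="module")
def tiny_dataset():
    """Small noise-free dataset on a 32px frame for smoke-level training."""
    model = normalise_cloud(make_parametric_model("random_blob", n_points=30, seed=1))
    rng = np.random.default_rng(0)
    ds = make_dataset(model, 96, 1, NoiseConfig(), 3.0, rng, RenderConfig(32, 32))
    return model, ds


TINY_SPEC = NetworkSpec(image_size=32, n_conv=6, base_channels=4, fc_hidden=(32,))


class TestSigmaSchedule:
    def test_boundaries(self):
        s = SigmaSchedule(sigma_start=10.0, sigma_floor=3.2, epochs=40)
        assert s.sigma_at_epoch(0) == pytest.approx(10.0)
        assert s.sigma_at_epoch(39) == pytest.approx(3.2, rel=0.01)

    def test_non_increasing_piecewise_constant(self):
        s = SigmaSchedule(sigma_start=8.0, sigma_floor=2.0, epochs=12)
        vals = s.values()
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_cep152_floor(self):
        assert SigmaSchedule.cep152().sigma_floor == pytest.approx(3.2)

    def test_out_of_range_epoch(self):
        s = SigmaSchedule(epochs=5)
        with pytest.raises(ValueError):
            s.sigma_at_epoch(5)
        with pytest.raises(ValueError):
            s.sigma_at_epoch(-1)

    def test_validation(self):
        with pytest.raises(ValueError):
            SigmaSchedule(sigma_start=1.0, sigma_floor=2.0)
        with pytest.raises(ValueError):
            SigmaSchedule(sigma_floor=0.0, sigma_start=1.0)


class TestMaskedL1:
    def test_identical_images(self, rng):
        img = rng.uniform(size=(8, 8))
        assert masked_l1(img, img) == 0.0

    def test_hand_computed_example(self):
        target = np.array([[1.0, 0.0], [0.0, 0.0]])
        pred = np.array([[0.5, 0.2], [0.0, 0.0]])
        # mask covers only the 1.0 pixel; the 0.2 lies outside it
        assert masked_l1(pred, target) == pytest.approx(0.5)

    def test_invariant_outside_mask(self, rng):
        target = np.zeros((6, 6))
        target[2, 2] = 1.0
        pred = rng.uniform(size=(6, 6))
        base = masked_l1(pred, target)
        pred2 = pred.copy()
        pred2[0, :] += 100.0
        assert masked_l1(pred2, target) == base

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            masked_l1(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_gradient_is_masked_sign(self):
        target = np.array([[1.0, 0.0], [0.0, 0.0]])
        pred = np.array([[0.5, 0.2], [0.3, 0.0]])
        _, g = masked_l1_with_grad(pred, target)
        np.testing.assert_array_equal(g, [[-1.0, 0.0], [0.0, 0.0]])


class TestLayers:
    def test_conv_gradcheck(self, rng):
        for stride in (1, 2):
            conv = Conv2d(2, 3, stride, rng)
            x = rng.normal(size=(2, 2, 8, 8))
            y = conv.forward(x)
            g = rng.normal(size=y.shape)
            conv.w.zero_grad()
            dx = conv.backward(g)
            h = 1e-6
            for _ in range(5):
                i = tuple(int(rng.integers(0, s)) for s in x.shape)
                x1, x2 = x.copy(), x.copy()
                x1[i] += h
                x2[i] -= h
                fd = ((conv.forward(x1) - conv.forward(x2)) * g).sum() / (2 * h)
                assert dx[i] == pytest.approx(fd, rel=1e-5, abs=1e-8)
            wi = (0, 1, 2, 0)
            w0 = conv.w.value[wi]
            conv.w.value[wi] = w0 + h
            y1 = conv.forward(x)
            conv.w.value[wi] = w0 - h
            y2 = conv.forward(x)
            conv.w.value[wi] = w0
            fd = ((y1 - y2) * g).sum() / (2 * h)
            assert conv.w.grad[wi] == pytest.approx(fd, rel=1e-5)

    def test_linear_gradcheck(self, rng):
        lin = Linear(6, 4, rng)
        x = rng.normal(size=(3, 6))
        g = rng.normal(size=(3, 4))
        lin.forward(x)
        lin.w.zero_grad()
        dx = lin.backward(g)
        np.testing.assert_allclose(dx, g @ lin.w.value, atol=1e-12)
        np.testing.assert_allclose(lin.w.grad, g.T @ x, atol=1e-12)

    def test_leaky_relu(self):
        lr = LeakyReLU(0.1)
        x = np.array([-2.0, 3.0])
        np.testing.assert_allclose(lr.forward(x), [-0.2, 3.0])
        np.testing.assert_allclose(lr.backward(np.ones(2)), [0.1, 1.0])

    def test_flatten_roundtrip(self, rng):
        f = Flatten()
        x = rng.normal(size=(2, 3, 4, 4))
        y = f.forward(x)
        assert y.shape == (2, 48)
        np.testing.assert_array_equal(f.backward(y), x)

    def test_adam_decreases_quadratic(self):
        from smlmfit.trainer.layers import Param

        p = Param(np.array([5.0]))
        opt = Adam([p], lr=0.1)
        for _ in range(200):
            p.zero_grad()
            p.grad += 2 * p.value
            opt.step()
        assert abs(p.value[0]) < 0.1


class TestNetworkSpec:
    def test_output_dimension_fixed_at_six(self):
        with pytest.raises(ValueError):
            NetworkSpec(out_dim=5)

    def test_strides_reduce_to_one(self):
        for size in (32, 64, 128):
            spec = NetworkSpec(image_size=size)
            out = size
            for s in spec.strides():
                out = out // s if s == 2 else out
            assert out == 1
            assert len(spec.strides()) == spec.n_conv

    def test_channels_double_every_other_layer(self):
        ch = NetworkSpec().channels()
        assert ch[0] == 16 and ch[-1] == 512 and len(ch) == 10


class TestPredict:
    def test_shape_contract_and_positive_sigma(self, rng):
        net = PoseNet(TINY_SPEC, rng)
        images = rng.uniform(size=(4, 32, 32))
        preds = predict(net, images)
        assert len(preds) == 4
        for p in preds:
            assert p.pose.rot.shape == (3,) and p.pose.trans.shape == (2,)
            assert p.output_sigma > 0

    def test_eval_determinism(self, rng):
        net = PoseNet(TINY_SPEC, rng)
        img = rng.uniform(size=(1, 32, 32))
        a = predict(net, img)[0]
        b = predict(net, img)[0]
        np.testing.assert_array_equal(a.pose.rot, b.pose.rot)
        assert a.output_sigma == b.output_sigma

    def test_unnormalised_input_warns(self, rng, caplog):
        net = PoseNet(TINY_SPEC, rng)
        img = rng.uniform(size=(1, 32, 32))  # sums nowhere near 100
        with caplog.at_level(logging.WARNING, logger="smlmfit.trainer.network"):
            predict(net, img, normalisation_scalar=100.0)
        assert any("not normalised" in r.message for r in caplog.records)


class TestEndToEndGradient:
    def test_model_matrix_gradient_matches_finite_differences(self, rng):
        # masked_l1 o normalise o splat o transform_project on a 5-point toy
        from smlmfit.geometry import Pose, transform_project
        from smlmfit.renderer import normalise_image, splat

        rc = RenderConfig(32, 32)
        cfg = TrainConfig(model_size=5, epochs=1)
        verts = rng.uniform(-0.5, 0.5, size=(5, 3))
        rot = rng.normal(size=3)
        trans = rng.uniform(-0.2, 0.2, size=2)
        tgt = normalise_image(
            splat(
                transform_project(rng.uniform(-0.5, 0.5, size=(5, 3)), Pose(rng.normal(size=3))),
                2.0,
                rc,
            ),
            cfg.normalisation_scalar,
        ).pixels

        _, gv, _, _, _ = _sample_loss_and_grads(verts, rot, trans, 2.0, tgt, cfg, rc)

        def loss_of(v):
            return _sample_loss_and_grads(v, rot, trans, 2.0, tgt, cfg, rc)[0]

        h = 1e-6
        for i in range(5):
            for j in range(3):
                v1, v2 = verts.copy(), verts.copy()
                v1[i, j] += h
                v2[i, j] -= h
                fd = (loss_of(v1) - loss_of(v2)) / (2 * h)
                assert gv[i, j] == pytest.approx(fd, rel=1e-5, abs=1e-7)


class TestTrain:
    def test_losses_finite_and_decreasing(self, tiny_dataset):
        # constant sigma so per-epoch losses are directly comparable
        _, ds = tiny_dataset
        cfg = TrainConfig(
            model_size=30, epochs=3, batch_size=32, seed=3, verts_learning_rate=0.002
        )
        sched = SigmaSchedule(sigma_start=3.0, sigma_floor=3.0, epochs=3)
        res = train(ds, TINY_SPEC, cfg, sched)
        losses = [t for t, _ in res.trace]
        assert all(np.isfinite(losses))
        assert losses[-1] < losses[0]

    def test_seed_reproducibility(self, tiny_dataset):
        _, ds = tiny_dataset
        cfg = TrainConfig(model_size=10, epochs=1, seed=4)
        sched = SigmaSchedule(sigma_start=3.0, sigma_floor=3.0, epochs=1)
        a = train(ds, TINY_SPEC, cfg, sched)
        b = train(ds, TINY_SPEC, cfg, sched)
        np.testing.assert_array_equal(a.reconstruction.vertices, b.reconstruction.vertices)

    @pytest.mark.parametrize("model_size", [100, 350, 1000])
    def test_model_matrix_sizes_train(self, tiny_dataset, model_size):
        _, ds = tiny_dataset
        cfg = TrainConfig(model_size=model_size, epochs=1, seed=5)
        sched = SigmaSchedule(sigma_start=3.0, sigma_floor=3.0, epochs=1)
        res = train(ds, TINY_SPEC, cfg, sched, max_steps_per_epoch=2)
        assert res.reconstruction.vertices.shape == (model_size, 3)
        assert np.isfinite(res.trace[0][0])

    def test_partial_epoch_beats_untrained_on_held_out(self, tiny_dataset):
        # information sharing: even half an epoch helps on unseen samples
        _, ds = tiny_dataset
        cfg = TrainConfig(model_size=30, epochs=1, batch_size=16, seed=6, test_fraction=0.25)
        sched = SigmaSchedule(sigma_start=3.0, sigma_floor=3.0, epochs=1)
        rc = ds.render_config

        rng = np.random.default_rng(cfg.seed)
        untrained = PoseNet(TINY_SPEC, rng, dtype=np.dtype(cfg.dtype))
        untrained.sigma_ref = sched.sigma_start
        verts0 = rng.uniform(-0.5, 0.5, size=(cfg.model_size, 3))
        from smlmfit.trainer.train import _split_indices

        _, test_idx = _split_indices(ds, cfg.test_fraction, np.random.default_rng(cfg.seed + 99))
        loss_untrained = evaluate_loss(untrained, ds, test_idx, 3.0, cfg, verts0, rc)

        res = train(ds, TINY_SPEC, cfg, sched, max_steps_per_epoch=3)
        loss_half = evaluate_loss(
            res.net, ds, test_idx, 3.0, cfg, res.reconstruction.vertices, rc
        )
        assert loss_half < loss_untrained

    def test_normalisation_invariance(self, tiny_dataset):
        # scaling every raw target image leaves the trajectory unchanged
        import copy

        _, ds = tiny_dataset
        cfg = TrainConfig(model_size=10, epochs=1, seed=7)
        sched = SigmaSchedule(sigma_start=3.0, sigma_floor=3.0, epochs=1)
        scaled = copy.copy(ds)
        scaled.intensity_scale = 7.5
        a = train(ds, TINY_SPEC, cfg, sched, max_steps_per_epoch=3)
        b = train(scaled, TINY_SPEC, cfg, sched, max_steps_per_epoch=3)
        np.testing.assert_allclose(
            a.reconstruction.vertices, b.reconstruction.vertices, atol=1e-9
        )

    def test_short_schedule_rejected(self, tiny_dataset):
        _, ds = tiny_dataset
        cfg = TrainConfig(model_size=10, epochs=2, seed=8)
        with pytest.raises(ValueError):
            train(ds, TINY_SPEC, cfg, SigmaSchedule(epochs=1))


class TestScaledRecoveryExamples:
    def test_recovery_below_random_baseline(self, recovery_run):
        # 100-point model, 64px, 2,000 samples, 10 epochs, no noise
        assert recovery_run["cnn_rmsd"] < recovery_run["baseline"]

    def test_direct_ablation_worse_than_cnn(self, recovery_run):
        assert recovery_run["direct_rmsd"] > recovery_run["cnn_rmsd"]


class TestTrainDirect:
    def test_pose_table_shape_and_reproducibility(self, tiny_dataset):
        _, ds = tiny_dataset
        cfg = TrainConfig(model_size=10, epochs=1, seed=9)
        sched = SigmaSchedule(sigma_start=3.0, sigma_floor=3.0, epochs=1)
        a = train_direct(ds, cfg, sched)
        assert a.pose_table.shape == (len(ds), 5)
        assert a.pose_table.size == 5 * len(ds)
        b = train_direct(ds, cfg, sched)
        np.testing.assert_array_equal(a.reconstruction.vertices, b.reconstruction.vertices)
        assert np.isfinite(a.trace[0][0])
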