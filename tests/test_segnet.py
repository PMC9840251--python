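import numpy as np
import pytest

from rodentseg.phantom import PhantomSpec, generate_phantom
from rodentseg.segnet import (NetConfig, ProbabilityMap, TrainConfig, UNet3D,
                              _P_EPS, _combined_grad, combined_loss,
                              dice_loss, focal_loss, load_checkpoint, predict,
                              save_checkpoint, segment_stepwise, train_model)
from rodentseg.volio import Mask, ModalityStack

TINY = NetConfig(levels=2, base_filters=2, patch=8, seed=0)


def _tiny_cases(n=4, seed=0, size=16):
    specs = [PhantomSpec(matrix=(size,) * 3, spacing=(0.5,) * 3,
                         tumor_radius_frac=0.6, base_snr=15.0, seed=seed + i)
             for i in range(n)]
    return [generate_phantom(s).record for s in specs]


class TestConfig:
    def test_patch_divisibility(self):
        with pytest.raises(ValueError, match="divisible"):
            NetConfig(levels=3, patch=60)
        with pytest.raises(ValueError, match="levels"):
            NetConfig(levels=1)

    def test_train_config_weights(self):
        with pytest.raises(ValueError):
            TrainConfig(w_roi=0.8, w_bg=0.3)


class TestLosses:
    def test_dice_perfect_and_total_miss(self, rng):
        g = (rng.random((6, 6, 6)) < 0.3).astype(float)
        g.flat[0] = 1
        assert dice_loss(g, g) < 1e-4
        assert dice_loss(np.zeros_like(g), g) == pytest.approx(1.0, abs=1e-4)

    def test_dice_uniform_half_against_sum_oracle(self):
        g = np.zeros((4, 4, 4))
        g[:2] = 1.0  # half the voxels
        p = np.full((4, 4, 4), 0.5)
        num = 2 * (p * g).sum() + 1e-6
        den = p.sum() + g.sum() + 1e-6
        assert dice_loss(p, g) == pytest.approx(1 - num / den, abs=1e-6)

    def test_focal_single_voxel_hand_value(self):
        """p=0.5 on a true ROI voxel with gamma=2: 0.75 * 0.25 * ln 2."""
        # 2x2x2 grid of identical voxels has the same mean as one voxel
        p = np.full((2, 2, 2), 0.5)
        g = np.ones((2, 2, 2))
        expected = 0.75 * 0.25 * np.log(2.0)
        assert focal_loss(p, g, 0.75, 0.25, 2.0) == pytest.approx(expected, rel=1e-9)

    def test_focal_gamma0_reduces_to_half_bce(self, rng):
        p = rng.uniform(0.05, 0.95, (5, 5, 5))
        g = (rng.random((5, 5, 5)) < 0.4).astype(float)
        bce = -(g * np.log(p) + (1 - g) * np.log(1 - p)).mean()
        assert focal_loss(p, g, 0.5, 0.5, 0.0) == pytest.approx(bce / 2, abs=1e-6)

    def test_focal_perfect_prediction_limit(self):
        g = np.zeros((4, 4, 4))
        g[1:3, 1:3, 1:3] = 1
        p = np.where(g > 0, 1.0 - 1e-7, 1e-7)
        assert focal_loss(p, g) < 1e-6

    def test_combined_degenerate_mixes(self, rng):
        p = rng.uniform(0.01, 0.99, (4, 4, 4))
        g = (rng.random((4, 4, 4)) < 0.5).astype(float)
        assert combined_loss(p, g, TrainConfig(dice_focal_mix=1.0)) == \
            pytest.approx(dice_loss(p, g))
        assert combined_loss(p, g, TrainConfig(dice_focal_mix=0.0)) == \
            pytest.approx(focal_loss(p, g))
        perfect = np.where(g > 0, 1.0 - 1e-7, 1e-7)
        assert combined_loss(perfect, g, TrainConfig()) < 1e-4

    def test_loss_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))

    def test_combined_grad_matches_finite_differences(self, rng):
        p = rng.uniform(0.2, 0.8, (3, 3, 3))
        g = (rng.random((3, 3, 3)) < 0.5).astype(float)
        cfg = TrainConfig()
        grad = _combined_grad(p, g, cfg)
        for idx in [(0, 0, 0), (1, 2, 1), (2, 2, 2)]:
            eps = 1e-6
            pp, pm = p.copy(), p.copy()
            pp[idx] += eps
            pm[idx] -= eps
            num = (combined_loss(pp, g, cfg) - combined_loss(pm, g, cfg)) / (2 * eps)
            assert grad[idx] == pytest.approx(num, rel=1e-4)


class TestNetwork:
    def test_forward_shape_and_range(self, rng):
        net = UNet3D(TINY)
        x = rng.normal(size=(3, 8, 8, 8)).astype(np.float32)
        p = net.forward(x)
        assert p.shape == (8, 8, 8)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_deterministic_initialization(self):
        a, b = UNet3D(TINY), UNet3D(TINY)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa, pb)

    def test_input_validation(self, rng):
        net = UNet3D(TINY)
        with pytest.raises(ValueError, match="divisible"):
            net.forward(rng.normal(size=(3, 6, 8, 8)).astype(np.float32))
        with pytest.raises(ValueError):
            net.forward(rng.normal(size=(2, 8, 8, 8)).astype(np.float32))

    def test_backprop_matches_numerical_gradient(self, rng):
        net = UNet3D(TINY)
        x = rng.normal(size=(3, 8, 8, 8)).astype(np.float32)
        g = (rng.random((8, 8, 8)) < 0.3).astype(np.uint8)
        cfg = TrainConfig()
        p = net.forward(x, train=True)
        grad = _combined_grad(np.clip(p.astype(np.float64), _P_EPS, 1 - _P_EPS),
                              g.astype(np.float64), cfg)
        net.zero_grad()
        net.backward(grad)
        params, grads = net.parameters(), net.gradients()
        check = np.random.default_rng(7)
        for pi in (0, 5, len(params) - 2):
            flat, gflat = params[pi].reshape(-1), grads[pi].reshape(-1)
            j = int(check.integers(flat.size))
            eps, orig = 1e-3, flat[j]
            flat[j] = orig + eps
            lp = combined_loss(net.forward(x), g, cfg)
            flat[j] = orig - eps
            lm = combined_loss(net.forward(x), g, cfg)
            flat[j] = orig
            num = (lp - lm) / (2 * eps)
            assert gflat[j] == pytest.approx(num, rel=0.05, abs=1e-6)


class TestTraining:
    def test_training_is_deterministic(self):
        cases = _tiny_cases()
        cfg = NetConfig(levels=2, base_filters=4, patch=16, seed=3)
        tcfg = TrainConfig(lr=1e-3, epochs=2, batch_size=1, seed=3)
        _, trace_a = train_model(cases, "brain", cfg, tcfg, 0.25)
        _, trace_b = train_model(cases, "brain", cfg, tcfg, 0.25)
        assert trace_a.equals(trace_b)
        assert len(trace_a) == 2 * 2  # one train + one val row per epoch

    def test_loss_decreases_on_tiny_fixture(self):
        cases = _tiny_cases(n=6, seed=50)
        cfg = NetConfig(levels=2, base_filters=4, patch=16, seed=1)
        tcfg = TrainConfig(lr=3e-3, epochs=5, batch_size=1, augment=False, seed=1)
        _, trace = train_model(cases, "brain", cfg, tcfg, 0.2)
        tr = trace[trace.split == "train"]
        assert tr.loss.iloc[-1] < tr.loss.iloc[0]
        assert np.isfinite(trace.loss).all()

    def test_error_cases(self):
        cases = _tiny_cases()
        cfg = NetConfig(levels=2, base_filters=2, patch=16)
        with pytest.raises(ValueError, match="2 cases"):
            train_model(cases[:1], "brain", cfg, TrainConfig())
        stripped = [type(c)(c.case_id, c.stack, c.brain_mask, None)
                    for c in cases]
        with pytest.raises(ValueError, match="lacks"):
            train_model(stripped, "tumor", cfg, TrainConfig())
        empty = [type(c)(c.case_id, c.stack, c.brain_mask,
                         Mask(np.zeros(c.stack.shape, np.uint8),
                              c.stack.spacing, "tumor"))
                 for c in cases]
        with pytest.raises(ValueError, match="empty"):
            train_model(empty, "tumor", cfg, TrainConfig())


class TestInference:
    def test_predict_range_tiling_and_determinism(self, rng):
        net = UNet3D(NetConfig(levels=2, base_filters=2, patch=16, seed=2))
        x = rng.normal(size=(3, 16, 32, 32)).astype(np.float32)
        p1 = predict(net, x, 16)
        p2 = predict(net, x, 16)
        assert p1.values.shape == (16, 32, 32)  # 1*2*2 tiles reassembled
        assert p1.values.min() >= 0 and p1.values.max() <= 1
        np.testing.assert_array_equal(p1.values, p2.values)

    def test_probability_map_binarize(self):
        pm = ProbabilityMap(np.linspace(0, 1, 8).reshape(2, 2, 2), (1, 1, 1))
        assert set(np.unique(pm.binarize().labels)) <= {0, 1}

    def test_stepwise_containment_with_random_nets(self, rng):
        net1 = UNet3D(NetConfig(levels=2, base_filters=2, patch=16, seed=5))
        net2 = UNet3D(NetConfig(levels=2, base_filters=2, patch=16, seed=6))
        case = _tiny_cases(n=1, seed=77)[0]
        brain, tumor = segment_stepwise(net1, net2, case.stack)
        assert np.all(tumor.labels <= brain.labels)

    def test_zeroed_input_gives_empty_masks_with_warning(self):
        net1 = UNet3D(NetConfig(levels=2, base_filters=2, patch=16, seed=5))
        net2 = UNet3D(NetConfig(levels=2, base_filters=2, patch=16, seed=6))
        # bias the head so that zero input maps below threshold
        net1.head.b[:] = -10.0
        stack = ModalityStack.from_array(np.zeros((3, 16, 16, 16), np.float32),
                                         (0.5, 0.5, 0.5))
        with pytest.warns(UserWarning, match="empty brain"):
            brain, tumor = segment_stepwise(net1, net2, stack)
        assert brain.is_empty() and tumor.is_empty()

    def test_case_id_relabeling_invariance(self):
        net1 = UNet3D(NetConfig(levels=2, base_filters=2, patch=16, seed=5))
        net2 = UNet3D(NetConfig(levels=2, base_filters=2, patch=16, seed=6))
        case = _tiny_cases(n=1, seed=78)[0]
        b1, t1 = segment_stepwise(net1, net2, case.stack)
        case.case_id = "renamed"
        for v in case.stack.volumes:
            v.case_id = "renamed"
        b2, t2 = segment_stepwise(net1, net2, case.stack)
        np.testing.assert_array_equal(b1.labels, b2.labels)
        np.testing.assert_array_equal(t1.labels, t2.labels)


class TestCheckpoint:
    def test_round_trip_preserves_weights_and_predictions(self, tmp_path, rng):
        net = UNet3D(NetConfig(levels=2, base_filters=3, patch=16, seed=9))
        path = save_checkpoint(net, tmp_path / "m.npz", TrainConfig())
        back = load_checkpoint(path)
        assert back.cfg == net.cfg
        for a, b in zip(net.parameters(), back.parameters()):
            np.testing.assert_array_equal(a, b)
        x = rng.normal(size=(3, 16, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(net.forward(x), back.forward(x))
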