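"""Completion network: losses, gradients, architecture, padding, training."""

import numpy as np
import pytest

import sinomar as sm
from sinomar.network import (NetConfig, TrainConfig, UNet, crop_from_net,
                             load_checkpoint, pad_for_net, save_checkpoint,
                             total_loss, total_loss_grad, train,
                             validation_trace_mae)
from sinomar.traces import TraceMask

# the hand-worked 2x2 example: rows = detector, cols = angle
F_OUT = np.array([[1.0, 2.0], [3.0, 4.0]])
F_LAB = np.array([[1.0, 2.0], [5.0, 4.0]])
MASK = np.array([[0.0, 0.0], [1.0, 0.0]])


class TestLosses:
    def test_worked_example(self):
        assert sm.loss_l2(F_OUT, F_LAB, MASK) == 4.0
        assert sm.loss_amp(F_OUT, F_LAB) == 4.0
        assert sm.loss_diff(F_OUT, F_LAB) == 4.0
        rep = total_loss(F_OUT, F_LAB, MASK)
        assert (rep.l2, rep.amp, rep.diff, rep.total) == (4.0, 4.0, 4.0, 12.0)

    def test_zero_when_output_equals_label(self):
        rep = total_loss(F_LAB, F_LAB, MASK)
        assert (rep.l2, rep.amp, rep.diff, rep.total) == (0.0, 0.0, 0.0, 0.0)

    def test_l2_ignores_unmasked_entries(self):
        rng = np.random.default_rng(0)
        out = rng.random((8, 6))
        lab = rng.random((8, 6))
        assert sm.loss_l2(out, lab, np.zeros((8, 6))) == 0.0

    def test_amp_invariant_to_column_constant_shift(self):
        rng = np.random.default_rng(1)
        out = rng.random((8, 6))
        lab = rng.random((8, 6))
        shifted = out.copy()
        shifted[:, 2] += 3.7
        assert sm.loss_amp(shifted, lab) == pytest.approx(
            sm.loss_amp(out, lab))

    def test_diff_invariant_to_permutation_within_column(self):
        rng = np.random.default_rng(2)
        out = rng.random((8, 6))
        lab = rng.random((8, 6))
        perm = out.copy()
        perm[:, 3] = rng.permutation(perm[:, 3])
        assert sm.loss_diff(perm, lab) == pytest.approx(
            sm.loss_diff(out, lab))

    def test_weights_contract(self):
        rep = total_loss(F_OUT, F_LAB, MASK, weights=(1.0, 0.0, 0.0))
        assert rep.total == rep.l2
        with pytest.raises(ValueError):
            total_loss(F_OUT, F_LAB, MASK, weights=(1.0, -0.5, 1.0))

    def test_losses_nonnegative_and_faithful(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            out = rng.normal(size=(6, 5))
            lab = rng.normal(size=(6, 5))
            m = (rng.random((6, 5)) < 0.5).astype(float)
            rep = total_loss(out, lab, m)
            assert min(rep.l2, rep.amp, rep.diff, rep.total) >= 0.0

    def test_diff_matches_order0_projection_moments(self, metal_pair):
        # the consistency loss is the squared mismatch of per-angle masses
        completed = sm.li_mar(metal_pair.corrupted, metal_pair.mask)
        v_out = sm.projection_moment(completed, 0).values
        v_lab = sm.projection_moment(metal_pair.label, 0).values
        spacing = metal_pair.label.geometry.detector_spacing
        expected = ((v_out - v_lab) ** 2).sum() / spacing ** 2
        assert sm.loss_diff(completed.values, metal_pair.label.values) \
            == pytest.approx(expected, rel=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sm.loss_amp(F_OUT, np.ones((3, 2)))
        with pytest.raises(ValueError):
            sm.loss_l2(F_OUT, F_LAB, np.ones((3, 2)))


class TestLossGradient:
    def test_analytic_matches_finite_difference_on_worked_example(self):
        g = total_loss_grad(F_OUT, F_LAB, MASK)
        eps = 1e-6
        for i in range(2):
            for j in range(2):
                up, down = F_OUT.copy(), F_OUT.copy()
                up[i, j] += eps
                down[i, j] -= eps
                fd = (total_loss(up, F_LAB, MASK).total
                      - total_loss(down, F_LAB, MASK).total) / (2 * eps)
                assert abs(g[i, j] - fd) <= 1e-4 * max(abs(fd), 1.0)

    def test_gradient_on_random_batched_arrays(self):
        rng = np.random.default_rng(4)
        out = rng.normal(size=(2, 5, 4))
        lab = rng.normal(size=(2, 5, 4))
        m = (rng.random((2, 5, 4)) < 0.4).astype(float)
        w = (0.7, 1.3, 0.2)
        g = total_loss_grad(out, lab, m, w)
        eps = 1e-6
        idx = [(0, 0, 0), (1, 4, 3), (0, 2, 1), (1, 0, 2)]
        for i in idx:
            up, down = out.copy(), out.copy()
            up[i] += eps
            down[i] -= eps
            fd = (total_loss(up, lab, m, w).total
                  - total_loss(down, lab, m, w).total) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-8)


class TestNetworkParameterGradients:
    def test_backprop_matches_finite_differences(self):
        net = UNet(NetConfig(depth=2, base_channels=3), seed=1,
                   dtype=np.float64)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 8, 8, 1))
        y = rng.normal(size=(2, 8, 8, 1))
        m = (rng.random((2, 8, 8, 1)) < 0.3).astype(float)

        out = net.forward(x)
        g = total_loss_grad(out[..., 0], y[..., 0], m[..., 0])
        net.backward(g[..., None])
        handles = net.parameters()
        grads = [getattr(o, "d" + n).copy() for o, n in handles]

        def loss():
            return total_loss(net.forward(x)[..., 0], y[..., 0],
                              m[..., 0]).total

        pick = np.random.default_rng(5)
        for h, (obj, name) in enumerate(handles):
            flat = getattr(obj, name).reshape(-1)
            for i in pick.choice(flat.size, size=min(2, flat.size),
                                 replace=False):
                old = flat[i]
                flat[i] = old + 1e-6
                up = loss()
                flat[i] = old - 1e-6
                down = loss()
                flat[i] = old
                fd = (up - down) / 2e-6
                assert grads[h].reshape(-1)[i] == pytest.approx(
                    fd, rel=1e-4, abs=1e-7)


class TestArchitecture:
    def test_output_shape_matches_input_at_full_size(self):
        net = UNet(NetConfig(depth=4, base_channels=2), seed=0)
        out = net.forward(np.zeros((1, 512, 512, 1), np.float32))
        assert out.shape == (1, 512, 512, 1)

    def test_channel_schedule_doubles_then_saturates(self):
        cfg = NetConfig(depth=5, base_channels=64)
        assert cfg.channel_schedule == (64, 128, 256, 512, 512)
        assert NetConfig.desk().channel_schedule == (16, 32, 64, 128)

    def test_bottleneck_spatial_side_is_input_over_2_to_depth(self):
        net = UNet(NetConfig.desk(), seed=0)
        net.forward(np.zeros((1, 96, 96, 1), np.float32))
        # the bottleneck convolution's cached input records its spatial side
        _, (n, h, w, ci), _, _ = net.bott["conv1"]._cache
        assert (h, w) == (96 // 2 ** 4, 96 // 2 ** 4)
        assert ci == NetConfig.desk().bottleneck_channels

    def test_same_seed_same_initial_parameters(self):
        a = sm.build_unet(NetConfig.desk(), seed=7)
        b = sm.build_unet(NetConfig.desk(), seed=7)
        for (oa, na), (ob, nb) in zip(a.parameters(), b.parameters()):
            assert np.array_equal(getattr(oa, na), getattr(ob, nb))

    def test_indivisible_input_rejected_naming_padding(self):
        net = UNet(NetConfig.desk(), seed=0)
        with pytest.raises(ValueError, match="pad"):
            net.forward(np.zeros((1, 96, 90, 1), np.float32))


class TestPadding:
    def test_pad_and_crop_roundtrip_512x360(self):
        rng = np.random.default_rng(0)
        values = rng.random((512, 360))
        padded, rec = pad_for_net(values, depth=5)
        assert padded.shape == (512, 384)
        assert np.array_equal(crop_from_net(padded, rec), values)

    def test_circular_angle_padding(self):
        values = np.arange(512 * 360, dtype=float).reshape(512, 360)
        padded, _ = pad_for_net(values, depth=5)
        for j in range(384 - 360):
            assert np.array_equal(padded[:, 360 + j], values[:, j])

    def test_already_divisible_input_unchanged(self):
        values = np.ones((64, 64))
        padded, rec = pad_for_net(values, depth=4)
        assert padded.shape == (64, 64)
        assert np.array_equal(padded, values)

    def test_detector_axis_zero_padded_symmetrically(self):
        values = np.ones((60, 64))
        padded, rec = pad_for_net(values, depth=4)
        assert padded.shape == (64, 64)
        assert not padded[:2].any() and not padded[-2:].any()
        assert np.array_equal(crop_from_net(padded, rec), values)


class TestTraining:
    @pytest.fixture(scope="class")
    def tiny_pairs(self, small_geometry):
        pairs = []
        for seed in range(6):
            spec = sm.sample_random_phantom(
                seed, sm.GenerationConfig(
                    image_size=48, metal_count_range=(1, 1),
                    metal_radius_range=(0.08, 0.15),
                    n_internal_range=(0, 1)))
            pairs.append(sm.make_pair(spec, small_geometry, dilation_px=1))
        return pairs

    def test_history_is_finite_and_loss_decreases(self, tiny_pairs):
        nc = NetConfig(depth=3, base_channels=4)
        tc = TrainConfig(steps=30, batch_size=4, learning_rate=1e-3, seed=0)
        model, hist = train(tiny_pairs, nc, tc)
        totals = [h["total"] for h in hist]
        assert all(np.isfinite(totals))
        assert totals[-1] < totals[0]
        assert model.scale > 0

    def test_fixed_seed_reproduces_history(self, tiny_pairs):
        nc = NetConfig(depth=3, base_channels=4)
        tc = TrainConfig(steps=5, batch_size=4, seed=3)
        _, h1 = train(tiny_pairs, nc, tc)
        _, h2 = train(tiny_pairs, nc, tc)
        assert [h["total"] for h in h1] == [h["total"] for h in h2]

    def test_divergence_aborts_with_diagnostic(self, tiny_pairs):
        nc = NetConfig(depth=3, base_channels=4)
        tc = TrainConfig(steps=200, batch_size=4, learning_rate=1e8, seed=0)
        with pytest.raises(RuntimeError, match="diverged"):
            train(tiny_pairs, nc, tc)

    def test_ablation_flags_produce_distinct_objectives(self, tiny_pairs):
        nc = NetConfig(depth=3, base_channels=4)
        variants = [
            dict(use_mask=True, use_amp=True, use_diff=True),
            dict(use_mask=True, use_amp=False, use_diff=False),
            dict(use_mask=False, use_amp=False, use_diff=False),
            dict(use_mask=False, use_amp=True, use_diff=True),
        ]
        firsts = []
        for flags in variants:
            tc = TrainConfig(steps=2, batch_size=4, seed=0, **flags)
            _, hist = train(tiny_pairs, nc, tc)
            firsts.append(round(hist[0]["total"], 6))
        assert len(set(firsts)) == len(variants)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train([], NetConfig.desk(), TrainConfig(steps=1))

    def test_training_log_csv_written(self, tiny_pairs, tmp_path):
        nc = NetConfig(depth=3, base_channels=4)
        tc = TrainConfig(steps=3, batch_size=4, seed=0,
                         log_path=str(tmp_path / "log.csv"))
        train(tiny_pairs, nc, tc)
        lines = (tmp_path / "log.csv").read_text().strip().splitlines()
        assert lines[0].startswith("step,l2,amp,diff,total")
        assert len(lines) == 4


class TestComplete:
    @pytest.fixture(scope="class")
    def trained(self, small_geometry):
        spec = sm.sample_random_phantom(
            0, sm.GenerationConfig(image_size=48, metal_count_range=(1, 1),
                                   n_internal_range=(0, 1)))
        pair = sm.make_pair(spec, small_geometry, dilation_px=1)
        model, _ = train([pair], NetConfig(depth=3, base_channels=4),
                         TrainConfig(steps=5, batch_size=2, seed=0))
        return model, pair

    def test_empty_mask_returns_input_bit_exact(self, trained):
        model, pair = trained
        empty = TraceMask(np.zeros_like(pair.mask.values))
        out = sm.complete(pair.corrupted, empty, model)
        assert np.array_equal(out.values, pair.corrupted.values)

    def test_unaffected_entries_preserved_bit_exact(self, trained):
        model, pair = trained
        out = sm.complete(pair.corrupted, pair.mask, model)
        m = pair.mask.values.astype(bool)
        assert np.array_equal(out.values[~m], pair.corrupted.values[~m])
        assert np.all(np.isfinite(out.values))

    def test_missing_scale_rejected(self, trained):
        _, pair = trained
        fresh = UNet(NetConfig(depth=3, base_channels=4), seed=0)
        with pytest.raises(ValueError, match="scale"):
            sm.complete(pair.corrupted, pair.mask, fresh)

    def test_checkpoint_roundtrip_preserves_predictions(self, trained,
                                                        tmp_path):
        model, pair = trained
        save_checkpoint(model, tmp_path / "w.npz")
        back = load_checkpoint(tmp_path / "w.npz")
        a = sm.complete(pair.corrupted, pair.mask, model)
        b = sm.complete(pair.corrupted, pair.mask, back)
        assert np.array_equal(a.values, b.values)
        assert back.scale == model.scale

    def test_validation_trace_mae_requires_trace(self, trained,
                                                 small_geometry):
        model, _ = trained
        spec = sm.PhantomSpec((sm.EllipseSpec(0, 0, 0.5, 0.5, 0, 1.0),), (),
                              image_size=48)
        metal_free = sm.make_pair(spec, small_geometry)
        with pytest.raises(ValueError, match="trace"):
            validation_trace_mae(model, [metal_free])
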