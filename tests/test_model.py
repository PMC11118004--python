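"""Quality model: architecture contracts, training loop, inference, checkpoints."""

import numpy as np
import pytest
from scipy import ndimage

from glottisqc import (
    LossParams,
    ModelConfig,
    TrainConfig,
    build_model,
    compute_iou,
    load_checkpoint,
    predict,
    predict_batch,
    save_checkpoint,
    train,
)
from glottisqc.model import _should_stop, samples_to_arrays


TINY = ModelConfig(input_size=32, width_multiplier=0.0625)


def tiny_samples(pairs, rng, n=None):
    from glottisqc import PerturbationConfig, perturb_pairs

    cfg = PerturbationConfig()
    samples = perturb_pairs(pairs if n is None else pairs[:n], cfg, rng, samples_per_pair=2)
    return samples


@pytest.fixture(scope="module")
def scored_32():
    from glottisqc import GlottisPhantomParams, generate_pair

    params = GlottisPhantomParams(image_size=32, closed_probability=0.0, seed=21)
    rng = np.random.default_rng(21)
    pairs = [generate_pair(params, rng) for _ in range(24)]
    return tiny_samples(pairs, rng)


class TestArchitecture:
    def test_single_scalar_output_per_sample(self):
        net = build_model(TINY, rng=np.random.default_rng(0))
        out = net.forward(np.random.rand(3, 2, 32, 32).astype(np.float32), train=False)
        assert out.shape == (3,)
        assert np.isfinite(out).all()

    def test_batch_of_18_gives_18_outputs(self):
        net = build_model(TINY, rng=np.random.default_rng(0))
        out = net.forward(np.random.rand(18, 2, 32, 32).astype(np.float32), train=True)
        assert out.shape == (18,)

    def test_width_multiplier_shrinks_parameter_count(self):
        full = build_model(ModelConfig(input_size=64), rng=np.random.default_rng(0))
        quarter = build_model(
            ModelConfig(input_size=64, width_multiplier=0.25), rng=np.random.default_rng(0)
        )
        assert quarter.num_params() < full.num_params()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(width_multiplier=0.0)
        with pytest.raises(ValueError):
            ModelConfig(in_channels=3)

    def test_conv_gradients_match_finite_differences(self):
        """Backprop through a small conv/bn/pool stack agrees with numeric
        differentiation of the scalar output sum."""
        net = build_model(TINY, rng=np.random.default_rng(1))
        x = np.random.default_rng(2).random((2, 2, 32, 32)).astype(np.float32)
        out = net.forward(x, train=False)  # eval mode: frozen BN stats
        net.zero_grad()
        # d(sum of outputs)/d(params): backward with ones
        # re-run forward in train=False caches, then backward
        net.forward(x, train=False)
        net.backward(np.ones(2, dtype=np.float32))
        p = net.fc.weight
        eps = 1e-3
        i = 0
        orig = p.data[0, i]
        p.data[0, i] = orig + eps
        up = net.forward(x, train=False).sum()
        p.data[0, i] = orig - eps
        dn = net.forward(x, train=False).sum()
        p.data[0, i] = orig
        fd = (up - dn) / (2 * eps)
        assert p.grad[0, i] == pytest.approx(fd, rel=1e-2, abs=1e-3)


class TestTraining:
    def test_overfits_small_set(self, scored_32):
        samples = scored_32[:32]
        net = build_model(TINY, rng=np.random.default_rng(3))
        tc = TrainConfig(max_epochs=12, augment=False, seed=3, learning_rate=3e-4)
        net, log = train(net, samples, samples, LossParams(1.0, 0.0, 0.6), tc,
                         rng=np.random.default_rng(3))
        assert log[-1]["train_loss"] < log[0]["train_loss"]

    def test_early_stop_rule(self):
        tc = TrainConfig(early_stop_after=20, early_stop_patience=10)
        assert not _should_stop(epoch=18, best_epoch=0, tc=tc)  # too early
        assert not _should_stop(epoch=25, best_epoch=20, tc=tc)  # recent best
        assert _should_stop(epoch=31, best_epoch=20, tc=tc)
        assert _should_stop(epoch=19, best_epoch=5, tc=tc)  # exactly at onset

    def test_training_log_schema_and_best_model_selection(self, scored_32):
        net = build_model(TINY, rng=np.random.default_rng(4))
        tc = TrainConfig(max_epochs=3, augment=False, seed=4)
        net, log = train(net, scored_32[:24], scored_32[24:36], LossParams(), tc,
                         rng=np.random.default_rng(4))
        assert [row["epoch"] for row in log] == list(range(len(log)))
        assert all({"train_loss", "val_mse", "lr"} <= set(row) for row in log)
        # returned model reproduces the best epoch's validation MSE
        x, y = samples_to_arrays(scored_32[24:36])
        pred = net.forward(x, train=False)
        assert float(np.mean((pred - y) ** 2)) == pytest.approx(
            min(r["val_mse"] for r in log), abs=1e-6
        )

    def test_joint_rotation_preserves_iou_label(self, scored_32):
        """Geometric augmentation applied to frame+masks jointly keeps the
        label valid: IoU(rot(cand), rot(gt)) stays within 0.02 of IoU."""
        for s in scored_32[:8]:
            if not s.gt_mask.any():
                continue
            rot_gt = ndimage.rotate(s.gt_mask.astype(float), 12, reshape=False, order=0) > 0.5
            rot_cand = (
                ndimage.rotate(s.candidate_mask.astype(float), 12, reshape=False, order=0) > 0.5
            )
            assert compute_iou(rot_cand, rot_gt) == pytest.approx(s.iou, abs=0.02)

    def test_empty_split_rejected(self, scored_32):
        net = build_model(TINY, rng=np.random.default_rng(5))
        with pytest.raises(ValueError):
            train(net, [], scored_32[:2], LossParams(), TrainConfig(max_epochs=1))


class TestInference:
    def test_decision_threshold(self, scored_32):
        net = build_model(TINY, rng=np.random.default_rng(6))
        s = scored_32[0]
        q = predict(net, s.frame, s.candidate_mask, threshold=0.6)
        assert 0.0 <= q.score <= 1.0
        assert q.decision == ("accepted" if q.score >= 0.6 else "declined")

    def test_inference_deterministic(self, scored_32):
        net = build_model(TINY, rng=np.random.default_rng(7))
        s = scored_32[1]
        q1 = predict(net, s.frame, s.candidate_mask)
        q2 = predict(net, s.frame, s.candidate_mask)
        assert q1 == q2

    def test_batch_prediction_equals_per_sample(self, scored_32):
        net = build_model(TINY, rng=np.random.default_rng(8))
        batch = predict_batch(net, scored_32[:6])
        singles = [predict(net, s.frame, s.candidate_mask) for s in scored_32[:6]]
        for b, s in zip(batch, singles):
            assert b.score == pytest.approx(s.score, abs=1e-6)

    def test_shape_mismatch_rejected(self, scored_32):
        net = build_model(TINY, rng=np.random.default_rng(9))
        with pytest.raises(ValueError):
            predict(net, scored_32[0].frame, np.zeros((8, 8), dtype=bool))


class TestCheckpoint:
    def test_round_trip_reproduces_probe_outputs(self, tmp_path, scored_32):
        net = build_model(TINY, rng=np.random.default_rng(10))
        x, _ = samples_to_arrays(scored_32[:4])
        before = net.forward(x, train=False)
        save_checkpoint(net, tmp_path / "ckpt.npz", loss_params=LossParams(), seed=10)
        loaded, meta = load_checkpoint(tmp_path / "ckpt.npz")
        after = loaded.forward(x, train=False)
        np.testing.assert_array_equal(before, after)
        assert meta["model_config"]["width_multiplier"] == 0.0625
        assert meta["loss_params"]["t"] == 0.6
        assert meta["seed"] == 10

    def test_missing_checkpoint_fails_loudly(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_checkpoint(tmp_path / "nope.npz")
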