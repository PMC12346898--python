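import numpy as np
import pytest

from lungsound import nn
from lungsound.model import (
    LungSoundNet,
    ModelConfig,
    ResidualBlock,
    activation_map,
    build_model,
    describe,
    load_checkpoint,
    predict,
    save_checkpoint,
)
from lungsound.nn import RAdam, softmax_cross_entropy

TINY = ModelConfig(stage_widths=(4, 8, 8, 16))


def _zero_residual_branch(block: ResidualBlock) -> None:
    for layer in (block.conv1, block.bn1, block.conv2, block.bn2):
        for p in layer.params():
            p.value[...] = 0.0


class TestResidualBlock:
    def test_identity_with_zeroed_branch(self, rng):
        block = ResidualBlock(8, 8, stride=1, rng=np.random.default_rng(0))
        _zero_residual_branch(block)
        x = rng.standard_normal((2, 8, 6, 10)).astype(np.float32)
        y = block.forward(x, train=False)
        assert np.array_equal(y, x)

    def test_zero_input_returns_branch_output(self, rng):
        block = ResidualBlock(4, 4, stride=1, rng=np.random.default_rng(1))
        x = np.zeros((1, 4, 6, 6), dtype=np.float32)
        y = block.forward(x, train=False)
        f = block.residual(x, train=False)
        assert np.allclose(y, f)

    def test_projection_used_when_shape_changes(self, rng):
        block = ResidualBlock(4, 8, stride=2, rng=np.random.default_rng(2))
        assert block.has_projection
        x = rng.standard_normal((2, 4, 8, 8)).astype(np.float32)
        assert block.forward(x, train=False).shape == (2, 8, 4, 4)


class TestConvOracle:
    def test_matches_hand_rolled_convolution(self, rng):
        """3x3 conv on a 4x4 input against explicit nested loops."""
        conv = nn.Conv2d(2, 3, 3, stride=1, pad=1, rng=np.random.default_rng(3))
        x = rng.standard_normal((1, 2, 4, 4)).astype(np.float32)
        y = conv.forward(x)
        w = conv.w.value
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        expected = np.zeros((1, 3, 4, 4), dtype=np.float64)
        for co in range(3):
            for i in range(4):
                for j in range(4):
                    acc = 0.0
                    for ci in range(2):
                        for di in range(3):
                            for dj in range(3):
                                acc += xp[0, ci, i + di, j + dj] * w[co, ci, di, dj]
                    expected[0, co, i, j] = acc
        assert np.allclose(y, expected, atol=1e-5)


class TestBuildAndPredict:
    def test_forward_gives_probabilities(self, rng):
        model = build_model(TINY, seed=0)
        x = rng.standard_normal((3, 1, 128, 350)).astype(np.float32)
        logits = model.forward(x)
        probs = nn.softmax(logits)
        assert probs.shape == (3, 3)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_seeded_builds_are_identical(self):
        a = build_model(TINY, seed=5)
        b = build_model(TINY, seed=5)
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa.value, pb.value)

    def test_different_seeds_differ(self):
        a = build_model(TINY, seed=5)
        b = build_model(TINY, seed=6)
        assert any(
            not np.array_equal(pa.value, pb.value)
            for pa, pb in zip(a.params(), b.params())
        )

    def test_predict_deterministic(self, rng):
        model = build_model(TINY, seed=1)
        grid = rng.standard_normal((128, 350))
        p1 = predict(model, grid)
        p2 = predict(model, grid)
        assert np.array_equal(p1.class_probs, p2.class_probs)
        assert p1.class_probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_tie_break_lowest_index(self, rng):
        model = build_model(TINY, seed=1)
        # zero the head: all logits equal -> exact three-way tie
        model.fc.w.value[...] = 0.0
        model.fc.b.value[...] = 0.0
        pred = predict(model, rng.standard_normal((128, 350)))
        assert np.allclose(pred.class_probs, 1 / 3)
        assert pred.predicted_class == 0

    def test_wrong_shape_rejected(self, rng):
        model = build_model(TINY, seed=0)
        with pytest.raises(ValueError):
            model.forward(rng.standard_normal((1, 1, 64, 350)).astype(np.float32))

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(variant="transformer")

    @pytest.mark.parametrize("variant", ["cnn_ts", "cnn_mfcc", "cnn_lstm_ts", "cnn_lstm_mfcc"])
    def test_all_variants_build_and_run(self, variant, rng):
        model = build_model(ModelConfig(variant=variant, stage_widths=(4, 8, 8, 16)), seed=0)
        x = rng.standard_normal((2, 1, 128, 350)).astype(np.float32)
        assert model.forward(x).shape == (2, 3)
        assert ("lstm" in variant) == (model.lstm is not None)


class TestTrainingStep:
    def test_single_step_reduces_loss(self, rng):
        """Gradient-flow sanity: one small RAdam step on one example."""
        model = build_model(TINY, seed=2)
        x = rng.standard_normal((2, 1, 128, 350)).astype(np.float32)
        y = np.array([0, 2])
        opt = RAdam(model.params(), lr=1e-2)
        losses = []
        for _ in range(6):
            logits = model.forward(x, train=True)
            loss, dl = softmax_cross_entropy(logits, y)
            losses.append(loss)
            opt.zero_grad()
            model.backward(dl)
            opt.step()
        assert losses[-1] < losses[0]

    def test_parameter_count_stable(self):
        a = build_model(TINY, seed=0)
        b = build_model(TINY, seed=9)
        assert a.n_parameters() == b.n_parameters()
        text = describe(a)
        assert f"{a.n_parameters():,}" in text
        assert "lstm" in text


class TestCheckpoint:
    def test_round_trip(self, tmp_path, rng):
        model = build_model(TINY, seed=3)
        grid = rng.standard_normal((128, 350))
        before = predict(model, grid).class_probs
        save_checkpoint(model, tmp_path / "m.npz")
        loaded = load_checkpoint(tmp_path / "m.npz")
        after = predict(loaded, grid).class_probs
        assert loaded.config == model.config
        assert np.array_equal(before, after)


class TestActivationMap:
    def test_bounds_and_shape(self, rng):
        model = build_model(TINY, seed=4)
        cam = activation_map(model, rng.standard_normal((128, 350)), target_class=1)
        assert cam.shape == (128, 350)
        assert cam.min() >= 0.0
        assert cam.max() <= 1.0

    def test_inference_leaves_no_gradients(self, rng):
        model = build_model(TINY, seed=4)
        activation_map(model, rng.standard_normal((128, 350)), 0)
        assert all(np.all(p.grad == 0) for p in model.params())

    def test_planted_feature_concentrates_mass(self, rng):
        """Train a tiny model where class 1 lights up columns 200-300; the
        class-1 CAM on a positive example must concentrate there."""
        def sample(label, rg):
            g = rg.standard_normal((128, 350)).astype(np.float32) * 0.1
            if label == 1:
                g[:, 200:300] += 3.0
            return g

        rg = np.random.default_rng(11)
        x = np.stack([sample(i % 2, rg) for i in range(24)])[:, None]
        y = np.array([i % 2 for i in range(24)])
        model = build_model(
            ModelConfig(variant="cnn_mfcc", stage_widths=(4, 8, 8, 16)), seed=5
        )
        opt = RAdam(model.params(), lr=3e-3)
        for _ in range(40):
            logits = model.forward(x, train=True)
            loss, dl = softmax_cross_entropy(logits, y)
            opt.zero_grad()
            model.backward(dl)
            opt.step()
        cam = activation_map(model, sample(1, np.random.default_rng(99)), 1)
        total = cam.sum()
        assert total > 0
        band = cam[:, 190:310].sum()
        assert band / total > 0.5
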