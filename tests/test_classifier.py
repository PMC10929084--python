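"""Multi-branch convolutional classifier: architecture, training, fusion."""

import numpy as np
import pytest

import rpifusion as rf
from rpifusion.classifier import (
    FC_SIZES,
    ModelConfig,
    RpiConvNet,
    StackingClassifier,
    build_model,
    fuse,
    load_model,
    save_model,
    train,
)
from rpifusion.errors import (
    ConfigError,
    DimensionError,
    SingleClassError,
    StrategyError,
)
from rpifusion import nn


@pytest.fixture
def toy_blocks():
    rng = np.random.default_rng(30)
    blocks = {"a": rng.normal(size=(80, 40)), "b": rng.normal(size=(80, 20))}
    y = (blocks["a"][:, 0] + blocks["b"][:, 1] > 0).astype(int)
    return blocks, y


class TestArchitecture:
    def test_forward_on_zeros_softmax_normalized(self):
        model = RpiConvNet({"a": 40, "b": 20}, ModelConfig(seed=0))
        probs = model.predict_proba(
            {"a": np.zeros((5, 40)), "b": np.zeros((5, 20))}
        )
        assert np.all(np.isfinite(probs))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_output_layer_width_two(self):
        model = RpiConvNet({"a": 40}, ModelConfig(seed=0))
        last_dense = [
            l for l in model.head.layers if isinstance(l, nn.Dense)
        ][-1]
        assert last_dense.w.value.shape[1] == 2

    def test_fc_parameter_counts(self):
        model = RpiConvNet({"a": 40}, ModelConfig(seed=0))
        dense = [l for l in model.head.layers if isinstance(l, nn.Dense)]
        f = dense[0].w.value.shape[0]
        expected = [(f + 1) * 16, (16 + 1) * 8, (8 + 1) * 2]
        got = [d.w.value.size + d.b.value.size for d in dense]
        assert got == expected
        assert FC_SIZES == (16, 8, 2)

    def test_small_branch_falls_back_to_single_conv(self, caplog):
        model = RpiConvNet({"tiny": 8}, ModelConfig(seed=0))
        convs = [
            l for l in model.branches["tiny"].layers if isinstance(l, nn.Conv1d)
        ]
        assert len(convs) == 1

    def test_too_small_branch_rejected(self):
        with pytest.raises(ConfigError):
            RpiConvNet({"tiny": 2}, ModelConfig(seed=0))


class TestTraining:
    def test_loss_decreases_on_separable_data(self, toy_blocks):
        blocks, y = toy_blocks
        cfg = ModelConfig(epochs=30, early_stopping_patience=0, seed=1)
        model = RpiConvNet({"a": 40, "b": 20}, cfg)
        history = train(model, blocks, y, cfg)
        assert history[-1] <= history[0]

    def test_seeded_determinism(self, toy_blocks):
        blocks, y = toy_blocks
        cfg = ModelConfig(epochs=5, seed=2)
        h1 = train(RpiConvNet({"a": 40, "b": 20}, cfg), blocks, y, cfg)
        h2 = train(RpiConvNet({"a": 40, "b": 20}, cfg), blocks, y, cfg)
        assert h1 == h2

    def test_single_class_rejected(self, toy_blocks):
        blocks, _ = toy_blocks
        cfg = ModelConfig(epochs=2, seed=0)
        model = RpiConvNet({"a": 40, "b": 20}, cfg)
        with pytest.raises(SingleClassError):
            train(model, blocks, np.zeros(80, dtype=int), cfg)

    def test_sgd_optimizer_runs(self, toy_blocks):
        blocks, y = toy_blocks
        cfg = ModelConfig(epochs=3, optimizer="sgd", learning_rate=1e-3, seed=0)
        model = RpiConvNet({"a": 40, "b": 20}, cfg)
        history = train(model, blocks, y, cfg)
        assert np.all(np.isfinite(history))


class TestFuse:
    def test_concatenate_dims_add(self):
        parts = [np.zeros((3, a)) for a in (4, 6, 8, 2)]
        assert fuse(parts, "concatenate").shape == (3, 20)

    def test_stacking_meta_dim(self):
        parts = [np.full((3, 2), 0.5) for _ in range(4)]
        assert fuse(parts, "stacking").shape == (3, 8)
        with pytest.raises(DimensionError):
            fuse([np.zeros((3, 4))] * 2, "stacking")

    def test_unknown_strategy(self):
        with pytest.raises(StrategyError):
            fuse([np.zeros((3, 2))] * 2, "blend")
        with pytest.raises(StrategyError):
            ModelConfig(fusion="blend")


class TestPredict:
    def test_score_half_is_negative_class(self):
        pred = rf.ScoredPrediction(
            pair=rf.InteractionPair("r", "p", 1), score=0.5
        )
        assert pred.predicted == 0
        assert rf.ScoredPrediction(pred.pair, 0.5000001).predicted == 1

    def test_scores_in_unit_interval_and_row_consistency(self, toy_blocks):
        blocks, y = toy_blocks
        cfg = ModelConfig(epochs=3, seed=0)
        model = RpiConvNet({"a": 40, "b": 20}, cfg)
        train(model, blocks, y, cfg)
        dup = {k: np.vstack([v[:1], v[:1]]) for k, v in blocks.items()}
        probs = model.predict_proba(dup)
        assert np.all((probs >= 0) & (probs <= 1))
        assert np.allclose(probs[0], probs[1])

    def test_dim_mismatch_rejected(self, toy_blocks):
        blocks, y = toy_blocks
        model = RpiConvNet({"a": 40, "b": 20}, ModelConfig(epochs=1, seed=0))
        with pytest.raises(DimensionError):
            model.predict_proba({"a": np.zeros((2, 39)), "b": np.zeros((2, 20))})


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, toy_blocks):
        blocks, y = toy_blocks
        cfg = ModelConfig(epochs=3, seed=4)
        model = RpiConvNet({"a": 40, "b": 20}, cfg)
        train(model, blocks, y, cfg)
        save_model(model, tmp_path / "m.npz")
        loaded = load_model(tmp_path / "m.npz")
        assert np.allclose(
            model.predict_proba(blocks), loaded.predict_proba(blocks)
        )


class TestStacking:
    def test_stacking_fits_and_predicts(self, toy_blocks):
        blocks, y = toy_blocks
        cfg = ModelConfig(epochs=3, fusion="stacking", seed=0)
        model = build_model(cfg, {"a": 40, "b": 20})
        assert isinstance(model, StackingClassifier)
        model.fit(blocks, y)
        probs = model.predict_proba(blocks)
        assert probs.shape == (80, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
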