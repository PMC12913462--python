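"""Architecture audit, gradient correctness, training sanity, prediction."""

import numpy as np
import pytest

from peptigen import _nn
from peptigen.submodels import (
    DEFAULT_TRAIN_CONFIGS,
    SubmodelPipeline,
    TrainConfig,
    build_submodel,
    predict_scores,
    train,
)
from peptigen.synthetic import GeneratorSpec, generate_training_set


class TestArchitectureAudit:
    def test_fcnn_tf_layers_and_hyperparameters(self):
        net = build_submodel("FCNN_TF", input_dim=100)
        assert net.layer_summary == [
            "dense(100->64)",
            "relu",
            "dropout(0.2)",
            "dense(64->2)",
        ]
        cfg = DEFAULT_TRAIN_CONFIGS["FCNN_TF"]
        assert (cfg.batch_size, cfg.epochs, cfg.learning_rate) == (32, 45, 1e-4)

    def test_fcnn_tf_parameter_count_closed_form(self):
        net = build_submodel("FCNN_TF", input_dim=100)
        assert net.n_params == (100 * 64 + 64) + (64 * 2 + 2) == 6594

    def test_cnn_biobert_parallel_branches(self):
        net = build_submodel("CNN_BioBERT", embed_dim=32)
        assert net.config.kernel_widths == (3, 4, 5)
        assert net.config.filters_per_width == 120
        assert net.config.dropout == 0.1
        assert "concat(360)" in net.layer_summary
        cfg = DEFAULT_TRAIN_CONFIGS["CNN_BioBERT"]
        assert (cfg.batch_size, cfg.epochs, cfg.learning_rate) == (32, 19, 1e-4)
        expected = sum((w * 32 * 120 + 120) for w in (3, 4, 5)) + (360 * 2 + 2)
        assert net.n_params == expected

    def test_fcnn_biobert_fuses_embeddings_with_11_features(self):
        net = build_submodel("FCNN_BioBERT", embed_dim=32)
        assert net.config.input_dim == 32 + 11
        assert net.config.hidden_size == 53
        assert net.config.dropout == 0.5
        cfg = DEFAULT_TRAIN_CONFIGS["FCNN_BioBERT"]
        assert (cfg.batch_size, cfg.epochs, cfg.learning_rate) == (32, 31, 1e-4)

    def test_unknown_name_raises(self):
        with pytest.raises(ValueError):
            build_submodel("RF_onehot", input_dim=5)


class TestGradients:
    def test_fcnn_gradient_matches_numerical(self, rng):
        net = build_submodel("FCNN_TF", input_dim=7, seed=0)
        X = rng.normal(size=(5, 7))
        y = np.array([0, 1, 0, 1, 1])
        logits = net.forward(X, rng=None)
        _, dlogits = _nn.cross_entropy(logits, y)
        net.backward(dlogits)
        analytic = net.fc1.dW.copy()
        eps = 1e-6
        for idx in [(0, 0), (3, 5), (6, 63)]:
            net.fc1.W[idx] += eps
            lp, _ = _nn.cross_entropy(net.forward(X, rng=None), y)
            net.fc1.W[idx] -= 2 * eps
            lm, _ = _nn.cross_entropy(net.forward(X, rng=None), y)
            net.fc1.W[idx] += eps
            assert analytic[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-5)

    def test_conv_gradient_matches_numerical(self, rng):
        net = build_submodel("CNN_BioBERT", embed_dim=6, seed=0)
        X = rng.normal(size=(4, 9, 6))
        lengths = np.array([9, 7, 9, 6])
        y = np.array([0, 1, 1, 0])
        logits = net.forward((X, lengths), rng=None)
        _, dlogits = _nn.cross_entropy(logits, y)
        net.backward(dlogits)
        analytic = net.conv.dW[0].copy()
        eps = 1e-6
        for idx in [(0, 0), (10, 50), (17, 119)]:
            net.conv.W[0][idx] += eps
            lp, _ = _nn.cross_entropy(net.forward((X, lengths), rng=None), y)
            net.conv.W[0][idx] -= 2 * eps
            lm, _ = _nn.cross_entropy(net.forward((X, lengths), rng=None), y)
            net.conv.W[0][idx] += eps
            assert analytic[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-5)


class TestTraining:
    def test_loss_decreases_on_separable_data(self, rng):
        X = np.vstack([rng.normal(-2, 1, (100, 10)), rng.normal(2, 1, (100, 10))])
        y = np.array([0] * 100 + [1] * 100)
        net = build_submodel("FCNN_TF", input_dim=10, seed=0)
        model = train(net, X, y, TrainConfig(epochs=45, seed=0), name="FCNN_TF")
        assert len(model.history) == 45
        assert model.history[-1]["train_loss"] < model.history[0]["train_loss"]

    def test_same_seed_reproduces_history(self, rng):
        X = rng.normal(size=(64, 8))
        y = (X[:, 0] > 0).astype(int)
        histories = []
        for _ in range(2):
            net = build_submodel("FCNN_TF", input_dim=8, seed=5)
            m = train(net, X, y, TrainConfig(epochs=3, seed=5), name="FCNN_TF")
            histories.append([h["train_loss"] for h in m.history])
        assert histories[0][0] == pytest.approx(histories[1][0], abs=1e-6)
        assert histories[0] == pytest.approx(histories[1])

    def test_can_overfit_32_memorizable_records(self, rng):
        X = rng.normal(size=(32, 20))
        y = rng.integers(0, 2, 32)
        net = build_submodel("FCNN_TF", input_dim=20, seed=1)
        cfg = TrainConfig(epochs=300, learning_rate=1e-2, seed=1)
        model = train(net, X, y, cfg, name="FCNN_TF")
        assert model.history[-1]["train_loss"] < 0.05

    def test_empty_train_raises(self):
        net = build_submodel("FCNN_TF", input_dim=4)
        with pytest.raises(ValueError):
            train(net, np.zeros((0, 4)), np.zeros(0, int), TrainConfig())


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(-1, 1, (40, 6)), rng.normal(1, 1, (40, 6))])
    y = np.array([0] * 40 + [1] * 40)
    net = build_submodel("FCNN_TF", input_dim=6, seed=0)
    return train(net, X, y, TrainConfig(epochs=20, seed=0), name="FCNN_TF")


class TestPrediction:

    def test_scores_are_probabilities(self, trained, rng):
        X = rng.normal(size=(10, 6))
        ranking = predict_scores(trained, X, [f"r{i}" for i in range(10)])
        scores = [s for _, s, _ in ranking.entries]
        assert all(0.0 <= s <= 1.0 for s in scores)
        assert all(np.isfinite(scores))

    def test_duplicate_rows_get_identical_scores(self, trained, rng):
        x = rng.normal(size=(1, 6))
        X = np.vstack([x, x])
        ranking = predict_scores(trained, X, ["a", "b"])
        scores = ranking.scores()
        assert scores["a"] == scores["b"]

    def test_ranks_descending_with_id_tie_break(self, trained, rng):
        X = rng.normal(size=(8, 6))
        ranking = predict_scores(trained, X, [f"r{i}" for i in range(8)])
        scores = [s for _, s, _ in ranking.entries]
        assert scores == sorted(scores, reverse=True)
        ranks = [r for _, _, r in ranking.entries]
        assert ranks == list(range(1, 9))

    def test_rank_order_invariant_under_monotone_transforms(self, rng):
        """A strictly monotone transform of scores never changes the order."""
        from peptigen.ensemble import RankedList

        for _ in range(20):
            scores = rng.uniform(size=12)
            ids = [f"r{i}" for i in range(12)]
            base = RankedList.from_scores(ids, scores).record_ids
            a, b = rng.uniform(0.5, 3.0), rng.uniform(-2, 2)
            transformed = np.exp(a * scores) + b
            assert RankedList.from_scores(ids, transformed).record_ids == base


class TestPipelineHygiene:
    def test_pipeline_scores_only_original_records(self):
        """SMOTE-generated rows never appear in a prediction: the ranking
        covers exactly the evaluation dataset's record ids."""
        ds, _ = generate_training_set(GeneratorSpec(n_records=160, seed=4))
        from peptigen.preprocess import SplitSpec, split

        tr, va, te = split(ds, SplitSpec(seed=4))
        pipe = SubmodelPipeline(
            "FCNN_BioBERT",
            seed=4,
            train_config=TrainConfig(epochs=3, seed=4),
        )
        pipe.fit(tr, va)
        ranking = pipe.predict(te)
        assert sorted(ranking.record_ids) == sorted(te.record_ids())

    def test_fit_requires_train_role(self):
        ds, _ = generate_training_set(GeneratorSpec(n_records=60, seed=1))
        ds.role = "test"
        with pytest.raises(ValueError, match="train"):
            SubmodelPipeline("FCNN_BioBERT", seed=0).fit(ds)
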