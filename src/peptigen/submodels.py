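"""The three immunogenicity submodels and their end-to-end pipelines.

Architecture and training hyperparameters per submodel:

* ``FCNN_TF`` — peptide+HLA merged, 6-mer sliced, TF-IDF encoded; dense(64)
  -> ReLU -> dropout 0.2 -> dense(2); batch 32, 45 epochs, Adam lr 1e-4.
* ``CNN_BioBERT`` — 4-mer tokens, fixed contextual embeddings at token
  level; three parallel 1-D convolutions of widths [3, 4, 5] with 120
  filters each, ReLU + global max pooling per branch, concatenation,
  dropout 0.1, dense classifier; batch 32, 19 epochs, Adam lr 1e-4.
* ``FCNN_BioBERT`` — 2-mer tokens, mean-pooled embeddings concatenated
  with the 11 z-scored structured features; dense(53) -> ReLU -> dropout
  0.5 -> dense(2); batch 32, 31 epochs, Adam lr 1e-4.

The classifier head emits raw logits; the immunogenicity score is the
softmax probability of the positive class.  Training uses two-class
cross-entropy and a fixed epoch budget (no early stopping; validation
data is monitored only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import _nn
from .encoders import (
    ContextualEmbedder,
    DeterministicStubEmbedder,
    EncodedMatrix,
    TfidfModel,
    TokenMatrixBatch,
    embed,
    fit_tfidf,
    tokenize_dataset,
    transform_tfidf,
)
from .ensemble import RankedList
from .preprocess import SmoteConfig, ZScoreScaler, apply_scaler, fit_scaler, smote
from .records_io import FEATURE_NAMES, LABEL_IMMUNOGENIC, Dataset

SUBMODEL_NAMES = ("FCNN_TF", "CNN_BioBERT", "FCNN_BioBERT")


@dataclass(frozen=True)
class FcnnConfig:
    input_dim: int
    hidden_size: int
    dropout: float
    n_classes: int = 2


@dataclass(frozen=True)
class CnnConfig:
    embed_dim: int
    kernel_widths: tuple[int, ...] = (3, 4, 5)
    filters_per_width: int = 120
    dropout: float = 0.1
    n_classes: int = 2


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    epochs: int = 45
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    seed: int = 0


DEFAULT_TRAIN_CONFIGS: dict[str, TrainConfig] = {
    "FCNN_TF": TrainConfig(batch_size=32, epochs=45, learning_rate=1e-4),
    "CNN_BioBERT": TrainConfig(batch_size=32, epochs=19, learning_rate=1e-4),
    "FCNN_BioBERT": TrainConfig(batch_size=32, epochs=31, learning_rate=1e-4),
}

KMER_BY_SUBMODEL = {"FCNN_TF": 6, "CNN_BioBERT": 4, "FCNN_BioBERT": 2}
N_STRUCTURED_FEATURES = len(FEATURE_NAMES)


class FcnnNet:
    """dense(input -> hidden) -> ReLU -> dropout -> dense(hidden -> 2)."""

    def __init__(self, config: FcnnConfig, rng: np.random.Generator):
        self.config = config
        self.fc1 = _nn.Dense(config.input_dim, config.hidden_size, rng)
        self.relu = _nn.ReLU()
        self.drop = _nn.Dropout(config.dropout)
        self.fc2 = _nn.Dense(config.hidden_size, config.n_classes, rng)

    @property
    def layer_summary(self) -> list[str]:
        c = self.config
        return [
            f"dense({c.input_dim}->{c.hidden_size})",
            "relu",
            f"dropout({c.dropout})",
            f"dense({c.hidden_size}->{c.n_classes})",
        ]

    @property
    def n_params(self) -> int:
        return self.fc1.n_params + self.fc2.n_params

    def forward(self, x, rng: np.random.Generator | None = None) -> np.ndarray:
        h = self.fc1.forward(x)
        h = self.relu.forward(h)
        h = self.drop.forward(h, rng)
        return self.fc2.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.fc2.backward(dlogits)
        g = self.drop.backward(g)
        g = self.relu.backward(g)
        self.fc1.backward(g)

    def params(self):
        return self.fc1.params() + self.fc2.params()


class CnnNet:
    """Three parallel conv branches -> concat -> dropout -> dense classifier."""

    def __init__(self, config: CnnConfig, rng: np.random.Generator):
        self.config = config
        self.conv = _nn.MultiWidthConv1d(
            list(config.kernel_widths), config.filters_per_width, config.embed_dim, rng
        )
        self.drop = _nn.Dropout(config.dropout)
        self.fc = _nn.Dense(
            len(config.kernel_widths) * config.filters_per_width, config.n_classes, rng
        )

    @property
    def layer_summary(self) -> list[str]:
        c = self.config
        branches = [
            f"conv1d(width={w},filters={c.filters_per_width})+relu+maxpool"
            for w in c.kernel_widths
        ]
        concat_dim = len(c.kernel_widths) * c.filters_per_width
        return branches + [
            f"concat({concat_dim})",
            f"dropout({c.dropout})",
            f"dense({concat_dim}->{c.n_classes})",
        ]

    @property
    def n_params(self) -> int:
        return self.conv.n_params + self.fc.n_params

    def forward(self, batch, rng: np.random.Generator | None = None) -> np.ndarray:
        x, lengths = batch
        h = self.conv.forward(x, lengths)
        h = self.drop.forward(h, rng)
        return self.fc.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.fc.backward(dlogits)
        g = self.drop.backward(g)
        self.conv.backward(g)

    def params(self):
        return self.conv.params() + self.fc.params()


def build_submodel(
    name: str,
    input_dim: int | None = None,
    embed_dim: int | None = None,
    seed: int = 0,
):
    """Construct an untrained submodel with its canonical architecture."""
    rng = np.random.default_rng(seed)
    if name == "FCNN_TF":
        if input_dim is None:
            raise ValueError("FCNN_TF requires input_dim (TF-IDF vocabulary size)")
        return FcnnNet(FcnnConfig(input_dim=input_dim, hidden_size=64, dropout=0.2), rng)
    if name == "CNN_BioBERT":
        if embed_dim is None:
            raise ValueError("CNN_BioBERT requires embed_dim")
        return CnnNet(CnnConfig(embed_dim=embed_dim), rng)
    if name == "FCNN_BioBERT":
        if embed_dim is None:
            raise ValueError("FCNN_BioBERT requires embed_dim")
        return FcnnNet(
            FcnnConfig(
                input_dim=embed_dim + N_STRUCTURED_FEATURES, hidden_size=53, dropout=0.5
            ),
            rng,
        )
    raise ValueError(f"unknown submodel {name!r}; expected one of {SUBMODEL_NAMES}")


@dataclass
class TrainedSubmodel:
    name: str
    net: object
    train_config: TrainConfig
    history: list[dict[str, float]] = field(default_factory=list)

    def score(self, data) -> np.ndarray:
        logits = self.net.forward(data, rng=None)
        return _nn.softmax(logits)[:, 1]


class DivergenceError(RuntimeError):
    pass


def train(
    net,
    train_data,
    train_labels: np.ndarray,
    config: TrainConfig,
    name: str = "",
    validation_data=None,
    validation_labels: np.ndarray | None = None,
) -> TrainedSubmodel:
    """Train for exactly ``config.epochs`` epochs of seeded mini-batch Adam.

    ``train_data`` is a design matrix (dense or sparse) for FCNNs or a
    ``(tensor, lengths)`` pair for the CNN.  Validation data, when given,
    is scored after each epoch for monitoring only.
    """
    y = np.asarray(train_labels, dtype=int)
    n = len(y)
    if n == 0:
        raise ValueError("empty training partition")
    rng = np.random.default_rng(config.seed)
    opt = _nn.Adam(lr=config.learning_rate)
    is_pair = isinstance(train_data, tuple)
    history: list[dict[str, float]] = []
    for epoch in range(config.epochs):
        losses = []
        for idx in _nn.iterate_minibatches(n, config.batch_size, rng):
            if is_pair:
                xb = (train_data[0][idx], train_data[1][idx])
            else:
                xb = train_data[idx]
            logits = net.forward(xb, rng=rng)
            loss, dlogits = _nn.cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch + 1}")
            net.backward(dlogits)
            opt.step(net.params())
            losses.append(loss)
        entry = {"epoch": epoch + 1, "train_loss": float(np.mean(losses))}
        if validation_data is not None and validation_labels is not None:
            vlogits = net.forward(validation_data, rng=None)
            vloss, _ = _nn.cross_entropy(vlogits, np.asarray(validation_labels, int))
            entry["val_loss"] = vloss
        history.append(entry)
    return TrainedSubmodel(name=name, net=net, train_config=config, history=history)


def predict_scores(model: TrainedSubmodel, data, row_ids: list[str]) -> RankedList:
    """Score records and return the descending-score ranking.

    The score is the softmax probability of the immunogenic class; ties
    break lexicographically on record_id.
    """
    n = data[0].shape[0] if isinstance(data, tuple) else data.shape[0]
    if n != len(row_ids):
        raise ValueError(f"data has {n} rows but {len(row_ids)} row_ids given")
    scores = model.score(data)
    return RankedList.from_scores(row_ids, scores, model_tag=model.name)


# --- End-to-end pipelines ----------------------------------------------

def _labels_binary(dataset: Dataset) -> np.ndarray:
    return np.array([1 if r.label == LABEL_IMMUNOGENIC else 0 for r in dataset])


def _feature_matrix(dataset: Dataset) -> EncodedMatrix:
    rows = []
    for rec in dataset:
        missing = [f for f in FEATURE_NAMES if f not in rec.features]
        if missing:
            raise ValueError(
                f"record {rec.record_id!r} is missing structured features {missing}"
            )
        rows.append([rec.features[f] for f in FEATURE_NAMES])
    return EncodedMatrix(
        values=np.array(rows, dtype=np.float64),
        row_ids=dataset.record_ids(),
        encoder_tag="structured-F1..F11",
        role=dataset.role,
    )


@dataclass
class SubmodelPipeline:
    """Encoder state + trained net for one submodel, fit on train data only.

    Owns whatever the submodel's encoder needs to be replayed on new data
    (the fitted TF-IDF vocabulary, the embedder, the feature scaler and
    the padded token budget), so prediction uses exactly the training-time
    representation.
    """

    name: str
    embedder: ContextualEmbedder | None = None
    hla_repr: str = "allele_name"
    smote_config: SmoteConfig | None = None
    train_config: TrainConfig | None = None
    seed: int = 0

    tfidf: TfidfModel | None = field(default=None, repr=False)
    scaler: ZScoreScaler | None = field(default=None, repr=False)
    max_tokens: int | None = field(default=None, repr=False)
    model: TrainedSubmodel | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.name not in SUBMODEL_NAMES:
            raise ValueError(f"unknown submodel {self.name!r}")
        if self.name != "FCNN_TF" and self.embedder is None:
            self.embedder = DeterministicStubEmbedder()
        if self.train_config is None:
            base = DEFAULT_TRAIN_CONFIGS[self.name]
            self.train_config = TrainConfig(
                batch_size=base.batch_size,
                epochs=base.epochs,
                learning_rate=base.learning_rate,
                seed=self.seed,
            )
        if self.smote_config is None:
            self.smote_config = SmoteConfig(seed=self.seed)

    @property
    def k(self) -> int:
        return KMER_BY_SUBMODEL[self.name]

    def _encode(self, dataset: Dataset, fitting: bool):
        toks = tokenize_dataset(dataset, self.k, hla_repr=self.hla_repr)
        if self.name == "FCNN_TF":
            if fitting:
                self.tfidf = fit_tfidf(toks)
            return transform_tfidf(self.tfidf, toks, role=dataset.role).values
        if self.name == "CNN_BioBERT":
            batch = embed(toks, self.embedder, pooling="none", role=dataset.role)
            assert isinstance(batch, TokenMatrixBatch)
            if fitting:
                self.max_tokens = max(m.shape[0] for m in batch.matrices)
            return batch.padded(self.max_tokens)
        # FCNN_BioBERT: pooled embeddings + z-scored structured features
        pooled = embed(toks, self.embedder, pooling="mean", role=dataset.role)
        feats = _feature_matrix(dataset)
        if fitting:
            self.scaler = fit_scaler(feats)
        scaled = apply_scaler(self.scaler, feats)
        return np.hstack([pooled.dense(), scaled.dense()])

    def fit(self, train_ds: Dataset, validation_ds: Dataset | None = None) -> "SubmodelPipeline":
        if train_ds.role != "train":
            raise ValueError(f"fit requires a train-tagged dataset, got {train_ds.role!r}")
        X = self._encode(train_ds, fitting=True)
        y = _labels_binary(train_ds)
        # SMOTE in the submodel's own design-matrix space (the CNN's padded
        # token tensor is flattened for interpolation, then reshaped back).
        if isinstance(X, tuple):
            tensor, lengths = X
            n, T, d = tensor.shape
            flat, y_aug, syn = smote(tensor.reshape(n, T * d), y, self.smote_config)
            len_aug = np.concatenate(
                [lengths, np.full(syn.sum(), T, dtype=lengths.dtype)]
            )
            X_train = (flat.reshape(-1, T, d), len_aug)
        else:
            X_aug, y_aug, syn = smote(X, y, self.smote_config)
            X_train = X_aug
        val_X = val_y = None
        if validation_ds is not None:
            val_X = self._encode(validation_ds, fitting=False)
            val_y = _labels_binary(validation_ds)
        if self.name == "FCNN_TF":
            net = build_submodel(self.name, input_dim=X.shape[1], seed=self.seed)
        else:
            net = build_submodel(self.name, embed_dim=self.embedder.dimension, seed=self.seed)
        self.model = train(
            net,
            X_train,
            y_aug,
            self.train_config,
            name=self.name,
            validation_data=val_X,
            validation_labels=val_y,
        )
        return self

    def predict(self, dataset: Dataset) -> RankedList:
        if self.model is None:
            raise RuntimeError("pipeline has not been fitted")
        X = self._encode(dataset, fitting=False)
        return predict_scores(self.model, X, dataset.record_ids())

    def score(self, dataset: Dataset) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("pipeline has not been fitted")
        return self.model.score(self._encode(dataset, fitting=False))
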