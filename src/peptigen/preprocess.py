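"""Train-only preprocessing: z-score scaling, SMOTE rebalancing, splitting.

The contract throughout is strict train/evaluation hygiene: the scaler is
fitted on the training partition only, SMOTE-generated rows are flagged so
they can never leak into an evaluation partition, and splits are seeded
and (by default) stratified by label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, KFold, train_test_split
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler

from .encoders import EncodedMatrix
from .records_io import Dataset


class RoleError(RuntimeError):
    """An operation was attempted on data from the wrong partition."""


@dataclass
class ZScoreScaler:
    """Column-wise z-score transform fitted on the training partition.

    Uses the population (n) standard deviation so the fitting data itself
    maps to mean 0 / std 1 exactly; constant columns map to 0 with a
    warning.  Fitted statistics are immutable after fit.
    """

    _scaler: StandardScaler = field(default_factory=StandardScaler)
    fitted_on: str | None = None

    @property
    def means(self) -> np.ndarray:
        self._require_fitted()
        return self._scaler.mean_

    @property
    def stds(self) -> np.ndarray:
        self._require_fitted()
        return np.sqrt(self._scaler.var_)

    def _require_fitted(self) -> None:
        if self.fitted_on is None:
            raise RoleError("scaler has not been fitted")


def fit_scaler(train_matrix: EncodedMatrix) -> ZScoreScaler:
    if train_matrix.role != "train":
        raise RoleError(
            f"scaler must be fitted on the train partition, got role "
            f"{train_matrix.role!r}"
        )
    X = train_matrix.dense()
    scaler = ZScoreScaler()
    scaler._scaler.fit(X)
    if np.any(scaler._scaler.var_ == 0):
        warnings.warn("constant column(s) present; they scale to 0", stacklevel=2)
    scaler.fitted_on = train_matrix.encoder_tag
    return scaler


def apply_scaler(scaler: ZScoreScaler, matrix: EncodedMatrix) -> EncodedMatrix:
    scaler._require_fitted()
    X = scaler._scaler.transform(matrix.dense())
    return EncodedMatrix(
        values=X,
        row_ids=list(matrix.row_ids),
        encoder_tag=f"{matrix.encoder_tag}-zscored",
        role=matrix.role,
    )


# --- SMOTE --------------------------------------------------------------

@dataclass(frozen=True)
class SmoteConfig:
    k_neighbors: int = 5
    target_ratio: float = 1.0
    seed: int = 0


def smote(
    X: np.ndarray,
    y: np.ndarray,
    config: SmoteConfig = SmoteConfig(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rebalance by synthetic minority over-sampling.

    Each synthetic row is ``x + u * (x_nn - x)`` for a minority point x,
    one of its ``k_neighbors`` nearest minority neighbors x_nn (Euclidean)
    and u ~ U[0, 1].  Returns ``(X_out, y_out, synthetic_mask)`` with
    originals first and unchanged; the mask flags synthetic rows so they
    can be excluded from any evaluation.  ``X`` may be a scipy sparse
    matrix (the output is then sparse too).
    """
    import scipy.sparse as sp

    sparse = sp.issparse(X)
    if sparse:
        X = X.tocsr()
    else:
        X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"SMOTE requires exactly two classes, got {list(classes)}")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if config.k_neighbors >= n_min:
        raise ValueError(
            f"k_neighbors={config.k_neighbors} must be < minority class size {n_min}"
        )
    target = int(round(config.target_ratio * n_maj))
    n_new = max(0, target - n_min)
    mask = np.zeros(len(y) + n_new, dtype=bool)
    if n_new == 0:
        return X.copy(), y.copy(), mask
    rng = np.random.default_rng(config.seed)
    min_idx = np.flatnonzero(y == minority)
    Xmin = X[min_idx]
    nn = NearestNeighbors(n_neighbors=config.k_neighbors + 1).fit(Xmin)
    _, neigh = nn.kneighbors(Xmin)
    neigh = neigh[:, 1:]  # drop self
    base = rng.integers(0, Xmin.shape[0], size=n_new)
    pick = rng.integers(0, config.k_neighbors, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    anchors = Xmin[base]
    partners = Xmin[neigh[base, pick]]
    if sparse:
        U = sp.diags(u)
        synthetic = anchors + U @ (partners - anchors)
        X_out = sp.vstack([X, synthetic], format="csr")
    else:
        synthetic = anchors + u[:, None] * (partners - anchors)
        X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    mask[len(y) :] = True
    return X_out, y_out, mask


# --- Splitting ----------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    stratify_by_label: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {self.fractions}")
        if any(f <= 0 for f in self.fractions):
            raise ValueError("every split fraction must be > 0")


def split(dataset: Dataset, spec: SplitSpec = SplitSpec()) -> tuple[Dataset, Dataset, Dataset]:
    """Split into train/validation/test partitions by the given fractions."""
    idx = np.arange(len(dataset))
    labels = np.array(dataset.labels())
    f_train, f_val, f_test = spec.fractions
    strat = labels if spec.stratify_by_label else None
    idx_train, idx_rest = train_test_split(
        idx,
        train_size=f_train,
        random_state=spec.seed,
        stratify=strat,
        shuffle=True,
    )
    rest_labels = labels[idx_rest] if spec.stratify_by_label else None
    idx_val, idx_test = train_test_split(
        idx_rest,
        train_size=f_val / (f_val + f_test),
        random_state=spec.seed + 1,
        stratify=rest_labels,
        shuffle=True,
    )

    def _subset(indices: np.ndarray, role: str) -> Dataset:
        indices = np.sort(indices)  # preserve original relative order
        return Dataset(records=[dataset.records[i] for i in indices], role=role)

    return (
        _subset(idx_train, "train"),
        _subset(idx_val, "validation"),
        _subset(idx_test, "test"),
    )


def kfold(dataset: Dataset, k: int = 5, seed: int = 0, stratify: bool = True) -> np.ndarray:
    """Assign each record a fold index in 0..k-1 (stratified by default)."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    labels = np.array(dataset.labels())
    if stratify:
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() < k:
            raise ValueError(
                f"smallest class has {counts.min()} records, fewer than k={k} folds"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        iterator = splitter.split(np.zeros(len(labels)), labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        iterator = splitter.split(np.zeros(len(labels)))
    assignment = np.full(len(labels), -1, dtype=int)
    for fold, (_, test_idx) in enumerate(iterator):
        assignment[test_idx] = fold
    return assignment


def write_split_manifest(path, datasets: dict[str, Dataset]) -> None:
    import pandas as pd

    rows = [
        {"record_id": rec.record_id, "partition": name}
        for name, ds in datasets.items()
        for rec in ds
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
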