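"""Predicting word concreteness from embeddings under tenfold CV.

Does grounding sharpen the separation between concrete and abstract
words? The protocol regresses standardized concreteness ratings on word
vectors with (a) an ordinary linear regression and (b) a two-hidden-
layer perceptron (512 and 100 units, ReLU, batch normalization and
dropout), under tenfold cross-validation, scoring each held-out fold by
Spearman's rho and reporting the mean rho x 100 across folds.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LinearRegression

from .autodiff import Tensor, mse as mse_tensor
from .errors import CoverageError, DegenerateInputError
from .evaluation import spearman_rho, standardize
from .io_formats import ConcretenessRatings, EmbeddingTable
from .layers import BatchNorm1d, Dropout, Linear, Module
from .optim import make_optimizer

MODEL_KINDS = ("linear", "mlp")


@dataclass
class CVResult:
    model_kind: str
    fold_rhos: list[float]
    seed: int
    folds: list[np.ndarray] = field(default_factory=list)

    @property
    def mean_rho_x100(self) -> float:
        return float(np.mean(self.fold_rhos) * 100.0)


def fit_linear_regressor(X: np.ndarray, y: np.ndarray) -> LinearRegression:
    """Ordinary least-squares regression of y on X; deterministic."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != y.shape[0] or X.shape[0] == 0:
        raise DegenerateInputError("X must be (n, d) with matching y length")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise DegenerateInputError("non-finite values in regression inputs")
    return LinearRegression().fit(X, y)


class MLPRegressor(Module):
    """512 -> 100 perceptron with batch normalization and dropout.

    Training details left open by the protocol are fixed defaults here:
    ReLU activations, dropout rate 0.2 (disabled at prediction), 50
    epochs of NAdam at 1e-3 on batches of 64, seeded end to end.
    """

    def __init__(self, n_in: int, seed: int = 0, hidden: tuple[int, int] = (512, 100),
                 dropout: float = 0.2, epochs: int = 50, batch_size: int = 64,
                 learning_rate: float = 1e-3):
        rng = np.random.default_rng(seed)
        self.fc1 = Linear(rng, n_in, hidden[0])
        self.bn1 = BatchNorm1d(hidden[0])
        self.do1 = Dropout(dropout, rng)
        self.fc2 = Linear(rng, hidden[0], hidden[1])
        self.bn2 = BatchNorm1d(hidden[1])
        self.do2 = Dropout(dropout, rng)
        self.out = Linear(rng, hidden[1], 1)
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.rng = rng
        self.loss_trace: list[float] = []

    def _forward(self, x: Tensor) -> Tensor:
        h = self.do1(self.bn1(self.fc1(x)).relu())
        h = self.do2(self.bn2(self.fc2(h)).relu())
        return self.out(h)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLPRegressor":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).reshape(-1, 1)
        if X.shape[0] == 0:
            raise DegenerateInputError("empty training set")
        opt = make_optimizer("nadam", self.parameters(), self.learning_rate)
        order = np.arange(X.shape[0])
        self.set_training(True)
        for _ in range(self.epochs):
            self.rng.shuffle(order)
            epoch_loss, n = 0.0, 0
            for start in range(0, len(order), self.batch_size):
                idx = order[start:start + self.batch_size]
                if len(idx) < 2:
                    continue  # batchnorm needs >= 2 rows
                loss = mse_tensor(self._forward(Tensor(X[idx])), Tensor(y[idx]))
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data)
                n += 1
            self.loss_trace.append(epoch_loss / max(n, 1))
        self.set_training(False)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        self.set_training(False)
        return self._forward(Tensor(np.asarray(X, dtype=np.float64))).data.ravel()


def fit_mlp_regressor(X: np.ndarray, y: np.ndarray, seed: int = 0,
                      **kwargs) -> MLPRegressor:
    return MLPRegressor(n_in=X.shape[1], seed=seed, **kwargs).fit(X, y)


def crossval_concreteness(table: EmbeddingTable, ratings: ConcretenessRatings,
                          model_kind: str = "linear", seed: int = 0,
                          n_folds: int = 10) -> CVResult:
    """Tenfold CV of concreteness prediction from word vectors.

    Words present in both the table and the ratings are shuffled by
    ``seed`` into ``n_folds`` near-equal folds (sizes differ by at most
    one and partition the data). Targets are the standardized ratings.
    For each fold the model trains on the other folds and is scored by
    Spearman's rho on the held-out fold; the result reports all fold
    rhos and their mean x 100.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
    words = [w for w in table.words if w in ratings]
    if len(words) < n_folds:
        raise CoverageError(
            f"need >= {n_folds} rated in-vocabulary words, have {len(words)}")
    raw = np.array([ratings[w] for w in words], dtype=np.float64)
    if np.ptp(raw) == 0:
        raise DegenerateInputError("constant concreteness targets")
    y = standardize(raw)
    X = np.stack([table.lookup(w) for w in words])
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(words))
    folds = [np.sort(f) for f in np.array_split(perm, n_folds)]
    fold_rhos: list[float] = []
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, test_idx)
        if model_kind == "linear":
            model = fit_linear_regressor(X[train_idx], y[train_idx])
        else:
            model = fit_mlp_regressor(X[train_idx], y[train_idx],
                                      seed=seed * n_folds + i)
        preds = model.predict(X[test_idx])
        fold_rhos.append(spearman_rho(preds, y[test_idx]))
    return CVResult(model_kind=model_kind, fold_rhos=fold_rhos, seed=seed,
                    folds=folds)
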