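"""The grounding model: a linear text-to-vision alignment learned from captions.

The model maps a textual word vector ``t`` (dimension *d*) into a
grounded space of dimension *c* through a linear alignment ``M`` with no
bias, ``g = t @ M``. During training a caption's grounded token vectors
are summarized by a *bridge* encoder (word-level regression, bag of
words, GRU, LSTM, or stacked transformer encoders) whose output is
regressed onto the caption's image feature vector under a mean-squared
error over all batch x D_img elements. The textual embedding table and
the image vectors are frozen throughout; only ``M``, the encoder
parameters and an optional projection head are optimized.

After training, ``M`` alone is applied to an *entire* vocabulary — the
zero-shot step: words never seen in any caption, including abstract
ones, receive grounded vectors by the same matrix product.

Ablation variants replace the identity activation after ``M`` with ReLU
or Leaky-ReLU, optionally stacking a second activated c x c layer, which
lets images deform the textual space beyond a linear map.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .autodiff import Tensor
from .errors import (DegenerateInputError, EmptyInputError, ShapeError)
from .io_formats import CaptionImageDataset, EmbeddingTable
from .layers import (BoWEncoder, GRUEncoder, Linear, LSTMEncoder, Module,
                     TransformerEncoder, _param, _zeros)
from .optim import make_optimizer
from .preprocessing import CaptionVocabulary, filter_caption
from .stopwords import remove_stop_words

logger = logging.getLogger(__name__)

ENCODER_KINDS = ("word_level", "bow", "gru", "lstm", "transformer")
ACTIVATIONS = ("linear", "relu", "leaky_relu")


@dataclass
class GroundingConfig:
    """Hyper-parameters of a grounding run.

    Defaults reproduce the reference setup: grounded dimension 1024 from
    2048-dimensional image vectors, a single-layer LSTM with 2048 units
    (so the final hidden state is itself the image prediction and no
    projection head is needed), batches of 256, at most 20 epochs with
    early stopping after 5 non-improving validation epochs, NAdam at
    learning rate 1e-3, and a purely linear alignment.
    """

    d: int = 300
    c: int = 1024
    d_img: int = 2048
    encoder_kind: str = "lstm"
    encoder_layers: int = 1
    encoder_units: int = 2048
    activation: str = "linear"
    activation_layers: int = 1
    batch_size: int = 256
    max_epochs: int = 20
    patience: int = 5
    learning_rate: float = 1e-3
    optimizer_kind: str = "nadam"
    transformer_heads: int = 16
    learned_initial_state: bool = False
    leaky_relu_alpha: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.encoder_kind not in ENCODER_KINDS:
            raise ValueError(f"encoder_kind must be one of {ENCODER_KINDS}")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")
        for name in ("d", "c", "d_img", "encoder_layers", "encoder_units",
                     "batch_size", "max_epochs", "patience", "activation_layers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class TrainingTrace:
    """Per-epoch loss history plus the early-stopping bookkeeping."""

    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0

    def __post_init__(self) -> None:
        if self.val_losses and self.stopped_epoch - self.best_epoch < 0:
            raise ValueError("best_epoch cannot exceed stopped_epoch")


class GroundingModel(Module):
    """Alignment ``M`` plus the bridge encoder used only during training."""

    def __init__(self, config: GroundingConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.M = _param(rng, (config.d, config.c))
        # extra activated c x c layers for deep nonlinear ablations
        self.extra_layers: list[Tensor] = [
            _param(rng, (config.c, config.c))
            for _ in range(max(0, config.activation_layers - 1))
        ]
        self.encoder: Module | None = None
        self.projection: Linear | None = None
        kind = config.encoder_kind
        if kind == "lstm":
            self.encoder = LSTMEncoder(rng, config.c, config.encoder_units,
                                       config.encoder_layers,
                                       config.learned_initial_state)
            if config.encoder_units != config.d_img:
                self.projection = Linear(rng, config.encoder_units, config.d_img)
        elif kind == "gru":
            self.encoder = GRUEncoder(rng, config.c, config.encoder_units,
                                      config.encoder_layers,
                                      config.learned_initial_state)
            if config.encoder_units != config.d_img:
                self.projection = Linear(rng, config.encoder_units, config.d_img)
        elif kind == "bow":
            self.encoder = BoWEncoder(rng, config.c, config.encoder_units,
                                      config.d_img)
        elif kind == "transformer":
            self.encoder = TransformerEncoder(rng, config.c, config.encoder_units,
                                              config.d_img, config.encoder_layers,
                                              config.transformer_heads)
        # word_level: no encoder; M is fit directly by least squares.

    # -- grounding (numpy inference path) ----------------------------------

    def _activate(self, x: np.ndarray) -> np.ndarray:
        a = self.config.activation
        if a == "linear":
            return x
        if a == "relu":
            return np.maximum(x, 0.0)
        return np.where(x > 0, x, self.config.leaky_relu_alpha * x)

    def ground_word_vector(self, t: np.ndarray) -> np.ndarray:
        """Map a textual vector into the grounded space: ``t @ M`` plus
        the configured activation stack. With a linear activation this is
        exactly the matrix product."""
        t = np.asarray(t, dtype=np.float64)
        if t.shape[-1] != self.config.d:
            raise ShapeError(
                f"expected dimension {self.config.d}, got {t.shape[-1]}")
        g = self._activate(t @ self.M.data)
        for layer in self.extra_layers:
            g = self._activate(g @ layer.data)
        return g

    def ground_vocabulary(self, table: EmbeddingTable) -> EmbeddingTable:
        """Apply the alignment to every row of a table — the zero-shot
        step; words unseen during training are treated identically."""
        if table.dim != self.config.d:
            raise ShapeError(
                f"table dim {table.dim} != alignment input dim {self.config.d}")
        return EmbeddingTable(words=list(table.words),
                              matrix=self.ground_word_vector(table.matrix))

    # -- encoding (autodiff path) ------------------------------------------

    def _ground_tensor(self, x: Tensor) -> Tensor:
        g = x @ self.M
        g = self._activate_tensor(g)
        for layer in self.extra_layers:
            g = self._activate_tensor(g @ layer)
        return g

    def _activate_tensor(self, x: Tensor) -> Tensor:
        a = self.config.activation
        if a == "linear":
            return x
        if a == "relu":
            return x.relu()
        return x.leaky_relu(self.config.leaky_relu_alpha)

    def forward_caption(self, sequences: Tensor) -> Tensor:
        """(batch, n, d) textual sequences -> (batch, D_img) predictions."""
        if self.encoder is None:
            raise ValueError("word_level models do not encode captions")
        grounded = self._ground_tensor(sequences)
        out = self.encoder(grounded)
        if self.projection is not None:
            out = self.projection(out)
        return out

    def encode_caption(self, grounded_seq: np.ndarray) -> np.ndarray:
        """Encode an already-grounded (n, c) sequence to a D_img vector."""
        if self.encoder is None:
            raise ValueError("word_level models do not encode captions")
        seq = np.asarray(grounded_seq, dtype=np.float64)
        if seq.ndim != 2 or seq.shape[0] == 0:
            raise EmptyInputError("encode_caption needs a nonempty (n, c) sequence")
        out = self.encoder(Tensor(seq[None, :, :]))
        if self.projection is not None:
            out = self.projection(out)
        return out.data[0]


def mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean over all elements of squared differences."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ShapeError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return float(np.mean((pred - target) ** 2))


def pca_reduce(vectors: np.ndarray, target_dim: int) -> tuple[PCA, np.ndarray]:
    """Orthonormal projection onto the top ``target_dim`` principal axes.

    Fit on the supplied (training-split) vectors only; components are
    ordered by decreasing explained variance.
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.shape[0] < target_dim:
        raise DegenerateInputError(
            f"need >= {target_dim} vectors to extract {target_dim} components")
    rank = np.linalg.matrix_rank(vectors - vectors.mean(axis=0))
    if target_dim > rank:
        raise DegenerateInputError(
            f"target_dim {target_dim} exceeds data rank {rank}")
    pca = PCA(n_components=target_dim, svd_solver="full")
    reduced = pca.fit_transform(vectors)
    return pca, reduced


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _prepare_arrays(dataset: CaptionImageDataset, table: EmbeddingTable,
                    vocabulary: CaptionVocabulary
                    ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Token-index sequences and image vectors for non-empty captions."""
    seqs: list[np.ndarray] = []
    targets: list[np.ndarray] = []
    for record, image_vec in dataset.records:
        kept = filter_caption(record.tokens, vocabulary)
        kept = [t for t in kept if t in table]
        if not kept:
            continue
        seqs.append(np.array([table.index(t) for t in kept], dtype=np.intp))
        targets.append(np.asarray(image_vec, dtype=np.float64))
    return seqs, targets


def _batch_forward(model: GroundingModel, table: EmbeddingTable,
                   seqs: Sequence[np.ndarray], targets: Sequence[np.ndarray],
                   ) -> Tensor:
    """Loss over one batch, grouping captions of equal length so each
    group forms a dense (group, n, d) tensor."""
    total = None
    n_elems = 0
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    d_img = model.config.d_img
    for length in sorted(by_len):
        idx = by_len[length]
        x = Tensor(np.stack([table.matrix[seqs[i]] for i in idx]))
        y = np.stack([targets[i] for i in idx])
        pred = model.forward_caption(x)
        diff = pred - Tensor(y)
        sq = (diff * diff).sum()
        total = sq if total is None else total + sq
        n_elems += len(idx) * d_img
    assert total is not None
    return total * (1.0 / n_elems)


def _validation_loss(model: GroundingModel, table: EmbeddingTable,
                     seqs: Sequence[np.ndarray],
                     targets: Sequence[np.ndarray]) -> float:
    if not seqs:
        return float("nan")
    model.set_training(False)
    loss = _batch_forward(model, table, seqs, targets)
    model.set_training(True)
    return float(loss.data)


def train_grounding(dataset: CaptionImageDataset, table: EmbeddingTable,
                    vocabulary: CaptionVocabulary, config: GroundingConfig,
                    validation: CaptionImageDataset | None = None,
                    ) -> tuple[GroundingModel, TrainingTrace]:
    """Fit the alignment (and bridge) by minimizing the image-prediction MSE.

    ``dataset`` is the training split; ``validation`` drives early
    stopping (no improvement for ``patience`` consecutive epochs halts
    the run and the best epoch's parameters are restored). The textual
    table is frozen: it is never modified. Fully deterministic given
    ``config.seed``.

    ``encoder_kind="word_level"`` bypasses the encoder entirely: stop
    words are removed, image vectors are PCA-reduced to dimension *c*
    when ``c != D_img``, and ``M`` is the ordinary least-squares
    regression of each remaining word's (reduced) image vector on its
    textual vector.
    """
    if config.d != table.dim:
        raise ShapeError(f"config.d={config.d} but table dim is {table.dim}")
    if config.encoder_kind == "word_level":
        return _train_word_level(dataset, table, vocabulary, config)

    model = GroundingModel(config)
    train_seqs, train_targets = _prepare_arrays(dataset, table, vocabulary)
    if not train_seqs:
        raise EmptyInputError("no usable training captions after filtering")
    val_seqs: list[np.ndarray] = []
    val_targets: list[np.ndarray] = []
    if validation is not None:
        val_seqs, val_targets = _prepare_arrays(validation, table, vocabulary)

    rng = np.random.default_rng(config.seed)
    opt = make_optimizer(config.optimizer_kind, model.parameters(),
                         config.learning_rate)
    trace = TrainingTrace()
    best_val = np.inf
    best_state = model.state_arrays()
    epochs_since_best = 0
    order = np.arange(len(train_seqs))
    for epoch in range(1, config.max_epochs + 1):
        rng.shuffle(order)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            loss = _batch_forward(model, table,
                                  [train_seqs[i] for i in batch],
                                  [train_targets[i] for i in batch])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        trace.train_losses.append(epoch_loss / n_batches)
        val_loss = _validation_loss(model, table, val_seqs, val_targets)
        trace.val_losses.append(val_loss)
        monitored = val_loss if val_seqs else trace.train_losses[-1]
        logger.info("epoch %d train %.6g val %.6g", epoch,
                    trace.train_losses[-1], val_loss)
        if monitored < best_val:
            best_val = monitored
            trace.best_epoch = epoch
            best_state = model.state_arrays()
            epochs_since_best = 0
        else:
            epochs_since_best += 1
        trace.stopped_epoch = epoch
        if epochs_since_best >= config.patience:
            logger.info("early stop at epoch %d (best %d)", epoch, trace.best_epoch)
            break
    model.load_state_arrays(best_state)
    model.set_training(False)
    return model, trace


def _train_word_level(dataset: CaptionImageDataset, table: EmbeddingTable,
                      vocabulary: CaptionVocabulary, config: GroundingConfig,
                      ) -> tuple[GroundingModel, TrainingTrace]:
    rows: list[int] = []
    img_rows: list[np.ndarray] = []
    for record, image_vec in dataset.records:
        kept = filter_caption(remove_stop_words(record.tokens), vocabulary)
        kept = [t for t in kept if t in table]
        for tok in kept:
            rows.append(table.index(tok))
            img_rows.append(np.asarray(image_vec, dtype=np.float64))
    if not rows:
        raise EmptyInputError("no usable (word, image) pairs after filtering")
    X = table.matrix[rows]
    Y = np.stack(img_rows)
    if config.c != config.d_img:
        if Y.shape[0] < config.c:
            raise DegenerateInputError(
                f"word_level PCA needs >= c={config.c} samples, got {Y.shape[0]}")
        _, Y = pca_reduce(Y, config.c)
    M, *_ = np.linalg.lstsq(X, Y, rcond=None)
    model = GroundingModel(config)
    model.M.data = M
    model.set_training(False)
    resid = mse_loss(X @ M, Y)
    trace = TrainingTrace(train_losses=[resid], val_losses=[],
                          best_epoch=1, stopped_epoch=1)
    return model, trace


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def vocabulary_hash(vocabulary: CaptionVocabulary) -> str:
    h = hashlib.sha256("\n".join(vocabulary.tokens).encode()).hexdigest()
    return h[:16]


def save_checkpoint(model: GroundingModel, path: str | Path,
                    vocabulary: CaptionVocabulary | None = None) -> None:
    """Persist config + all parameter arrays in one ``.npz`` container."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    meta = {"config": asdict(model.config),
            "vocab_hash": vocabulary_hash(vocabulary) if vocabulary else None}
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> GroundingModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"].tobytes()).decode())
        model = GroundingModel(GroundingConfig(**meta["config"]))
        params = model.parameters()
        model.load_state_arrays([data[f"param_{i}"] for i in range(len(params))])
    model.set_training(False)
    return model
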