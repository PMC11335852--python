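"""Seedable synthetic worlds with a planted, known grounding.

Real inputs to the pipeline (pre-trained embeddings, captioned image
features, human benchmarks, concreteness norms) are large external
resources. This module fabricates all four from a single generative
story with known ground truth, so training, zero-shot application,
evaluation and the concreteness analysis are testable end to end:

* a textual embedding table with iid Gaussian coordinates,
* a planted full-rank alignment ``M*`` (d x c) defining the "true"
  grounded space, plus a projection ``P`` (c x D_img) into image space,
* captions that are uniform random token sequences whose image vector is
  ``P``-projected mean of the tokens' planted grounded vectors plus
  Gaussian noise — composition is a token mean, deliberately encoder-
  agnostic so a linear bridge is well specified,
* benchmarks whose "human" score is the cosine of the two words'
  planted grounded vectors plus noise,
* concreteness ratings that are a fixed linear functional of the textual
  vector plus noise.

At noise 0 the pipeline's recovery properties hold by construction and
degrade gracefully as ``noise_sd`` grows. Every generator is a pure
function of its seed and arguments.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyInputError
from .io_formats import (CaptionImageDataset, CaptionRecord, ConcretenessRatings,
                         EmbeddingTable, WordPairBenchmark)

#: realistic caption lengths for a desk-scale corpus (COCO captions
#: average ~10 tokens; after vocabulary filtering somewhat fewer)
DEFAULT_LEN_RANGE = (4, 12)


@dataclass
class SyntheticWorld:
    """A fully reproducible planted-grounding universe."""

    table: EmbeddingTable
    M_star: np.ndarray        # d x c planted alignment
    P: np.ndarray             # c x D_img projection into image space
    seed: int

    @property
    def grounded_matrix(self) -> np.ndarray:
        return self.table.matrix @ self.M_star

    @property
    def grounded_table(self) -> EmbeddingTable:
        return EmbeddingTable(words=list(self.table.words),
                              matrix=self.grounded_matrix)


def make_world(V: int = 300, d: int = 16, c: int = 8, d_img: int = 32,
               seed: int = 0, projection: str = "random") -> SyntheticWorld:
    """Create a deterministic world; words are named ``w0000``...

    ``projection="identity"`` (requires ``c == d_img``) makes the image
    space coincide with the planted grounded space, which gives exact
    closed-form recovery targets. ``M*`` is regenerated on the
    measure-zero event that it is rank deficient.
    """
    if min(V, d, c, d_img) < 1:
        raise ValueError("V, d, c, d_img must all be >= 1")
    rng = np.random.default_rng(seed)
    matrix = rng.standard_normal((V, d))
    width = max(4, len(str(V - 1)))
    words = [f"w{i:0{width}d}" for i in range(V)]
    M_star = rng.standard_normal((d, c)) / np.sqrt(d)
    while np.linalg.matrix_rank(M_star) < min(d, c):  # pragma: no cover
        M_star = rng.standard_normal((d, c)) / np.sqrt(d)
    if projection == "identity":
        if c != d_img:
            raise ValueError("identity projection requires c == d_img")
        P = np.eye(c)
    elif projection == "random":
        P = rng.standard_normal((c, d_img)) / np.sqrt(c)
    else:
        raise ValueError("projection must be 'random' or 'identity'")
    return SyntheticWorld(table=EmbeddingTable(words=words, matrix=matrix),
                          M_star=M_star, P=P, seed=seed)


def make_caption_dataset(world: SyntheticWorld, n_samples: int = 2000,
                         len_range: tuple[int, int] = DEFAULT_LEN_RANGE,
                         noise_sd: float = 0.05, seed: int | None = None,
                         val_fraction: float = 0.1,
                         ) -> tuple[CaptionImageDataset, CaptionImageDataset]:
    """Sample captions and their image vectors; return (train, validation).

    Each caption is a uniform random token sequence with length drawn
    uniformly from ``len_range`` (inclusive); its image vector is
    ``mean_i(t_i @ M*) @ P + eps`` with iid Gaussian ``eps`` of standard
    deviation ``noise_sd``. The split is a seeded 90/10 partition.
    """
    if n_samples < 1:
        raise EmptyInputError("n_samples must be >= 1")
    rng = np.random.default_rng(world.seed + 1 if seed is None else seed)
    V = len(world.table)
    lo, hi = len_range
    records = []
    for j in range(n_samples):
        length = int(rng.integers(lo, hi + 1))
        idx = rng.integers(0, V, size=length)
        tokens = [world.table.words[i] for i in idx]
        g_mean = world.table.matrix[idx].mean(axis=0) @ world.M_star
        image = g_mean @ world.P
        if noise_sd > 0:
            image = image + rng.normal(0.0, noise_sd, size=image.shape)
        records.append((CaptionRecord(image_id=f"img{j:06d}", tokens=tokens), image))
    n_val = int(round(n_samples * val_fraction))
    perm = rng.permutation(n_samples)
    val_idx = set(perm[:n_val].tolist())
    train = [records[i] for i in range(n_samples) if i not in val_idx]
    val = [records[i] for i in range(n_samples) if i in val_idx]
    return (CaptionImageDataset(records=train, split="train"),
            CaptionImageDataset(records=val, split="validation"))


def make_benchmark(world: SyntheticWorld, n_pairs: int = 500,
                   noise_sd: float = 0.05, seed: int | None = None,
                   name: str = "synthetic") -> WordPairBenchmark:
    """Human-like scores: cosine of the planted grounded vectors + noise.

    Pairs are sampled without replacement from the distinct unordered
    (i, j) combinations.
    """
    V = len(world.table)
    if V < 2 or n_pairs < 2:
        raise EmptyInputError("need V >= 2 and n_pairs >= 2")
    max_pairs = V * (V - 1) // 2
    if n_pairs > max_pairs:
        raise ValueError(f"n_pairs={n_pairs} exceeds {max_pairs} distinct pairs")
    rng = np.random.default_rng(world.seed + 2 if seed is None else seed)
    chosen = rng.choice(max_pairs, size=n_pairs, replace=False)
    G = world.grounded_matrix
    norms = np.linalg.norm(G, axis=1)
    pairs: list[tuple[str, str, float]] = []
    for flat in np.sort(chosen):
        i, j = _unflatten_pair(int(flat), V)
        score = float(G[i] @ G[j] / (norms[i] * norms[j]))
        if noise_sd > 0:
            score += float(rng.normal(0.0, noise_sd))
        pairs.append((world.table.words[i], world.table.words[j], score))
    return WordPairBenchmark(name=name, pairs=pairs)


def _unflatten_pair(flat: int, V: int) -> tuple[int, int]:
    """Map a flat index in [0, V*(V-1)/2) to an unordered pair i < j."""
    # row i owns (V-1-i) pairs; walk rows until the index falls inside
    i = 0
    remaining = flat
    while remaining >= V - 1 - i:
        remaining -= V - 1 - i
        i += 1
    return i, i + 1 + remaining


def make_concreteness(world: SyntheticWorld, weight_seed: int = 0,
                      noise_sd: float = 0.0) -> ConcretenessRatings:
    """Ratings that are a fixed linear functional of the textual vectors.

    The weight vector depends only on ``weight_seed``; noise on
    ``world.seed`` and ``weight_seed``. Linear-in-embedding by
    construction, so an OLS regressor recovers them perfectly at noise 0.
    """
    rng = np.random.default_rng((world.seed + 3) * 1000 + weight_seed)
    w_rng = np.random.default_rng(weight_seed)
    weights = w_rng.standard_normal(world.table.dim)
    scores = world.table.matrix @ weights
    if noise_sd > 0:
        scores = scores + rng.normal(0.0, noise_sd, size=scores.shape)
    return ConcretenessRatings(
        ratings={w: float(s) for w, s in zip(world.table.words, scores)})
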