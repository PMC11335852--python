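"""Caption normalization and frequency-based vocabulary truncation.

Captions are lowercased, stripped of ASCII punctuation (characters are
deleted in place, not replaced by spaces, so ``co-pilot's`` becomes
``copilots``) and whitespace-tokenized. Training vocabularies keep only
the ``top_k`` most frequent caption tokens — frequency ties are broken
lexicographically so the truncation is deterministic — and are
intersected with the embedding table before training so that sequence
embedding can never fail mid-epoch.
"""
from __future__ import annotations

import logging
import string
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import EmptyInputError, VocabularyError
from .io_formats import CaptionRecord, EmbeddingTable

logger = logging.getLogger(__name__)

_PUNCT_TABLE = str.maketrans("", "", string.punctuation)


def normalize_caption(text: str) -> list[str]:
    """Lowercase, delete ASCII punctuation, split on whitespace."""
    tokens = [t.translate(_PUNCT_TABLE) for t in text.lower().split()]
    return [t for t in tokens if t]


@dataclass
class CaptionVocabulary:
    """The retained caption tokens, ordered by descending frequency."""

    tokens: list[str]
    frequencies: dict[str, int]

    def __post_init__(self) -> None:
        self._members = set(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._members


def build_vocabulary(
    captions: Iterable[Sequence[str]] | Iterable[CaptionRecord],
    top_k: int = 10_000,
) -> CaptionVocabulary:
    """Keep the ``top_k`` most frequent tokens across all captions.

    Ties in frequency are broken lexicographically (ascending) for
    determinism. Raises if the captions contain no tokens at all.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    counts: Counter[str] = Counter()
    for cap in captions:
        tokens = cap.tokens if isinstance(cap, CaptionRecord) else cap
        counts.update(tokens)
    if not counts:
        raise EmptyInputError("no tokens in any caption")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    return CaptionVocabulary(
        tokens=[t for t, _ in ranked], frequencies={t: c for t, c in ranked}
    )


def intersect_with_table(
    vocabulary: CaptionVocabulary, table: EmbeddingTable
) -> CaptionVocabulary:
    """Drop vocabulary tokens that lack a row in the embedding table."""
    kept = [t for t in vocabulary.tokens if t in table]
    dropped = len(vocabulary) - len(kept)
    if dropped:
        logger.warning("%d vocabulary tokens missing from embedding table", dropped)
    return CaptionVocabulary(
        tokens=kept, frequencies={t: vocabulary.frequencies[t] for t in kept}
    )


def filter_caption(tokens: Sequence[str], vocabulary: CaptionVocabulary) -> list[str]:
    """Remove out-of-vocabulary tokens, preserving order.

    An all-OOV caption filters to ``[]``; callers exclude such captions
    from training batches.
    """
    return [t for t in tokens if t in vocabulary]


def embed_caption(tokens: Sequence[str], table: EmbeddingTable) -> np.ndarray:
    """Stack the embedding rows of ``tokens`` into an n x d sequence."""
    if not tokens:
        return np.zeros((0, table.dim))
    try:
        idx = [table.index(t) for t in tokens]
    except VocabularyError:
        raise
    return table.matrix[idx]


def write_vocabulary(vocabulary: CaptionVocabulary, path: str | Path) -> None:
    """Serialize as TSV (token, frequency) in retained order."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for t in vocabulary.tokens:
            fh.write(f"{t}\t{vocabulary.frequencies[t]}\n")
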