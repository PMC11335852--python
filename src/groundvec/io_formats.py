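"""Readers and writers for the package's external text formats.

Five kinds of inputs flow through the grounding pipeline:

* **embedding tables** — whitespace-delimited text, one word plus *d*
  decimals per line (the GloVe dialect); an optional word2vec-style
  ``"V d"`` count header is auto-detected,
* **caption datasets** — a JSON list of ``{"image_id", "caption"}``
  records paired with a TSV matrix of precomputed image feature vectors
  keyed by image id,
* **word-pair benchmarks** — TSV ``word1 word2 score`` triples with an
  optional header,
* **concreteness ratings** — TSV ``word score`` pairs.

All downstream modules consume only the container types defined here;
image vectors are treated as opaque numeric features of whatever
dimension the upstream extractor produced.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, MissingReferenceError, VocabularyError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# container types
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingTable:
    """An ordered vocabulary together with its V x d coordinate matrix."""

    words: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise FormatError("embedding matrix must be two-dimensional")
        if len(self.words) != self.matrix.shape[0]:
            raise FormatError(
                f"{len(self.words)} words but {self.matrix.shape[0]} matrix rows"
            )
        if len(set(self.words)) != len(self.words):
            raise FormatError("duplicate words in embedding table")
        if self.matrix.size and not np.all(np.isfinite(self.matrix)):
            raise FormatError("non-finite entries in embedding matrix")
        self._index: dict[str, int] = {w: i for i, w in enumerate(self.words)}

    @property
    def dim(self) -> int:
        return int(self.matrix.shape[1])

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def index(self, word: str) -> int:
        try:
            return self._index[word]
        except KeyError:
            raise VocabularyError(f"word not in embedding table: {word!r}") from None

    def lookup(self, word: str) -> np.ndarray:
        return self.matrix[self.index(word)]


@dataclass
class CaptionRecord:
    """One caption: an opaque image identifier plus normalized tokens."""

    image_id: str
    tokens: list[str]


@dataclass
class ImageVectorStore:
    """Mapping image_id -> feature vector; all vectors share one dimension."""

    vectors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        dims = {v.shape[-1] for v in self.vectors.values()}
        if len(dims) > 1:
            raise FormatError(f"inconsistent image-vector dimensions: {sorted(dims)}")
        for k, v in self.vectors.items():
            if not np.all(np.isfinite(v)):
                raise FormatError(f"non-finite image vector for id {k!r}")

    @property
    def dim(self) -> int:
        if not self.vectors:
            raise EmptyInputError("empty image-vector store has no dimension")
        return int(next(iter(self.vectors.values())).shape[-1])

    def __contains__(self, image_id: str) -> bool:
        return image_id in self.vectors

    def __getitem__(self, image_id: str) -> np.ndarray:
        try:
            return self.vectors[image_id]
        except KeyError:
            raise MissingReferenceError(f"unknown image id: {image_id!r}") from None


@dataclass
class CaptionImageDataset:
    """Paired (caption, image vector) training records.

    An image with *k* captions contributes *k* records sharing one vector.
    """

    records: list[tuple[CaptionRecord, np.ndarray]]
    split: str = "train"

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class WordPairBenchmark:
    """Human similarity/relatedness judgements over word pairs."""

    name: str
    pairs: list[tuple[str, str, float]]
    normalized: bool = False
    #: provenance tag per pair (source benchmark name), filled on combination
    sources: list[str] = field(default_factory=list)
    #: optional per-pair metadata (extra TSV columns, e.g. SimLex POS/quartiles)
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.sources:
            self.sources = [self.name] * len(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, _, s in self.pairs], dtype=np.float64)

    @property
    def score_min(self) -> float:
        if not self.pairs:
            raise EmptyInputError(f"benchmark {self.name!r} has no pairs")
        return float(self.scores.min())

    @property
    def score_max(self) -> float:
        if not self.pairs:
            raise EmptyInputError(f"benchmark {self.name!r} has no pairs")
        return float(self.scores.max())


@dataclass
class ConcretenessRatings:
    """Word -> concreteness rating (rating-scale units, e.g. 1-5)."""

    ratings: dict[str, float]

    def __len__(self) -> int:
        return len(self.ratings)

    def __contains__(self, word: str) -> bool:
        return word in self.ratings

    def __getitem__(self, word: str) -> float:
        return self.ratings[word]


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------

def read_embeddings(path: str | Path, has_header: bool | None = None) -> EmbeddingTable:
    """Read a whitespace-delimited embedding table.

    ``has_header=None`` auto-detects a word2vec-style count header (a first
    line consisting of exactly two integers). Duplicate words keep their
    first occurrence; a warning is logged.
    """
    path = Path(path)
    words: list[str] = []
    rows: list[np.ndarray] = []
    seen: set[str] = set()
    dim: int | None = None
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    start = 0
    if lines and has_header is None:
        parts = lines[0].split()
        has_header = len(parts) == 2 and all(_is_int(p) for p in parts)
    if has_header and lines:
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split()
        word, values = parts[0], parts[1:]
        try:
            vec = np.array([float(v) for v in values], dtype=np.float64)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric value ({exc})") from None
        if dim is None:
            dim = vec.shape[0]
            if dim == 0:
                raise FormatError(f"{path}:{lineno}: no embedding values on line")
        elif vec.shape[0] != dim:
            raise FormatError(
                f"{path}:{lineno}: expected {dim} values, found {vec.shape[0]}"
            )
        if word in seen:
            logger.warning("duplicate word %r at %s:%d; keeping first", word, path, lineno)
            continue
        seen.add(word)
        words.append(word)
        rows.append(vec)
    if not words:
        raise EmptyInputError(f"no embedding rows in {path}")
    return EmbeddingTable(words=words, matrix=np.vstack(rows))


def write_embeddings(table: EmbeddingTable, path: str | Path) -> None:
    """Write a table in the headerless GloVe dialect, 8 significant digits."""
    path = Path(path)
    if len(table) == 0:
        logger.warning("writing empty embedding table to %s", path)
    with path.open("w", encoding="utf-8") as fh:
        for word, row in zip(table.words, table.matrix):
            fh.write(word + " " + " ".join(f"{v:.8g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# captions + image vectors
# ---------------------------------------------------------------------------

def read_image_vectors(path: str | Path) -> ImageVectorStore:
    """Read a TSV of ``image_id \\t v1 \\t ... \\t vD`` rows."""
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: image-vector rows need an id and >=1 value")
    ids = df.iloc[:, 0].astype(str).tolist()
    mat = df.iloc[:, 1:].to_numpy(dtype=np.float64)
    return ImageVectorStore(vectors={i: mat[k] for k, i in enumerate(ids)})


def read_caption_dataset(
    captions_path: str | Path,
    vectors_path: str | Path,
    split: str = "train",
) -> CaptionImageDataset:
    """Pair caption records with their image vectors.

    Captions are a JSON list of ``{"image_id": ..., "caption": ...}`` objects
    (the COCO ``annotations`` subset). Every caption is normalized with
    :func:`groundvec.preprocessing.normalize_caption`. A caption whose
    image_id is missing from the vector store is a hard error naming the
    offending ids.
    """
    from .preprocessing import normalize_caption

    with Path(captions_path).open("r", encoding="utf-8") as fh:
        raw = json.load(fh)
    if isinstance(raw, Mapping) and "annotations" in raw:
        raw = raw["annotations"]
    store = read_image_vectors(vectors_path)
    missing = sorted({str(r["image_id"]) for r in raw if str(r["image_id"]) not in store})
    if missing:
        raise MissingReferenceError(
            f"caption image ids missing from vector store: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    records = [
        (CaptionRecord(str(r["image_id"]), normalize_caption(r["caption"])),
         store[str(r["image_id"])])
        for r in raw
    ]
    if not records:
        logger.warning("caption dataset %s is empty", captions_path)
    return CaptionImageDataset(records=records, split=split)


# ---------------------------------------------------------------------------
# benchmarks + ratings
# ---------------------------------------------------------------------------

def read_benchmark(path: str | Path, name: str | None = None) -> WordPairBenchmark:
    """Read a TSV benchmark of (word1, word2, score) rows.

    A header row is auto-detected by a non-numeric third column. Extra
    columns beyond the third are preserved as per-pair metadata (this is how
    SimLex-style POS / concreteness-quartile annotations travel).
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if not lines:
        raise EmptyInputError(f"no benchmark rows in {path}")
    first = lines[0].split("\t")
    header: list[str] | None = None
    if len(first) >= 3 and not _is_float(first[2]):
        header = first
        lines = lines[1:]
    pairs: list[tuple[str, str, float]] = []
    extra_rows: list[list[str]] = []
    for lineno, line in enumerate(lines, start=2 if header else 1):
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated columns")
        if not _is_float(parts[2]):
            raise FormatError(f"{path}:{lineno}: non-numeric score {parts[2]!r}")
        pairs.append((parts[0], parts[1], float(parts[2])))
        extra_rows.append(parts[3:])
    metadata = None
    if any(extra_rows) and header and len(header) > 3:
        metadata = pd.DataFrame(extra_rows, columns=header[3:])
    elif any(extra_rows):
        width = max(len(r) for r in extra_rows)
        metadata = pd.DataFrame(
            [r + [""] * (width - len(r)) for r in extra_rows],
            columns=[f"col{i}" for i in range(width)],
        )
    return WordPairBenchmark(name=name or path.stem, pairs=pairs, metadata=metadata)


def write_benchmark(benchmark: WordPairBenchmark, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for w1, w2, s in benchmark.pairs:
            fh.write(f"{w1}\t{w2}\t{s:.8g}\n")


def read_concreteness(path: str | Path) -> ConcretenessRatings:
    """Read TSV (word, rating) pairs; duplicate words keep the last value."""
    path = Path(path)
    ratings: dict[str, float] = {}
    with path.open("r", encoding="utf-8") as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    for lineno, line in enumerate(lines, start=1):
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected word<TAB>score")
        if lineno == 1 and not _is_float(parts[1]):
            continue  # header
        if not _is_float(parts[1]):
            raise FormatError(f"{path}:{lineno}: non-numeric score {parts[1]!r}")
        if parts[0] in ratings:
            logger.warning("duplicate rating for %r at %s:%d; keeping last", parts[0], path, lineno)
        ratings[parts[0]] = float(parts[1])
    if not ratings:
        logger.warning("concreteness file %s is empty", path)
    return ConcretenessRatings(ratings=ratings)


def write_concreteness(ratings: ConcretenessRatings, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for word, score in ratings.ratings.items():
            fh.write(f"{word}\t{score:.8g}\n")


def write_image_vectors(store: ImageVectorStore, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for image_id, vec in store.vectors.items():
            fh.write(image_id + "\t" + "\t".join(f"{v:.8g}" for v in vec) + "\n")


def write_captions(records: Iterable[CaptionRecord], path: str | Path) -> None:
    payload = [{"image_id": r.image_id, "caption": " ".join(r.tokens)} for r in records]
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
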