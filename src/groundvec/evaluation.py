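"""Intrinsic evaluation of embeddings on human word-pair judgements.

Embeddings are scored by ranking word pairs with cosine similarity and
correlating the ranking with human scores via Spearman's rho (reported
as rho x 100, the conventional scale). Benchmarks with different rating
scales are min-max normalized to [0, 1] before being pooled. The pooled
set can be intersected with a word-concreteness norm — each pair's
concreteness is the mean of its two words' ratings — standardized, and
partitioned into four sigma-bins (highly abstract, abstract, concrete,
highly concrete) to ask where grounding helps most. Also here: SimLex-
style per-category breakdowns, nearest-neighbor listings, and a paired
t-test comparing two embedding tables' per-pair errors.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import (CoverageError, DegenerateInputError, EmptyInputError,
                     ShapeError, VocabularyError)
from .io_formats import ConcretenessRatings, EmbeddingTable, WordPairBenchmark

logger = logging.getLogger(__name__)

BIN_NAMES = ("highly_abstract", "abstract", "concrete", "highly_concrete")


@dataclass
class EvaluationReport:
    benchmark: str
    rho_x100: float
    n_pairs_scored: int
    n_pairs_skipped: int


@dataclass
class WCRPair:
    """A benchmark pair joined with pair-level concreteness."""

    word1: str
    word2: str
    x_in: float              # normalized human score in [0, 1]
    concreteness: float      # mean of the two words' ratings
    x_is: float | None = None  # standardized concreteness
    bin: str | None = None


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ShapeError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateInputError("cosine similarity undefined for zero vector")
    return float(u @ v / (nu * nv))


def spearman_rho(a: Sequence[float], b: Sequence[float]) -> float:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ShapeError("spearman_rho needs two equal-length 1-d sequences")
    if a.size < 2:
        raise CoverageError("need at least 2 observations for a correlation")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError("correlation undefined for constant input")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def standardize(values: Sequence[float], ddof: int = 0) -> np.ndarray:
    """Center and scale to unit (population, by default) standard deviation."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise CoverageError("need at least 2 values to standardize")
    sd = values.std(ddof=ddof)
    if sd == 0:
        raise DegenerateInputError("standardize undefined for zero spread")
    return (values - values.mean()) / sd


# ---------------------------------------------------------------------------
# benchmark scoring
# ---------------------------------------------------------------------------

def evaluate_benchmark(table: EmbeddingTable,
                       benchmark: WordPairBenchmark) -> EvaluationReport:
    """Cosine-score every pair covered by the table; Spearman against
    human scores, reported as rho x 100. Pairs with an out-of-vocabulary
    word are skipped and counted, not zero-filled."""
    if len(benchmark) == 0:
        raise EmptyInputError(f"benchmark {benchmark.name!r} is empty")
    preds: list[float] = []
    human: list[float] = []
    skipped = 0
    for w1, w2, score in benchmark.pairs:
        if w1 in table and w2 in table:
            preds.append(cosine_similarity(table.lookup(w1), table.lookup(w2)))
            human.append(score)
        else:
            skipped += 1
    if len(preds) < 2:
        raise CoverageError(
            f"benchmark {benchmark.name!r}: only {len(preds)} scorable pairs")
    rho = spearman_rho(preds, human)
    return EvaluationReport(benchmark=benchmark.name, rho_x100=100.0 * rho,
                            n_pairs_scored=len(preds), n_pairs_skipped=skipped)


def minmax_normalize(benchmark: WordPairBenchmark) -> WordPairBenchmark:
    """Rescale scores to [0, 1]: x_in = (x - min) / (max - min)."""
    lo, hi = benchmark.score_min, benchmark.score_max
    if hi == lo:
        raise DegenerateInputError(
            f"benchmark {benchmark.name!r} has constant scores")
    pairs = [(w1, w2, (s - lo) / (hi - lo)) for w1, w2, s in benchmark.pairs]
    return WordPairBenchmark(name=benchmark.name, pairs=pairs, normalized=True,
                             sources=list(benchmark.sources),
                             metadata=benchmark.metadata)


def combine_benchmarks(benchmarks: Sequence[WordPairBenchmark],
                       name: str = "combined") -> WordPairBenchmark:
    """Concatenate normalized benchmarks, keeping per-pair provenance.

    Pairs appearing in several sources are retained as distinct records.
    """
    if not benchmarks:
        raise EmptyInputError("no benchmarks to combine")
    for b in benchmarks:
        if not b.normalized:
            raise ValueError(f"benchmark {b.name!r} must be normalized first")
    pairs: list[tuple[str, str, float]] = []
    sources: list[str] = []
    for b in benchmarks:
        pairs.extend(b.pairs)
        sources.extend(b.sources)
    return WordPairBenchmark(name=name, pairs=pairs, normalized=True,
                             sources=sources)


# ---------------------------------------------------------------------------
# concreteness stratification (WCR)
# ---------------------------------------------------------------------------

def merge_concreteness(benchmark: WordPairBenchmark,
                       ratings: ConcretenessRatings) -> list[WCRPair]:
    """Keep pairs with BOTH words rated; pair concreteness is the mean of
    the two word ratings."""
    if len(ratings) == 0:
        raise EmptyInputError("concreteness ratings are empty")
    out: list[WCRPair] = []
    for w1, w2, score in benchmark.pairs:
        if w1 in ratings and w2 in ratings:
            out.append(WCRPair(word1=w1, word2=w2, x_in=score,
                               concreteness=(ratings[w1] + ratings[w2]) / 2.0))
    if not out:
        logger.warning("no benchmark pair has both words rated")
    return out


def bin_by_sigma(pairs: Sequence[WCRPair]) -> list[WCRPair]:
    """Standardize pair concreteness and assign each pair to one of four
    disjoint, exhaustive sigma-bins.

    Boundaries on the standardized scale (mean 0, sd 1):
    ``x <= -1`` highly abstract, ``-1 < x <= 0`` abstract,
    ``0 < x < 1`` concrete, ``x >= 1`` highly concrete. The extreme bins
    are inclusive of +/- sigma.
    """
    if not pairs:
        return []
    z = standardize([p.concreteness for p in pairs])
    out: list[WCRPair] = []
    for p, x in zip(pairs, z):
        if x <= -1.0:
            b = "highly_abstract"
        elif x <= 0.0:
            b = "abstract"
        elif x < 1.0:
            b = "concrete"
        else:
            b = "highly_concrete"
        out.append(WCRPair(p.word1, p.word2, p.x_in, p.concreteness,
                           x_is=float(x), bin=b))
    return out


def evaluate_wcr_bins(table: EmbeddingTable,
                      binned: Sequence[WCRPair]) -> dict[str, EvaluationReport]:
    """Per-bin benchmark evaluation of the sigma-binned WCR pairs."""
    reports: dict[str, EvaluationReport] = {}
    for name in BIN_NAMES:
        subset = [p for p in binned if p.bin == name]
        bench = WordPairBenchmark(
            name=name, pairs=[(p.word1, p.word2, p.x_in) for p in subset],
            normalized=True)
        try:
            reports[name] = evaluate_benchmark(table, bench)
        except (CoverageError, EmptyInputError, DegenerateInputError):
            reports[name] = EvaluationReport(name, float("nan"), 0, len(subset))
    return reports


# ---------------------------------------------------------------------------
# breakdowns / neighbors / significance
# ---------------------------------------------------------------------------

def simlex_breakdown(table: EmbeddingTable, benchmark: WordPairBenchmark,
                     category_map: Mapping[str, Sequence[int]],
                     ) -> dict[str, EvaluationReport | None]:
    """Evaluate per category; ``category_map`` maps a category name to
    the benchmark pair indices it contains (a pair may appear in any
    number of categories). Categories too small to correlate are
    reported as ``None`` rather than raising."""
    out: dict[str, EvaluationReport | None] = {}
    for cat, indices in category_map.items():
        sub = WordPairBenchmark(
            name=f"{benchmark.name}:{cat}",
            pairs=[benchmark.pairs[i] for i in indices],
            normalized=benchmark.normalized)
        try:
            out[cat] = evaluate_benchmark(table, sub)
        except (CoverageError, EmptyInputError, DegenerateInputError):
            out[cat] = None
    return out


def categories_from_metadata(benchmark: WordPairBenchmark,
                             pos_column: str | None = "POS",
                             quartile_column: str | None = "conc_q",
                             hard_column: str | None = "hard",
                             ) -> dict[str, list[int]]:
    """Build a category map from SimLex-style metadata columns.

    Produces "All", per-POS categories (Adjs/Nouns/Verbs for A/N/V),
    concreteness quartiles Conc-q1..q4, and "Hard" when the columns are
    present in ``benchmark.metadata``.
    """
    n = len(benchmark)
    cats: dict[str, list[int]] = {"All": list(range(n))}
    md = benchmark.metadata
    if md is None:
        return cats
    pos_names = {"A": "Adjs", "N": "Nouns", "V": "Verbs"}
    if pos_column in md.columns:
        for code, label in pos_names.items():
            idx = [i for i in range(n) if md[pos_column].iloc[i] == code]
            if idx:
                cats[label] = idx
    if quartile_column in md.columns:
        for q in ("1", "2", "3", "4"):
            idx = [i for i in range(n) if str(md[quartile_column].iloc[i]) == q]
            if idx:
                cats[f"Conc-q{q}"] = idx
    if hard_column in md.columns:
        idx = [i for i in range(n) if str(md[hard_column].iloc[i]) in ("1", "True", "yes")]
        if idx:
            cats["Hard"] = idx
    return cats


def nearest_neighbors(table: EmbeddingTable, query: str, k: int = 10) -> list[str]:
    """The k words with highest cosine to ``query`` (query excluded);
    exact ties are broken lexicographically."""
    if query not in table:
        raise VocabularyError(f"query word not in table: {query!r}")
    if k >= len(table):
        raise ValueError("k must be smaller than the vocabulary size")
    q = table.lookup(query)
    norms = np.linalg.norm(table.matrix, axis=1)
    qn = np.linalg.norm(q)
    if qn == 0:
        raise DegenerateInputError("query has a zero vector")
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = table.matrix @ q / (norms * qn)
    sims = np.where(norms == 0, -np.inf, sims)
    order = sorted(
        (i for i in range(len(table)) if table.words[i] != query),
        key=lambda i: (-sims[i], table.words[i]))
    return [table.words[i] for i in order[:k]]


def paired_model_test(table_a: EmbeddingTable, table_b: EmbeddingTable,
                      benchmark: WordPairBenchmark,
                      operand: str = "abs_error") -> tuple[float, float]:
    """Paired two-sided t-test between two embedding tables' per-pair
    errors against the (normalized) human scores.

    ``operand`` selects the per-pair quantity: ``abs_error`` (default)
    uses |cosine - x_in|, ``sq_error`` the squared error. Only pairs
    scorable by both tables enter the test. Two identical error vectors
    yield (t=0, p=1) by convention.
    """
    if operand not in ("abs_error", "sq_error"):
        raise ValueError("operand must be 'abs_error' or 'sq_error'")
    errs_a: list[float] = []
    errs_b: list[float] = []
    for w1, w2, score in benchmark.pairs:
        if all(w in t for t in (table_a, table_b) for w in (w1, w2)):
            ca = cosine_similarity(table_a.lookup(w1), table_a.lookup(w2))
            cb = cosine_similarity(table_b.lookup(w1), table_b.lookup(w2))
            if operand == "abs_error":
                errs_a.append(abs(ca - score))
                errs_b.append(abs(cb - score))
            else:
                errs_a.append((ca - score) ** 2)
                errs_b.append((cb - score) ** 2)
    if len(errs_a) < 2:
        raise CoverageError("need >= 2 pairs scorable by both tables")
    diffs = np.asarray(errs_a) - np.asarray(errs_b)
    if np.allclose(diffs, 0.0):
        return 0.0, 1.0
    res = stats.ttest_rel(errs_a, errs_b)
    return float(res.statistic), float(res.pvalue)


def mean_rho(reports: Sequence[EvaluationReport]) -> float:
    """Unweighted arithmetic mean of per-benchmark rho x 100."""
    if not reports:
        raise EmptyInputError("no reports to average")
    return float(np.mean([r.rho_x100 for r in reports]))
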