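"""Benchmark scoring, normalization, concreteness binning, significance."""
import numpy as np
import pytest
from scipy.stats import norm

from groundvec import (EmbeddingTable, bin_by_sigma, combine_benchmarks,
                       cosine_similarity, evaluate_benchmark,
                       evaluate_wcr_bins, make_benchmark, make_world,
                       mean_rho, merge_concreteness, minmax_normalize,
                       nearest_neighbors, paired_model_test, simlex_breakdown,
                       spearman_rho, standardize)
from groundvec.errors import (CoverageError, DegenerateInputError,
                              VocabularyError)
from groundvec.evaluation import WCRPair, categories_from_metadata
from groundvec.io_formats import ConcretenessRatings, WordPairBenchmark
import pandas as pd


def rank_oracle(values):
    """Average ranks computed by hand (independent of scipy)."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_oracle(a, b):
    ra, rb = rank_oracle(a), rank_oracle(b)
    ra, rb = ra - ra.mean(), rb - rb.mean()
    return float(ra @ rb / np.sqrt((ra @ ra) * (rb @ rb)))


class TestCosine:
    def test_identical_vectors(self, rng):
        v = rng.standard_normal(5)
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_formula_example(self):
        assert cosine_similarity([1, 1], [1, 0]) == pytest.approx(0.70710678)

    def test_zero_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            cosine_similarity([0, 0], [1, 0])

    def test_scale_invariance(self, rng):
        u, v = rng.standard_normal(6), rng.standard_normal(6)
        assert cosine_similarity(3.7 * u, v) == pytest.approx(
            cosine_similarity(u, v))


class TestSpearman:
    def test_monotone_and_reversed(self):
        a = [1.0, 2.0, 5.0, 9.0]
        assert spearman_rho(a, [2.0, 4.0, 9.0, 10.0]) == pytest.approx(1.0)
        assert spearman_rho(a, [10.0, 9.0, 4.0, 2.0]) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert spearman_rho([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_ties_match_hand_rank_oracle(self, rng):
        a = rng.integers(0, 5, size=40).astype(float)
        b = rng.integers(0, 5, size=40).astype(float) + 0.3 * a
        assert spearman_rho(a, b) == pytest.approx(spearman_oracle(a, b),
                                                   abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        a = rng.standard_normal(30)
        b = rng.standard_normal(30)
        assert spearman_rho(np.exp(a), b) == pytest.approx(spearman_rho(a, b))

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(CoverageError):
            spearman_rho([1.0], [2.0])


class TestEvaluateBenchmark:
    def test_planted_world_scores_100_at_zero_noise(self):
        world = make_world(V=50, d=6, c=4, seed=3)
        bench = make_benchmark(world, n_pairs=100, noise_sd=0.0)
        report = evaluate_benchmark(world.grounded_table, bench)
        assert report.rho_x100 == pytest.approx(100.0)
        assert report.n_pairs_scored == 100 and report.n_pairs_skipped == 0

    def test_oov_pairs_are_skipped_and_counted(self, tiny_table):
        bench = WordPairBenchmark(name="b", pairs=[
            ("cat", "dog", 1.0), ("cat", "fish", 2.0), ("dog", "fish", 0.5),
            ("cat", "quokka", 3.0)])
        report = evaluate_benchmark(tiny_table, bench)
        assert report.n_pairs_scored == 3
        assert report.n_pairs_skipped == 1

    def test_insufficient_coverage_rejected(self, tiny_table):
        bench = WordPairBenchmark(name="b", pairs=[("cat", "quokka", 1.0),
                                                   ("cat", "dog", 2.0)])
        with pytest.raises(CoverageError):
            evaluate_benchmark(tiny_table, bench)

    def test_per_vector_rescaling_invariance(self, rng):
        world = make_world(V=30, d=5, c=5, seed=4)
        bench = make_benchmark(world, n_pairs=60, noise_sd=0.1)
        scales = rng.uniform(0.5, 3.0, size=30)[:, None]
        rescaled = EmbeddingTable(words=list(world.table.words),
                                  matrix=world.table.matrix * scales)
        r1 = evaluate_benchmark(world.table, bench).rho_x100
        r2 = evaluate_benchmark(rescaled, bench).rho_x100
        assert r1 == pytest.approx(r2)


class TestMinMaxNormalize:
    def test_examples(self):
        b = WordPairBenchmark("b", [("a", "b", 0.0), ("c", "d", 5.0),
                                    ("e", "f", 10.0)])
        out = minmax_normalize(b)
        assert [s for *_, s in out.pairs] == [0.0, 0.5, 1.0]
        assert out.normalized

    def test_identity_on_unit_range(self):
        b = WordPairBenchmark("b", [("a", "b", 0.0), ("c", "d", 0.25),
                                    ("e", "f", 1.0)])
        assert [s for *_, s in minmax_normalize(b).pairs] == [0.0, 0.25, 1.0]

    def test_rank_invariance_of_evaluation(self):
        world = make_world(V=40, d=5, c=3, seed=5)
        bench = make_benchmark(world, n_pairs=80, noise_sd=0.1)
        raw = evaluate_benchmark(world.table, bench).rho_x100
        normed = evaluate_benchmark(world.table, minmax_normalize(bench)).rho_x100
        assert raw == pytest.approx(normed)

    def test_constant_scores_rejected(self):
        b = WordPairBenchmark("b", [("a", "b", 2.0), ("c", "d", 2.0)])
        with pytest.raises(DegenerateInputError):
            minmax_normalize(b)


class TestCombine:
    def _norm(self, name, pairs):
        return minmax_normalize(WordPairBenchmark(name, pairs))

    def test_cardinality_and_provenance(self):
        b1 = self._norm("men", [("a", "b", 0.0), ("c", "d", 1.0),
                                ("e", "f", 2.0)])
        b2 = self._norm("ws", [("g", "h", 1.0), ("i", "j", 2.0),
                               ("a", "b", 3.0), ("k", "l", 4.0)])
        combo = combine_benchmarks([b1, b2])
        assert len(combo) == 7
        assert combo.sources.count("men") == 3
        assert combo.sources.count("ws") == 4
        # duplicate (a, b) across sources kept as distinct records
        assert sum(1 for w1, w2, _ in combo.pairs if (w1, w2) == ("a", "b")) == 2

    def test_unnormalized_input_rejected(self):
        raw = WordPairBenchmark("raw", [("a", "b", 0.0), ("c", "d", 9.0)])
        with pytest.raises(ValueError):
            combine_benchmarks([raw])

    def test_empty_list_rejected(self):
        from groundvec.errors import EmptyInputError
        with pytest.raises(EmptyInputError):
            combine_benchmarks([])


class TestMergeConcreteness:
    def test_pair_score_is_mean(self):
        bench = WordPairBenchmark("b", [("a", "b", 0.5)], normalized=True)
        ratings = ConcretenessRatings({"a": 2.0, "b": 4.0})
        pairs = merge_concreteness(bench, ratings)
        assert pairs[0].concreteness == pytest.approx(3.0)

    def test_intersection_drops_unrated(self):
        bench = WordPairBenchmark("b", [("a", "b", 0.5), ("a", "x", 0.2)],
                                  normalized=True)
        ratings = ConcretenessRatings({"a": 2.0, "b": 4.0})
        assert len(merge_concreteness(bench, ratings)) == 1

    def test_survivor_count_oracle(self, rng):
        words = [f"w{i}" for i in range(50)]
        rated = set(rng.choice(words, size=25, replace=False))
        ratings = ConcretenessRatings({w: 1.0 + i for i, w in enumerate(rated)})
        pairs = [(words[int(i)], words[int(j)], 0.5)
                 for i, j in rng.integers(0, 50, size=(200, 2)) if i != j]
        bench = WordPairBenchmark("b", pairs, normalized=True)
        expect = sum(1 for w1, w2, _ in pairs if w1 in rated and w2 in rated)
        assert len(merge_concreteness(bench, ratings)) == expect


class TestStandardize:
    def test_two_point_example(self):
        assert np.allclose(standardize([0.0, 2.0]), [-1.0, 1.0])

    def test_idempotent(self, rng):
        x = rng.standard_normal(100)
        once = standardize(x)
        assert np.allclose(standardize(once), once, atol=1e-12)

    def test_moments(self, rng):
        z = standardize(rng.standard_normal(10_000) * 3 + 7)
        assert abs(z.mean()) < 1e-10
        assert abs(z.std() - 1.0) < 1e-10

    def test_zero_spread_rejected(self):
        with pytest.raises(DegenerateInputError):
            standardize([2.0, 2.0, 2.0])


class TestBinBySigma:
    def _pairs(self, values):
        return [WCRPair(f"a{i}", f"b{i}", 0.5, float(v))
                for i, v in enumerate(values)]

    def test_boundary_inclusivity(self):
        # concreteness values chosen so standardized scores hit the
        # boundaries exactly: mean 0, sd 1 on input {-1, 0, 1} x many
        vals = [-1.0, 0.0, 1.0] * 10
        binned = bin_by_sigma(self._pairs(vals))
        z = {p.concreteness: p.bin for p in binned}
        sd = np.std(vals)
        assert binned[0].x_is == pytest.approx(-1.0 / sd)
        # exact -1 lands in highly_abstract (inclusive boundary)
        exact = bin_by_sigma(self._pairs([-2.0, 0.0, 0.0, 2.0] * 5))
        lookup = {(p.concreteness, p.bin) for p in exact}
        assert (-2.0, "highly_abstract") in lookup
        assert (2.0, "highly_concrete") in lookup
        assert (0.0, "abstract") in lookup  # x=0 belongs to the left-middle bin

    def test_partition_disjoint_exhaustive(self, rng):
        binned = bin_by_sigma(self._pairs(rng.standard_normal(500)))
        assert all(p.bin is not None for p in binned)
        counts = {b: sum(p.bin == b for p in binned)
                  for b in ("highly_abstract", "abstract", "concrete",
                            "highly_concrete")}
        assert sum(counts.values()) == 500

    def test_gaussian_bin_fractions(self, rng):
        n = 100_000
        binned = bin_by_sigma(self._pairs(rng.standard_normal(n)))
        frac = {b: sum(p.bin == b for p in binned) / n
                for b in ("highly_abstract", "abstract", "concrete",
                          "highly_concrete")}
        expect = {"highly_abstract": norm.cdf(-1),
                  "abstract": norm.cdf(0) - norm.cdf(-1),
                  "concrete": norm.cdf(1) - norm.cdf(0),
                  "highly_concrete": 1 - norm.cdf(1)}
        for b in frac:
            assert abs(frac[b] - expect[b]) < 0.01

    def test_wcr_bin_reports_partition_scorable_pairs(self):
        world = make_world(V=80, d=6, c=4, seed=6)
        bench = minmax_normalize(make_benchmark(world, n_pairs=200,
                                                noise_sd=0.1))
        ratings = ConcretenessRatings(
            {w: float(i % 7) for i, w in enumerate(world.table.words)})
        binned = bin_by_sigma(merge_concreteness(bench, ratings))
        reports = evaluate_wcr_bins(world.table, binned)
        assert sum(r.n_pairs_scored for r in reports.values()) == len(binned)


class TestSimlexBreakdown:
    def test_all_category_matches_full_evaluation(self):
        world = make_world(V=40, d=5, c=3, seed=7)
        bench = make_benchmark(world, n_pairs=60, noise_sd=0.1)
        reports = simlex_breakdown(world.table, bench,
                                   {"All": list(range(len(bench)))})
        full = evaluate_benchmark(world.table, bench)
        assert reports["All"].rho_x100 == pytest.approx(full.rho_x100)

    def test_subset_oracle_and_sizes(self, rng):
        world = make_world(V=40, d=5, c=3, seed=8)
        bench = make_benchmark(world, n_pairs=60, noise_sd=0.1)
        idx = rng.permutation(60)
        cats = {"one": sorted(idx[:30].tolist()),
                "two": sorted(idx[30:].tolist())}
        reports = simlex_breakdown(world.table, bench, cats)
        for cat, indices in cats.items():
            sub = WordPairBenchmark("s", [bench.pairs[i] for i in indices])
            assert reports[cat].rho_x100 == pytest.approx(
                evaluate_benchmark(world.table, sub).rho_x100)
        assert len(cats["one"]) + len(cats["two"]) == 60

    def test_tiny_category_reported_as_none(self, tiny_table):
        bench = WordPairBenchmark("b", [("cat", "dog", 1.0),
                                        ("cat", "fish", 2.0)])
        reports = simlex_breakdown(tiny_table, bench, {"solo": [0]})
        assert reports["solo"] is None

    def test_categories_from_metadata(self):
        bench = WordPairBenchmark(
            "sl", [("a", "b", 1.0), ("c", "d", 2.0), ("e", "f", 3.0)],
            metadata=pd.DataFrame({"POS": ["N", "V", "N"],
                                   "conc_q": ["1", "4", "1"],
                                   "hard": ["1", "0", "0"]}))
        cats = categories_from_metadata(bench)
        assert cats["Nouns"] == [0, 2]
        assert cats["Verbs"] == [1]
        assert cats["Conc-q1"] == [0, 2]
        assert cats["Hard"] == [0]
        assert cats["All"] == [0, 1, 2]


class TestNearestNeighbors:
    def test_duplicate_vector_ranks_first(self):
        table = EmbeddingTable(words=["q", "twin", "far"],
                               matrix=[[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        assert nearest_neighbors(table, "q", 2) == ["twin", "far"]

    def test_k_equals_v_minus_one_returns_all(self, tiny_table):
        out = nearest_neighbors(tiny_table, "cat", 2)
        assert set(out) == {"dog", "fish"}

    def test_brute_force_oracle(self, rng):
        words = [f"w{i:03d}" for i in range(200)]
        table = EmbeddingTable(words=words,
                               matrix=rng.standard_normal((200, 8)))
        got = nearest_neighbors(table, "w000", 10)
        q = table.lookup("w000")
        sims = sorted(
            ((float(q @ table.matrix[i]
                    / (np.linalg.norm(q) * np.linalg.norm(table.matrix[i]))),
              words[i]) for i in range(1, 200)),
            key=lambda t: (-t[0], t[1]))
        assert got == [w for _, w in sims[:10]]

    def test_oov_query_rejected(self, tiny_table):
        with pytest.raises(VocabularyError):
            nearest_neighbors(tiny_table, "quokka", 1)


class TestPairedModelTest:
    def test_identical_tables_give_t0_p1(self, tiny_table):
        bench = WordPairBenchmark("b", [("cat", "dog", 0.5),
                                        ("cat", "fish", 0.7),
                                        ("dog", "fish", 0.2)], normalized=True)
        t, p = paired_model_test(tiny_table, tiny_table, bench)
        assert (t, p) == (0.0, 1.0)

    def test_swap_negates_t(self, rng):
        world = make_world(V=30, d=5, c=3, seed=9)
        bench = minmax_normalize(make_benchmark(world, n_pairs=50,
                                                noise_sd=0.2))
        other = EmbeddingTable(words=list(world.table.words),
                               matrix=world.grounded_matrix)
        t1, p1 = paired_model_test(world.table, other, bench)
        t2, p2 = paired_model_test(other, world.table, bench)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_matches_textbook_formula(self, rng):
        world = make_world(V=30, d=5, c=3, seed=10)
        bench = minmax_normalize(make_benchmark(world, n_pairs=50,
                                                noise_sd=0.2))
        other = EmbeddingTable(words=list(world.table.words),
                               matrix=world.grounded_matrix)
        t, _ = paired_model_test(world.table, other, bench)
        # recompute the paired-t statistic by hand
        errs_a, errs_b = [], []
        for w1, w2, s in bench.pairs:
            errs_a.append(abs(cosine_similarity(world.table.lookup(w1),
                                                world.table.lookup(w2)) - s))
            errs_b.append(abs(cosine_similarity(other.lookup(w1),
                                                other.lookup(w2)) - s))
        d = np.array(errs_a) - np.array(errs_b)
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert t == pytest.approx(t_hand, abs=1e-10)


def test_mean_rho_is_unweighted_average():
    from groundvec.evaluation import EvaluationReport
    reports = [EvaluationReport("a", 40.0, 10, 0),
               EvaluationReport("b", 60.0, 99, 1)]
    assert mean_rho(reports) == pytest.approx(50.0)
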