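import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqnls import (
    MiningConfig,
    SequenceRecord,
    SimulationSpec,
    TrainingCorpus,
    collect_patterns,
    count_ordered_support,
    enrichment_score,
    extract_words,
    mine_frequent_wordsets,
    permute_wordlists,
    simulate_training_corpus,
)
from seqnls.mining import WordSet, read_patterns, write_patterns

AA = "ACDEFGHIKLMNPQRSTVWY"


def corpus_from(positives, negatives=()):
    pos = [SequenceRecord(f"p{i}", s) for i, s in enumerate(positives)]
    neg = [SequenceRecord(f"n{i}", s) for i, s in enumerate(negatives)]
    return TrainingCorpus(pos, neg)


# --- independent oracle: exhaustive subset enumeration --------------------


def brute_force_wordsets(positives, min_support, max_set_size, word_length=2):
    """Enumerate every subset of observed words and count presence support."""
    transactions = [extract_words(s, word_length) for s in positives]
    vocabulary = sorted(set().union(*transactions)) if transactions else []
    frequent = {}
    for k in range(1, max_set_size + 1):
        for subset in combinations(vocabulary, k):
            support = sum(1 for t in transactions if set(subset) <= t)
            if support >= min_support:
                frequent[frozenset(subset)] = support
    return frequent


def naive_ordered_support(wordlist, sequences, max_gap=2):
    """Recursive placement search, one sequence at a time."""

    def placements(residues, words, min_start):
        if not words:
            return True
        w = words[0]
        for start in range(min_start, min(len(residues), min_start + max_gap + 1)):
            if residues[start : start + len(w)] == w:
                if placements(residues, words[1:], start + len(w)):
                    return True
        return False

    def contains(residues):
        w = wordlist[0]
        return any(
            residues[i : i + len(w)] == w
            and placements(residues, list(wordlist[1:]), i + len(w))
            for i in range(len(residues))
        )

    return sum(1 for s in sequences if contains(s.residues))


# --- extract_words ---------------------------------------------------------


class TestExtractWords:
    def test_enumeration(self):
        assert extract_words("ATKK", 2) == {"AT", "TK", "KK"}

    def test_deduplication(self):
        assert extract_words("AAAA", 2) == {"AA"}

    def test_too_short(self):
        assert extract_words("A", 2) == set()

    def test_x_words_excluded(self):
        assert extract_words("AXK", 2) == set()

    def test_word_length_one(self):
        assert extract_words("AKA", 1) == {"A", "K"}


# --- mine_frequent_wordsets ------------------------------------------------


class TestMineFrequentWordsets:
    def test_worked_example_at_kk(self):
        # 12 peptides containing both AT and KK, 8 lacking KK: {AT, KK} is
        # frequent with support 12
        positives = ["MATGKKW"] * 12 + ["MATGGGW"] * 8
        corpus = corpus_from(positives)
        sets = {ws.words: ws.support_pos for ws in mine_frequent_wordsets(corpus, 3, 4)}
        assert sets[frozenset({"AT", "KK"})] == 12

    def test_empty_positives(self):
        assert mine_frequent_wordsets(corpus_from([]), 3, 4) == []

    def test_matches_brute_force_on_random_corpus(self):
        rng = np.random.default_rng(5)
        positives = [
            "".join(rng.choice(list("ACDK"), size=10)) for _ in range(5)
        ]
        corpus = corpus_from(positives)
        mined = {ws.words: ws.support_pos for ws in mine_frequent_wordsets(corpus, 2, 3)}
        assert mined == brute_force_wordsets(positives, 2, 3)

    @given(
        st.lists(
            st.text(alphabet="ACDK", min_size=2, max_size=15),
            min_size=1,
            max_size=20,
        ),
        st.integers(1, 4),
        st.integers(1, 4),
    )
    @settings(max_examples=40, deadline=None)
    def test_oracle_equivalence(self, seqs, min_support, max_set_size):
        corpus = corpus_from(seqs)
        mined = {
            ws.words: ws.support_pos
            for ws in mine_frequent_wordsets(corpus, min_support, max_set_size)
        }
        assert mined == brute_force_wordsets(seqs, min_support, max_set_size)

    def test_anti_monotonicity(self):
        rng = np.random.default_rng(11)
        positives = ["".join(rng.choice(list("ACDKR"), size=12)) for _ in range(15)]
        mined = {
            ws.words: ws.support_pos
            for ws in mine_frequent_wordsets(corpus_from(positives), 1, 4)
        }
        for words, support in mined.items():
            for smaller in combinations(sorted(words), len(words) - 1):
                if smaller:
                    assert mined[frozenset(smaller)] >= support


# --- permute_wordlists -----------------------------------------------------


class TestPermuteWordlists:
    def test_pair(self):
        perms = permute_wordlists(WordSet(frozenset({"AT", "KK"}), 12))
        assert set(perms) == {("AT", "KK"), ("KK", "AT")}

    def test_singleton(self):
        assert permute_wordlists(WordSet(frozenset({"KK"}), 5)) == [("KK",)]

    def test_size_four_gives_24(self):
        perms = permute_wordlists({"AA", "CC", "DD", "KK"})
        assert len(perms) == 24
        assert len(set(perms)) == 24


# --- count_ordered_support -------------------------------------------------


class TestCountOrderedSupport:
    def test_order_matters(self):
        seqs = [SequenceRecord("a", "MATQKKL"), SequenceRecord("b", "MKKQATL")]
        assert count_ordered_support(("AT", "KK"), seqs, max_gap=2) == 1

    def test_empty_corpus(self):
        assert count_ordered_support(("AT", "KK"), [], max_gap=2) == 0

    def test_matches_naive_scanner(self):
        rng = np.random.default_rng(3)
        seqs = [
            SequenceRecord(f"s{i}", "".join(rng.choice(list("AKRT"), size=20)))
            for i in range(20)
        ]
        for wl in [("KK",), ("AT", "KK"), ("KR", "AT", "KK")]:
            assert count_ordered_support(wl, seqs) == naive_ordered_support(wl, seqs)

    def test_ordered_support_bounded_by_set_support(self):
        rng = np.random.default_rng(9)
        positives = ["".join(rng.choice(list("AKRT"), size=15)) for _ in range(20)]
        corpus = corpus_from(positives)
        for ws in mine_frequent_wordsets(corpus, 2, 3):
            for wl in permute_wordlists(ws):
                assert (
                    count_ordered_support(wl, corpus.positives) <= ws.support_pos
                )


# --- enrichment_score ------------------------------------------------------


class TestEnrichmentScore:
    def test_log_of_unity_is_zero(self):
        # n_p1/n_p == (n_b1+1)/(n_b+1): 10/100 vs 10/100
        assert enrichment_score(10, 100, 9, 99) == pytest.approx(0.0)

    def test_direct_arithmetic(self):
        # log2((12/108) / (101/26773)) = log2(29.4553...) = 4.8804...
        expected = math.log2((12 / 108) / (101 / 26773))
        assert enrichment_score(12, 108, 100, 26772) == pytest.approx(expected)
        assert enrichment_score(12, 108, 100, 26772) == pytest.approx(4.88, abs=0.01)

    def test_doubling_np1_adds_one(self):
        a = enrichment_score(6, 108, 50, 26772)
        b = enrichment_score(12, 108, 50, 26772)
        assert b - a == pytest.approx(1.0)

    def test_plain_ratio_formula(self):
        got = enrichment_score(12, 108, 100, 26772, formula="plain_ratio")
        assert got == pytest.approx((12 / 108) / (101 / 26773))

    @given(
        st.integers(1, 50),
        st.integers(0, 200),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotonicity(self, n_p1, n_b1):
        n_p, n_b = 100, 500
        n_p1 = min(n_p1, n_p)
        n_b1 = min(n_b1, n_b)
        base = enrichment_score(n_p1, n_p, n_b1, n_b)
        if n_p1 < n_p:
            assert enrichment_score(n_p1 + 1, n_p, n_b1, n_b) > base
        if n_b1 < n_b:
            assert enrichment_score(n_p1, n_p, n_b1 + 1, n_b) < base

    def test_zero_np1_rejected(self):
        with pytest.raises(ValueError):
            enrichment_score(0, 100, 5, 500)


# --- collect_patterns ------------------------------------------------------


class TestCollectPatterns:
    def test_all_retained_meet_threshold(self):
        spec = SimulationSpec(seed=2, n_pos=15, n_neg=100)
        corpus, _ = simulate_training_corpus(spec)
        patterns = collect_patterns(corpus, MiningConfig())
        assert patterns
        assert all(p.e_s >= 1.0 for p in patterns)
        assert all(p.n_p1 >= 1 for p in patterns)

    def test_unreachable_threshold_empty(self):
        spec = SimulationSpec(seed=2, n_pos=15, n_neg=100)
        corpus, _ = simulate_training_corpus(spec)
        assert collect_patterns(corpus, MiningConfig(es_threshold=1e6)) == []

    def test_planted_wordlists_recovered(self):
        spec = SimulationSpec(seed=4)
        corpus, truth = simulate_training_corpus(spec)
        patterns = {p.words for p in collect_patterns(corpus)}
        for planted in truth:
            assert planted in patterns

    def test_deterministic_lexicographic_order(self):
        spec = SimulationSpec(seed=2, n_pos=15, n_neg=100)
        corpus, _ = simulate_training_corpus(spec)
        patterns = collect_patterns(corpus)
        assert [p.words for p in patterns] == sorted(p.words for p in patterns)

    def test_pattern_store_round_trip(self, tmp_path):
        spec = SimulationSpec(seed=2, n_pos=15, n_neg=100)
        corpus, _ = simulate_training_corpus(spec)
        patterns = collect_patterns(corpus)
        path = tmp_path / "patterns.tsv"
        write_patterns(patterns, path)
        assert read_patterns(path) == patterns


class TestTrainingCorpus:
    def test_warns_on_off_length_negatives(self):
        with pytest.warns(UserWarning, match="length 40"):
            corpus_from(["MATKK"], ["MATKK"])

    def test_counts(self):
        corpus = corpus_from(["MATKK", "KRKRW"], ["A" * 40])
        assert corpus.n_p == 2
        assert corpus.n_b == 1
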