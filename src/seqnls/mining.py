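"""Frequent word-set mining and enrichment scoring of ordered word-lists.

A *word* is a fixed-length amino-acid substring (dipeptides by default).
Frequent word-sets are mined Apriori-style from the positive corpus using
presence semantics (a word counts once per sequence); each frequent set is
permuted into ordered word-lists, whose supports in both corpora are counted
under the gapped qualified-match rule, and word-lists enriched in the
positive corpus are collected as sequential patterns.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Iterable, Literal, Sequence

from seqnls.io import AMINO_ACIDS, SequenceRecord
from seqnls.matching import has_wordlist_match

EnrichmentFormula = Literal["log2_ratio", "plain_ratio"]


@dataclass
class MiningConfig:
    """Knobs of the pattern-mining stage."""

    word_length: int = 2
    min_support: int = 3
    max_set_size: int = 4
    max_gap: int = 2
    es_threshold: float = 1.0
    formula: EnrichmentFormula = "log2_ratio"

    def __post_init__(self) -> None:
        if self.word_length < 1:
            raise ValueError("word_length must be >= 1")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.max_set_size < 1:
            raise ValueError("max_set_size must be >= 1")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


@dataclass
class TrainingCorpus:
    """Positive NLS peptides and negative (non-NLS) length-40 peptides."""

    positives: list[SequenceRecord]
    negatives: list[SequenceRecord]

    def __post_init__(self) -> None:
        off = [s.id for s in self.negatives if len(s) != 40]
        if off:
            warnings.warn(
                f"{len(off)} negative peptides are not length 40 "
                f"(e.g. {off[:3]})",
                stacklevel=2,
            )

    @property
    def n_p(self) -> int:
        return len(self.positives)

    @property
    def n_b(self) -> int:
        return len(self.negatives)


@dataclass(frozen=True)
class WordSet:
    """An unordered frequent word-set with its positive-corpus support."""

    words: frozenset[str]
    support_pos: int


@dataclass(frozen=True)
class WordListPattern:
    """An ordered word-list with corpus supports and enrichment score."""

    words: tuple[str, ...]
    n_p1: int
    n_b1: int
    e_s: float

    def __str__(self) -> str:
        return "-".join(self.words)


def extract_words(seq: SequenceRecord | str, word_length: int = 2) -> set[str]:
    """All distinct substrings of the given length over the 20-letter alphabet.

    Substrings containing 'X' (or any non-standard letter) are skipped: such
    words can never produce a qualified match.
    """
    if word_length < 1:
        raise ValueError("word_length must be >= 1")
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    alphabet = set(AMINO_ACIDS)
    return {
        w
        for i in range(len(residues) - word_length + 1)
        if set(w := residues[i : i + word_length]) <= alphabet
    }


def mine_frequent_wordsets(
    corpus: TrainingCorpus,
    min_support: int = 3,
    max_set_size: int = 4,
    word_length: int = 2,
) -> list[WordSet]:
    """Apriori mining of word-sets frequent in the positive corpus.

    A word-set is frequent when all its words co-occur (presence) in at least
    ``min_support`` positive sequences and its size is at most
    ``max_set_size``. Anti-monotonicity prunes candidates whose sub-sets are
    infrequent.
    """
    transactions = [extract_words(s, word_length) for s in corpus.positives]
    # level 1: frequent single words
    counts: dict[str, int] = {}
    for t in transactions:
        for w in t:
            counts[w] = counts.get(w, 0) + 1
    frequent: dict[frozenset[str], int] = {
        frozenset([w]): c for w, c in counts.items() if c >= min_support
    }
    level = sorted(w for fs in frequent for w in fs)
    prev = [frozenset([w]) for w in level]
    k = 1
    while prev and k < max_set_size:
        k += 1
        # candidate generation: join frequent (k-1)-sets sharing k-2 words
        candidates: set[frozenset[str]] = set()
        for a, b in combinations(prev, 2):
            union = a | b
            if len(union) == k and all(
                frozenset(sub) in frequent
                for sub in combinations(sorted(union), k - 1)
            ):
                candidates.add(union)
        current: list[frozenset[str]] = []
        for cand in candidates:
            support = sum(1 for t in transactions if cand <= t)
            if support >= min_support:
                frequent[cand] = support
                current.append(cand)
        prev = current
    return sorted(
        (WordSet(ws, sup) for ws, sup in frequent.items()),
        key=lambda s: (len(s.words), tuple(sorted(s.words))),
    )


def permute_wordlists(wordset: WordSet | Iterable[str]) -> list[tuple[str, ...]]:
    """All orderings of a word-set's words."""
    words = wordset.words if isinstance(wordset, WordSet) else wordset
    return [tuple(p) for p in permutations(sorted(words))]


def count_ordered_support(
    wordlist: Sequence[str],
    sequences: Iterable[SequenceRecord],
    max_gap: int = 2,
) -> int:
    """Number of sequences containing a qualified (gap-bounded) ordered match."""
    if not wordlist:
        raise ValueError("empty word-list")
    return sum(
        1 for s in sequences if has_wordlist_match(s.residues, wordlist, max_gap)
    )


def enrichment_score(
    n_p1: int,
    n_p: int,
    n_b1: int,
    n_b: int,
    formula: EnrichmentFormula = "log2_ratio",
) -> float:
    """Over-representation of a word-list in positives relative to negatives.

    Default: log2 of the positive relative frequency over the negative one,
    with a +1 pseudocount on the negative side. ``plain_ratio`` returns the
    raw frequency ratio instead.
    """
    if n_p1 < 1:
        raise ValueError("n_p1 must be >= 1 (unsupported word-lists are dropped)")
    if n_p < n_p1:
        raise ValueError("n_p must be >= n_p1")
    if not 0 <= n_b1 <= n_b:
        raise ValueError("need 0 <= n_b1 <= n_b")
    ratio = (n_p1 / n_p) / ((n_b1 + 1) / (n_b + 1))
    if formula == "log2_ratio":
        return math.log2(ratio)
    if formula == "plain_ratio":
        return ratio
    raise ValueError(f"unknown enrichment formula {formula!r}")


def collect_patterns(
    corpus: TrainingCorpus, config: MiningConfig | None = None
) -> list[WordListPattern]:
    """End-to-end mining: frequent sets -> permutations -> supports -> E_S.

    Keeps word-lists with positive ordered support and enrichment at least
    ``config.es_threshold``; output sorted lexicographically by words.
    """
    config = config or MiningConfig()
    wordsets = mine_frequent_wordsets(
        corpus,
        min_support=config.min_support,
        max_set_size=config.max_set_size,
        word_length=config.word_length,
    )
    patterns: list[WordListPattern] = []
    for ws in wordsets:
        for wl in permute_wordlists(ws):
            n_p1 = count_ordered_support(wl, corpus.positives, config.max_gap)
            if n_p1 < 1:
                continue
            n_b1 = count_ordered_support(wl, corpus.negatives, config.max_gap)
            e_s = enrichment_score(
                n_p1, corpus.n_p, n_b1, corpus.n_b, config.formula
            )
            if e_s >= config.es_threshold:
                patterns.append(WordListPattern(wl, n_p1, n_b1, e_s))
    patterns.sort(key=lambda p: p.words)
    return patterns


def write_patterns(patterns: Iterable[WordListPattern], path) -> None:
    """Persist patterns as TSV: words (dash-joined), n_p1, n_b1, e_s."""
    with open(path, "w") as fh:
        fh.write("words\tn_p1\tn_b1\te_s\n")
        for p in patterns:
            fh.write(f"{'-'.join(p.words)}\t{p.n_p1}\t{p.n_b1}\t{p.e_s!r}\n")


def read_patterns(path) -> list[WordListPattern]:
    patterns: list[WordListPattern] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("words"):
                continue
            words, n_p1, n_b1, e_s = line.split("\t")
            patterns.append(
                WordListPattern(
                    tuple(words.split("-")), int(n_p1), int(n_b1), float(e_s)
                )
            )
    return patterns
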