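"""Gapped word-list scanning, bipartite consensus matching, overlap merging."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from seqnls.io import AMINO_ACIDS, SequenceRecord

#: Sentinel enrichment for bipartite consensus matches ("arbitrarily large"):
#: they always survive any enrichment cutoff and normalize to 1.
BIPARTITE_ES = math.inf

BASIC = frozenset("KR")


@dataclass(frozen=True)
class Match:
    """A candidate NLS interval (0-based half-open) on a query sequence."""

    seq_id: str
    start: int
    end: int
    source: str  # pattern | bipartite | merged
    e_s: float
    s_l: float | None = None
    final_score: float | None = None
    irlc: float | None = None
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Match") -> bool:
        return self.seq_id == other.seq_id and (
            self.start < other.end and other.start < self.end
        )


def _word_positions(residues: str, word: str) -> list[int]:
    """All start offsets of ``word`` in ``residues`` (overlaps allowed).

    A word containing any letter outside the 20-letter alphabet (e.g. X)
    never matches.
    """
    if not set(word) <= set(AMINO_ACIDS):
        return []
    positions = []
    i = residues.find(word)
    while i != -1:
        positions.append(i)
        i = residues.find(word, i + 1)
    return positions


def _placement_spans(
    residues: str, wordlist: Sequence[str], max_gap: int
) -> set[tuple[int, int]]:
    """All distinct (start, end) spans of gap-bounded ordered placements.

    Words are placed left to right, non-overlapping, with 0..max_gap residues
    strictly between consecutive words. Spans reachable from the same first
    word by different interior placements are deduplicated.
    """
    occurrences = [_word_positions(residues, w) for w in wordlist]
    if any(not occ for occ in occurrences):
        return set()
    spans: set[tuple[int, int]] = set()
    # ends[i] = set of feasible end offsets after placing words[0..i] starting
    # the chain at a given first-word position
    for first in occurrences[0]:
        frontier = {first + len(wordlist[0])}
        for word, occ in zip(wordlist[1:], occurrences[1:]):
            nxt = set()
            for end in frontier:
                for pos in occ:
                    if end <= pos <= end + max_gap:
                        nxt.add(pos + len(word))
            frontier = nxt
            if not frontier:
                break
        for end in frontier:
            spans.add((first, end))
    return spans


def has_wordlist_match(
    residues: str, wordlist: Sequence[str], max_gap: int = 2
) -> bool:
    """Whether any qualified placement of the ordered word-list exists."""
    occurrences = [_word_positions(residues, w) for w in wordlist]
    if any(not occ for occ in occurrences):
        return False
    reachable = {p + len(wordlist[0]) for p in occurrences[0]}
    for word, occ in zip(wordlist[1:], occurrences[1:]):
        nxt = {
            pos + len(word)
            for pos in occ
            if any(end <= pos <= end + max_gap for end in reachable)
        }
        if not nxt:
            return False
        reachable = nxt
    return True


def match_wordlist(
    seq: SequenceRecord,
    wordlist: Sequence[str],
    max_gap: int = 2,
    e_s: float = 0.0,
    pattern_id: str | None = None,
) -> list[Match]:
    """All distinct qualified matches of an ordered word-list in a sequence.

    A qualified match places the words in order, non-overlapping, with each
    inter-word gap between 0 and ``max_gap`` residues. Identical spans are
    reported once.
    """
    if not wordlist:
        raise ValueError("empty word-list")
    name = pattern_id if pattern_id is not None else "-".join(wordlist)
    return [
        Match(seq.id, s, e, "pattern", e_s, provenance=(name,))
        for s, e in sorted(_placement_spans(seq.residues, wordlist, max_gap))
    ]


def match_bipartite(
    seq: SequenceRecord, spacer_lengths: Iterable[int] = (10,)
) -> list[Match]:
    """Matches of the bipartite consensus (K/R)(K/R) X-spacer (K/R)3/5.

    Positions 1-2 basic, a spacer of any residues (default exactly 10), then
    a 5-residue window containing at least 3 of K/R. Enrichment is the
    ``BIPARTITE_ES`` sentinel.
    """
    residues = seq.residues
    n = len(residues)
    matches: list[Match] = []
    for spacer in sorted(set(spacer_lengths)):
        width = 2 + spacer + 5
        for start in range(n - width + 1):
            if residues[start] not in BASIC or residues[start + 1] not in BASIC:
                continue
            tail = residues[start + 2 + spacer : start + width]
            if sum(r in BASIC for r in tail) >= 3:
                matches.append(
                    Match(
                        seq.id,
                        start,
                        start + width,
                        "bipartite",
                        BIPARTITE_ES,
                        provenance=("bipartite",),
                    )
                )
    matches.sort(key=lambda m: (m.start, m.end))
    return matches


def _combine(group: list[Match]) -> Match:
    if len(group) == 1:
        return group[0]

    def opt_max(values: list[float | None]) -> float | None:
        present = [v for v in values if v is not None]
        return max(present) if present else None

    provenance = tuple(
        dict.fromkeys(p for m in group for p in m.provenance)
    )
    return Match(
        group[0].seq_id,
        min(m.start for m in group),
        max(m.end for m in group),
        "merged",
        max(m.e_s for m in group),
        s_l=opt_max([m.s_l for m in group]),
        final_score=opt_max([m.final_score for m in group]),
        irlc=opt_max([m.irlc for m in group]),
        provenance=provenance,
    )


def merge_matches(matches: Iterable[Match]) -> list[Match]:
    """Merge overlapping matches per sequence to a fixed point.

    Overlap requires a shared residue; abutting intervals stay separate. The
    merged match spans the union, takes the max of each score field, and
    carries the union of provenances.
    """
    by_seq: dict[str, list[Match]] = {}
    for m in matches:
        by_seq.setdefault(m.seq_id, []).append(m)
    merged: list[Match] = []
    for seq_id in sorted(by_seq):
        group: list[Match] = []
        for m in sorted(by_seq[seq_id], key=lambda m: (m.start, m.end)):
            if group and m.start < max(g.end for g in group):
                group.append(m)
            else:
                if group:
                    merged.append(_combine(group))
                group = [m]
        if group:
            merged.append(_combine(group))
    return merged
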