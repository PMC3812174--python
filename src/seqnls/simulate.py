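"""Seeded synthetic corpora, query proteins and score tracks.

Generates data with the statistical structure the predictor assumes: planted
gapped word-lists and bipartite basic clusters over a background composition,
disorder elevated inside planted motifs, and conservation higher inside
motifs than in their flanks (with occasional conserved background spikes so
that relative-conservation masking has something to act on).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from seqnls.io import (
    AMINO_ACIDS,
    PSSM_COLUMNS,
    NlsAnnotation,
    Pssm,
    ResidueTrack,
    SequenceRecord,
)
from seqnls.matching import BASIC
from seqnls.mining import TrainingCorpus


@dataclass(frozen=True)
class PlantedWordList:
    """A ground-truth ordered word-list with its planting parameters."""

    words: tuple[str, ...]
    plant_prob: float = 1.0
    gap_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)  # P(gap=0,1,2)

    def __post_init__(self) -> None:
        if not self.words:
            raise ValueError("empty planted word-list")
        if not 0.0 <= self.plant_prob <= 1.0:
            raise ValueError("plant_prob outside [0, 1]")
        if abs(sum(self.gap_probs) - 1.0) > 1e-9:
            raise ValueError("gap_probs must sum to 1")


DEFAULT_WORDLISTS = (
    PlantedWordList(("KR", "KK")),
    PlantedWordList(("PK", "RK")),
)


@dataclass
class SimulationSpec:
    """All knobs of the synthetic generator; fully determined by ``seed``."""

    seed: int = 0
    n_pos: int = 30
    n_neg: int = 500
    n_query: int = 40
    pos_length: tuple[int, int] = (15, 30)
    neg_length: int = 40
    query_length: tuple[int, int] = (200, 600)
    background: dict[str, float] | None = None  # None = uniform over 20
    wordlists: tuple[PlantedWordList, ...] = DEFAULT_WORDLISTS
    bipartite_rate: float = 0.25  # fraction of planted query NLSs bipartite
    nls_per_query: int = 1
    disorder_inside: float = 0.63
    disorder_outside: float = 0.39
    disorder_sd: float = 0.08
    rsa_inside: float = 0.55
    rsa_outside: float = 0.35
    conservation_inside: tuple[int, int] = (4, 9)  # randint bounds [lo, hi)
    conservation_outside: tuple[int, int] = (-2, 3)
    conservation_spike_rate: float = 0.03  # conserved background residues
    conservation_spike: tuple[int, int] = (7, 10)


def _background_sampler(spec: SimulationSpec):
    letters = np.array(list(AMINO_ACIDS))
    if spec.background is None:
        probs = np.full(20, 1 / 20)
    else:
        probs = np.array([spec.background.get(a, 0.0) for a in AMINO_ACIDS])
        probs = probs / probs.sum()

    def sample(rng: np.random.Generator, n: int) -> str:
        return "".join(rng.choice(letters, size=n, p=probs))

    return sample


def _wordlist_instance(
    wl: PlantedWordList, rng: np.random.Generator, sample_bg
) -> str:
    parts = [wl.words[0]]
    for word in wl.words[1:]:
        gap = int(rng.choice([0, 1, 2], p=wl.gap_probs))
        parts.append(sample_bg(rng, gap))
        parts.append(word)
    return "".join(parts)


def _bipartite_instance(rng: np.random.Generator, sample_bg) -> str:
    basic = list(BASIC)
    head = "".join(rng.choice(basic, size=2))
    spacer = sample_bg(rng, 10)
    n_basic = int(rng.integers(3, 6))
    tail = list(sample_bg(rng, 5))
    for i in rng.choice(5, size=n_basic, replace=False):
        tail[i] = str(rng.choice(basic))
    return head + spacer + "".join(tail)


def simulate_training_corpus(
    spec: SimulationSpec,
) -> tuple[TrainingCorpus, list[tuple[str, ...]]]:
    """Positive peptides with planted word-lists; pure-background negatives.

    Returns the corpus and the ground-truth planted word-lists (the ordered
    tuples a miner should recover). Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    sample_bg = _background_sampler(spec)
    positives: list[SequenceRecord] = []
    for i in range(spec.n_pos):
        n = int(rng.integers(spec.pos_length[0], spec.pos_length[1] + 1))
        residues = list(sample_bg(rng, n))
        for wl in spec.wordlists:
            if rng.random() >= wl.plant_prob:
                continue
            instance = _wordlist_instance(wl, rng, sample_bg)
            if len(instance) > n:
                raise ValueError(
                    f"planted word-list {'-'.join(wl.words)} instance of "
                    f"length {len(instance)} exceeds peptide length {n}"
                )
            start = int(rng.integers(0, n - len(instance) + 1))
            residues[start : start + len(instance)] = instance
        positives.append(SequenceRecord(f"pos{i + 1}", "".join(residues)))
    negatives = [
        SequenceRecord(f"neg{i + 1}", sample_bg(rng, spec.neg_length))
        for i in range(spec.n_neg)
    ]
    truth = [wl.words for wl in spec.wordlists]
    return TrainingCorpus(positives, negatives), truth


@dataclass
class QuerySet:
    """Synthetic query proteins with ground truth and score tracks."""

    sequences: list[SequenceRecord]
    annotations: list[NlsAnnotation]
    disorder: dict[str, ResidueTrack]
    rsa: dict[str, ResidueTrack]
    conservation: dict[str, ResidueTrack]
    pssms: dict[str, Pssm]
    sources: list[str] = field(default_factory=list)  # per-annotation origin


def _smooth(values: np.ndarray, window: int = 3) -> np.ndarray:
    kernel = np.full(window, 1 / window)
    padded = np.pad(values, window // 2, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def _make_tracks(
    seq_id: str,
    n: int,
    intervals: list[tuple[int, int]],
    spec: SimulationSpec,
    rng: np.random.Generator,
) -> tuple[ResidueTrack, ResidueTrack, ResidueTrack]:
    inside = np.zeros(n, dtype=bool)
    for s, e in intervals:
        inside[s:e] = True
    dis = np.where(inside, spec.disorder_inside, spec.disorder_outside)
    dis = dis + rng.normal(0.0, spec.disorder_sd, size=n)
    dis = np.clip(_smooth(dis), 0.0, 1.0)
    rsa = np.where(inside, spec.rsa_inside, spec.rsa_outside)
    rsa = np.clip(_smooth(rsa + rng.normal(0.0, spec.disorder_sd, size=n)), 0, 1)
    cons = rng.integers(*spec.conservation_outside, size=n)
    spikes = rng.random(n) < spec.conservation_spike_rate
    cons[spikes] = rng.integers(*spec.conservation_spike, size=int(spikes.sum()))
    cons_in = rng.integers(*spec.conservation_inside, size=n)
    cons = np.where(inside, cons_in, cons).astype(float)
    return (
        ResidueTrack(seq_id, "disorder", [float(v) for v in dis]),
        ResidueTrack(seq_id, "rsa", [float(v) for v in rsa]),
        ResidueTrack(seq_id, "conservation", [float(v) for v in cons]),
    )


def _make_pssm(
    seq: SequenceRecord,
    conservation: ResidueTrack,
    rng: np.random.Generator,
) -> Pssm:
    """Toy PSSM whose own-residue diagonal equals the conservation track."""
    rows: list[dict[str, int]] = []
    for res, value in zip(seq.residues, conservation.values):
        row = {c: int(v) for c, v in zip(PSSM_COLUMNS, rng.integers(-4, 3, 20))}
        if res in row:
            row[res] = int(value)
        rows.append(row)
    return Pssm(seq.id, seq.residues, rows)


def simulate_query_set(spec: SimulationSpec) -> QuerySet:
    """Query proteins with planted NLSs, annotations and aligned tracks.

    Each protein receives ``nls_per_query`` planted intervals, bipartite with
    probability ``bipartite_rate`` and a planted word-list instance
    otherwise. Disorder and RSA are elevated inside planted intervals;
    conservation is higher inside intervals than in their flanks.
    """
    rng = np.random.default_rng(spec.seed + 1)
    sample_bg = _background_sampler(spec)
    sequences: list[SequenceRecord] = []
    annotations: list[NlsAnnotation] = []
    sources: list[str] = []
    disorder: dict[str, ResidueTrack] = {}
    rsa: dict[str, ResidueTrack] = {}
    conservation: dict[str, ResidueTrack] = {}
    pssms: dict[str, Pssm] = {}
    for i in range(spec.n_query):
        seq_id = f"query{i + 1}"
        n = int(rng.integers(spec.query_length[0], spec.query_length[1] + 1))
        residues = list(sample_bg(rng, n))
        intervals: list[tuple[int, int]] = []
        for _ in range(spec.nls_per_query):
            if rng.random() < spec.bipartite_rate:
                instance, origin = _bipartite_instance(rng, sample_bg), "bipartite"
            else:
                wl = spec.wordlists[int(rng.integers(len(spec.wordlists)))]
                instance, origin = _wordlist_instance(wl, rng, sample_bg), (
                    "-".join(wl.words)
                )
            # keep planted intervals well separated (a flank apart)
            for _attempt in range(200):
                start = int(rng.integers(0, n - len(instance) + 1))
                end = start + len(instance)
                if all(
                    start >= e + 10 or end <= s - 10 for s, e in intervals
                ):
                    break
            else:  # pragma: no cover - astronomically unlikely at defaults
                continue
            residues[start:end] = instance
            intervals.append((start, end))
            annotations.append(NlsAnnotation(seq_id, start, end))
            sources.append(origin)
        seq = SequenceRecord(seq_id, "".join(residues))
        sequences.append(seq)
        d, r, c = _make_tracks(seq_id, n, intervals, spec, rng)
        disorder[seq_id], rsa[seq_id], conservation[seq_id] = d, r, c
        pssms[seq_id] = _make_pssm(seq, c, rng)
    return QuerySet(
        sequences, annotations, disorder, rsa, conservation, pssms, sources
    )


def sample_negative_segments(
    annotations: Sequence[NlsAnnotation],
    sequences: Sequence[SequenceRecord],
    seed: int = 0,
) -> list[tuple[str, int, int]]:
    """Length-matched non-NLS segments from the same parent sequences.

    For each annotation, draws a random segment of the same length in the
    same sequence that does not overlap any annotation of that sequence.
    """
    rng = np.random.default_rng(seed)
    by_id = {s.id: s for s in sequences}
    ann_by_seq: dict[str, list[NlsAnnotation]] = {}
    for a in annotations:
        ann_by_seq.setdefault(a.seq_id, []).append(a)
    segments: list[tuple[str, int, int]] = []
    for a in annotations:
        seq = by_id[a.seq_id]
        length = a.end - a.start
        occupied = ann_by_seq[a.seq_id]
        for _attempt in range(1000):
            start = int(rng.integers(0, len(seq) - length + 1))
            end = start + length
            if all(end <= o.start or start >= o.end for o in occupied):
                segments.append((a.seq_id, start, end))
                break
        else:
            raise RuntimeError(
                f"could not place a negative segment of length {length} "
                f"in {a.seq_id!r}"
            )
    return segments
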