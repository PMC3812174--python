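"""End-to-end predictors: scan, score, filter, merge, mask."""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from seqnls.io import NlsAnnotation, ResidueTrack, SequenceRecord
from seqnls.irlc import IrlcConfig, apply_irlc_mask
from seqnls.matching import Match, match_bipartite, match_wordlist, merge_matches
from seqnls.mining import WordListPattern
from seqnls.scoring import (
    LinearMotifModel,
    ScoringConfig,
    final_score,
    linear_motif_score,
)
from seqnls.evaluation import evaluate

logger = logging.getLogger(__name__)


@dataclass
class PredictionSet:
    """Merged, disjoint predictions of one predictor run."""

    mode: str  # sequence_based | integrated
    predictions: list[Match]
    config: ScoringConfig
    n_raw_matches: int = 0
    n_filtered: int = 0
    n_masked: int = 0


def scan_sequences(
    sequences: Iterable[SequenceRecord],
    patterns: Sequence[WordListPattern],
    max_gap: int = 2,
    include_bipartite: bool = True,
) -> list[Match]:
    """Raw qualified matches of all patterns (and the bipartite consensus)."""
    matches: list[Match] = []
    for seq in sequences:
        for p in patterns:
            matches.extend(
                match_wordlist(seq, p.words, max_gap, e_s=p.e_s, pattern_id=str(p))
            )
        if include_bipartite:
            matches.extend(match_bipartite(seq))
    return matches


def predict_sequence_based(
    sequences: Sequence[SequenceRecord],
    patterns: Sequence[WordListPattern],
    config: ScoringConfig | None = None,
    max_gap: int = 2,
    include_bipartite: bool = True,
) -> PredictionSet:
    """Scan, drop pattern matches below the enrichment cutoff, merge.

    Bipartite-consensus matches are never removed by the enrichment cutoff.
    """
    config = config or ScoringConfig()
    raw = scan_sequences(sequences, patterns, max_gap, include_bipartite)
    kept = [
        m for m in raw if m.source == "bipartite" or m.e_s >= config.es_cutoff
    ]
    merged = merge_matches(kept)
    logger.info(
        "sequence-based: %d raw, %d after E_S >= %.3g, %d merged",
        len(raw),
        len(kept),
        config.es_cutoff,
        len(merged),
    )
    return PredictionSet(
        "sequence_based",
        merged,
        config,
        n_raw_matches=len(raw),
        n_filtered=len(raw) - len(kept),
    )


def predict_integrated(
    sequences: Sequence[SequenceRecord],
    patterns: Sequence[WordListPattern],
    model: LinearMotifModel,
    disorder: Mapping[str, ResidueTrack],
    config: ScoringConfig | None = None,
    rsa: Mapping[str, ResidueTrack] | None = None,
    conservation: Mapping[str, ResidueTrack] | None = None,
    irlc_config: IrlcConfig | None = None,
    max_gap: int = 2,
    include_bipartite: bool = True,
) -> PredictionSet:
    """Scan, score each match (S_L then final), filter, merge, IRLC-mask.

    Masking runs only when conservation tracks are supplied.
    """
    config = config or ScoringConfig()
    raw = scan_sequences(sequences, patterns, max_gap, include_bipartite)
    for seq in sequences:
        if seq.id not in disorder and any(m.seq_id == seq.id for m in raw):
            raise KeyError(f"no disorder track for sequence {seq.id!r}")
    scored: list[Match] = []
    for m in raw:
        s_l = linear_motif_score(model, m, disorder, rsa)
        final = final_score(m, s_l, config)
        scored.append(
            Match(
                m.seq_id,
                m.start,
                m.end,
                m.source,
                m.e_s,
                s_l=s_l,
                final_score=final,
                provenance=m.provenance,
            )
        )
    kept = [m for m in scored if m.final_score >= config.final_cutoff]
    merged = merge_matches(kept)
    n_masked = 0
    if conservation is not None:
        before = len(merged)
        merged = apply_irlc_mask(merged, conservation, irlc_config)
        n_masked = before - len(merged)
    logger.info(
        "integrated: %d raw, %d after final >= %.3g, %d merged, %d masked",
        len(raw),
        len(kept),
        config.final_cutoff,
        len(merged) + n_masked,
        n_masked,
    )
    return PredictionSet(
        "integrated",
        merged,
        config,
        n_raw_matches=len(raw),
        n_filtered=len(scored) - len(kept),
        n_masked=n_masked,
    )


def sweep_cutoffs(
    sequences: Sequence[SequenceRecord],
    annotations: Sequence[NlsAnnotation],
    patterns: Sequence[WordListPattern],
    cutoffs: Sequence[float],
    mode: str = "sequence_based",
    model: LinearMotifModel | None = None,
    disorder: Mapping[str, ResidueTrack] | None = None,
    rsa: Mapping[str, ResidueTrack] | None = None,
    conservation: Mapping[str, ResidueTrack] | None = None,
    config: ScoringConfig | None = None,
    irlc_config: IrlcConfig | None = None,
    max_gap: int = 2,
    include_bipartite: bool = True,
) -> pd.DataFrame:
    """Precision/recall/F1/mean-aPC over a grid of cutoffs for one predictor."""
    import dataclasses

    config = config or ScoringConfig()
    rows = []
    for cutoff in cutoffs:
        if mode == "sequence_based":
            cfg = dataclasses.replace(config, es_cutoff=cutoff)
            pred = predict_sequence_based(
                sequences, patterns, cfg, max_gap, include_bipartite
            )
        elif mode == "integrated":
            if model is None or disorder is None:
                raise ValueError("integrated sweep needs a model and disorder")
            cfg = dataclasses.replace(config, final_cutoff=cutoff)
            pred = predict_integrated(
                sequences,
                patterns,
                model,
                disorder,
                cfg,
                rsa=rsa,
                conservation=conservation,
                irlc_config=irlc_config,
                max_gap=max_gap,
                include_bipartite=include_bipartite,
            )
        else:
            raise ValueError(f"unknown mode {mode!r}")
        report = evaluate(pred.predictions, annotations)
        rows.append(
            {
                "cutoff": cutoff,
                "n_predictions": len(pred.predictions),
                "precision": report.precision,
                "recall": report.recall,
                "f1": report.f1,
                "mean_apc": report.mean_apc,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Prediction TSV (1-based inclusive coordinates on disk)

_MATCH_COLUMNS = [
    "seq_id",
    "start",
    "end",
    "source",
    "e_s",
    "s_l",
    "final_score",
    "irlc",
    "provenance",
]


def _fmt(value: float | None) -> str:
    if value is None:
        return "NA"
    if math.isinf(value):
        return "inf"
    return repr(float(value))


def write_matches(matches: Iterable[Match], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_MATCH_COLUMNS)
        for m in matches:
            w.writerow(
                [
                    m.seq_id,
                    m.start + 1,
                    m.end,
                    m.source,
                    _fmt(m.e_s),
                    _fmt(m.s_l),
                    _fmt(m.final_score),
                    _fmt(m.irlc),
                    ";".join(m.provenance),
                ]
            )


def read_matches(path: str | Path) -> list[Match]:
    matches: list[Match] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != _MATCH_COLUMNS:
            raise ValueError(f"{path}: unexpected match-table header {header}")

        def parse(v: str) -> float | None:
            if v == "NA":
                return None
            if v == "inf":
                return math.inf
            return float(v)

        for row in reader:
            matches.append(
                Match(
                    row[0],
                    int(row[1]) - 1,
                    int(row[2]),
                    row[3],
                    parse(row[4]),
                    s_l=parse(row[5]),
                    final_score=parse(row[6]),
                    irlc=parse(row[7]),
                    provenance=tuple(p for p in row[8].split(";") if p),
                )
            )
    return matches
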