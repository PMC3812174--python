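"""Inverse relative local conservation (IRLC) masking.

Linear motifs are more conserved than their flanks, so a prediction whose
flanking region contains a residue far more conserved than the prediction's
interior mean (in whole-sequence standard-deviation units) is likely a false
positive and is masked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from seqnls.io import ResidueTrack
from seqnls.matching import Match

logger = logging.getLogger(__name__)


@dataclass
class IrlcConfig:
    flank: int = 5  # residues inspected on each side of a prediction
    threshold_t: float = 1.7  # mask when IRLC strictly exceeds this

    def __post_init__(self) -> None:
        if self.flank < 1:
            raise ValueError("flank must be >= 1")
        if not np.isfinite(self.threshold_t):
            raise ValueError("threshold_t must be finite")


@dataclass
class IrlcResult:
    match: Match
    m: float  # mean conservation inside the prediction
    sigma: float  # population std of conservation over the whole sequence
    irlc: float  # max over flanking residues of (C_j - M) / sigma
    masked: bool


def irlc_score(
    match: Match, conservation: ResidueTrack, config: IrlcConfig | None = None
) -> IrlcResult:
    """Score one prediction against its flanks.

    M is the mean conservation inside the match; sigma the population
    standard deviation over all residues of the sequence; IRLC the maximum of
    (C_j - M) / sigma over flanking residues within ``config.flank`` of
    either boundary (truncated at the sequence ends). A flat track
    (sigma = 0), or a match with no flanking residues, scores 0.
    """
    config = config or IrlcConfig()
    values = np.asarray(conservation.values, dtype=float)
    n = len(values)
    if not 0 <= match.start < match.end <= n:
        raise ValueError(
            f"match [{match.start}, {match.end}) outside conservation track "
            f"of length {n} for {match.seq_id!r}"
        )
    m = float(values[match.start : match.end].mean())
    sigma = float(values.std())  # population std
    flank_idx = list(range(max(0, match.start - config.flank), match.start))
    flank_idx += list(range(match.end, min(n, match.end + config.flank)))
    if sigma == 0.0 or not flank_idx:
        irlc = 0.0
    else:
        irlc = float(max((values[j] - m) / sigma for j in flank_idx))
    return IrlcResult(match, m, sigma, irlc, masked=irlc > config.threshold_t)


def apply_irlc_mask(
    matches: Iterable[Match],
    conservation: Mapping[str, ResidueTrack],
    config: IrlcConfig | None = None,
    missing: str = "skip",
) -> list[Match]:
    """Drop matches whose IRLC strictly exceeds the threshold.

    Sequences without a conservation track are skipped with a warning
    (``missing='skip'``, default) or raise (``missing='error'``). Kept
    matches are annotated with their IRLC value.
    """
    config = config or IrlcConfig()
    if missing not in ("skip", "error"):
        raise ValueError("missing must be 'skip' or 'error'")
    kept: list[Match] = []
    for match in matches:
        track = conservation.get(match.seq_id)
        if track is None:
            if missing == "error":
                raise KeyError(
                    f"no conservation track for sequence {match.seq_id!r}"
                )
            logger.warning(
                "no conservation track for %r; match [%d, %d) not masked",
                match.seq_id,
                match.start,
                match.end,
            )
            kept.append(match)
            continue
        result = irlc_score(match, track, config)
        if result.masked:
            logger.info(
                "masked %r [%d, %d): IRLC %.3f > %.3f",
                match.seq_id,
                match.start,
                match.end,
                result.irlc,
                config.threshold_t,
            )
        else:
            kept.append(
                Match(
                    match.seq_id,
                    match.start,
                    match.end,
                    match.source,
                    match.e_s,
                    s_l=match.s_l,
                    final_score=match.final_score,
                    irlc=result.irlc,
                    provenance=match.provenance,
                )
            )
    return kept
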