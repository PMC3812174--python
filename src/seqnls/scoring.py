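"""Linear-motif probability (S_L) and final-score combination.

S_L is the calibrated probability that a segment is an NLS given its median
per-residue disorder (optionally also median RSA), from an RBF-kernel SVM
with probability estimation. It is combined with the normalized enrichment
into the final score with weights alpha (enrichment) and 1-alpha (motif),
where pattern matches have their S_L discounted by beta because their
boundaries are less accurate than those of bipartite-consensus matches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

from seqnls.io import ResidueTrack
from seqnls.matching import Match

Segment = tuple[str, int, int]  # seq_id, start, end (0-based half-open)


@dataclass
class ScoringConfig:
    """Thresholds and weights of the score-combination stage."""

    e_k: float = 1.62
    min_score: float = 1.0
    alpha: float = 0.8
    beta: float = 0.6
    final_cutoff: float = 0.85
    es_cutoff: float = 1.62
    use_rsa: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must be in (0, 1]")
        if self.e_k <= self.min_score:
            raise ValueError("e_k must exceed min_score")


@dataclass
class LinearMotifModel:
    """Trained probabilistic segment classifier plus training metadata."""

    classifier: CalibratedClassifierCV
    features: tuple[str, ...]
    seed: int
    n_pos: int
    n_neg: int
    version: str = "1"

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """P(NLS) for rows of feature values."""
        idx = list(self.classifier.classes_).index(1)
        return self.classifier.predict_proba(features)[:, idx]

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "LinearMotifModel":
        model = joblib.load(path)
        if not isinstance(model, LinearMotifModel):
            raise TypeError(f"{path} is not a LinearMotifModel")
        return model


def segment_median(track: ResidueTrack, start: int, end: int) -> float:
    """Median track value over [start, end); even length averages the middle two."""
    if not 0 <= start < end <= len(track):
        raise ValueError(
            f"interval [{start}, {end}) outside track of length {len(track)}"
        )
    return float(np.median(track.values[start:end]))


def _segment_features(
    segments: Iterable[Segment],
    disorder: Mapping[str, ResidueTrack],
    rsa: Mapping[str, ResidueTrack] | None,
    use_rsa: bool,
) -> np.ndarray:
    rows = []
    for seq_id, start, end in segments:
        if seq_id not in disorder:
            raise KeyError(
                f"no disorder track for segment ({seq_id!r}, {start}, {end})"
            )
        row = [segment_median(disorder[seq_id], start, end)]
        if use_rsa:
            if rsa is None or seq_id not in rsa:
                raise KeyError(f"no RSA track for sequence {seq_id!r}")
            row.append(segment_median(rsa[seq_id], start, end))
        rows.append(row)
    return np.asarray(rows, dtype=float)


def train_linear_motif_model(
    pos_segments: Sequence[Segment],
    neg_segments: Sequence[Segment],
    disorder: Mapping[str, ResidueTrack],
    config: ScoringConfig | None = None,
    seed: int = 0,
    rsa: Mapping[str, ResidueTrack] | None = None,
) -> LinearMotifModel:
    """Fit the RBF-kernel probabilistic classifier on segment medians.

    Hyperparameters are the library defaults (C=1, gamma='scale') and are
    recorded in the model metadata.
    """
    config = config or ScoringConfig()
    if len(pos_segments) < 2 or len(neg_segments) < 2:
        raise ValueError("need at least 2 training segments per class")
    x_pos = _segment_features(pos_segments, disorder, rsa, config.use_rsa)
    x_neg = _segment_features(neg_segments, disorder, rsa, config.use_rsa)
    x = np.vstack([x_pos, x_neg])
    y = np.concatenate([np.ones(len(x_pos)), np.zeros(len(x_neg))])
    # RBF-kernel SVM with Platt-style sigmoid calibration; library-default
    # hyperparameters (C=1, gamma='scale'), deterministic CV splits.
    clf = CalibratedClassifierCV(
        SVC(kernel="rbf", random_state=seed), method="sigmoid", ensemble=False
    )
    clf.fit(x, y)
    features = ("median_disorder", "median_rsa") if config.use_rsa else (
        "median_disorder",
    )
    return LinearMotifModel(
        clf, features, seed=seed, n_pos=len(x_pos), n_neg=len(x_neg)
    )


def linear_motif_score(
    model: LinearMotifModel,
    match: Match,
    disorder: Mapping[str, ResidueTrack],
    rsa: Mapping[str, ResidueTrack] | None = None,
) -> float:
    """S_L: probability in [0, 1] that the match interval is an NLS."""
    use_rsa = "median_rsa" in model.features
    x = _segment_features(
        [(match.seq_id, match.start, match.end)], disorder, rsa, use_rsa
    )
    return float(model.predict_proba(x)[0])


def normalized_enrichment(e_s: float, config: ScoringConfig | None = None) -> float:
    """Map enrichment onto [0, 1]: linear ramp from min_score to e_k, clamped.

    The bipartite infinite sentinel maps to 1.
    """
    config = config or ScoringConfig()
    if math.isinf(e_s) and e_s > 0:
        return 1.0
    ramp = (e_s - config.min_score) / (config.e_k - config.min_score)
    return min(1.0, max(0.0, ramp))


def final_score(
    match: Match, s_l: float, config: ScoringConfig | None = None
) -> float:
    """Convex combination of normalized enrichment and (discounted) S_L.

    Pattern matches: alpha * Normalized(E_S) + (1 - alpha) * beta * S_L.
    Bipartite matches: alpha * Normalized(E_S) + (1 - alpha) * S_L.
    """
    config = config or ScoringConfig()
    if not 0.0 <= s_l <= 1.0:
        raise ValueError(f"s_l {s_l} outside [0, 1]")
    norm = normalized_enrichment(match.e_s, config)
    discount = 1.0 if match.source == "bipartite" else config.beta
    return config.alpha * norm + (1.0 - config.alpha) * discount * s_l
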