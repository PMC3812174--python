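"""Overlap-hit metrics, the amino-acid performance coefficient, and AUC."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from seqnls.io import NlsAnnotation
from seqnls.matching import Match, merge_matches


@dataclass
class EvalReport:
    n_hits: int
    n_miss: int
    n_nls: int
    n_nls_covered: int
    precision: float
    recall: float
    f1: float
    apc_values: list[float] = field(default_factory=list)
    mean_apc: float = float("nan")


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def classify_hits(
    predictions: Sequence[Match],
    annotations: Sequence[NlsAnnotation],
    known_seq_ids: Iterable[str] | None = None,
) -> tuple[list[bool], list[bool]]:
    """Label predictions hit/miss and annotations covered/uncovered.

    A prediction is a hit when it shares at least one residue with any
    annotated NLS of the same sequence; an annotation is covered when any
    prediction overlaps it. Counting is many-to-many.
    """
    if known_seq_ids is not None:
        known = set(known_seq_ids)
        for p in predictions:
            if p.seq_id not in known:
                raise KeyError(f"prediction references unknown seq_id {p.seq_id!r}")
    hits = [False] * len(predictions)
    covered = [False] * len(annotations)
    for i, p in enumerate(predictions):
        for j, a in enumerate(annotations):
            if a.seq_id == p.seq_id and _overlap(p.start, p.end, a.start, a.end):
                hits[i] = True
                covered[j] = True
    return hits, covered


def apc(
    pred_start: int, pred_end: int, nls_start: int, nls_end: int
) -> float:
    """Amino-acid performance coefficient: aTP / (aTP + aFP + aFN).

    aTP is the shared residue count, aFP the prediction residues outside the
    NLS, aFN the NLS residues outside the prediction (the Jaccard index of
    the two intervals).
    """
    atp = _overlap(pred_start, pred_end, nls_start, nls_end)
    afp = (pred_end - pred_start) - atp
    afn = (nls_end - nls_start) - atp
    return atp / (atp + afp + afn)


def evaluate(
    predictions: Sequence[Match],
    annotations: Sequence[NlsAnnotation],
    merge_predictions: bool = False,
) -> EvalReport:
    """Precision/recall/F1 over hits plus mean aPC of the hit predictions.

    A hit prediction overlapping several NLSs contributes the aPC against
    the NLS it matches best. ``merge_predictions`` pre-merges overlapping
    predictions (for external predictors that emit overlaps).
    """
    if not annotations:
        raise ValueError("no annotations: recall is undefined")
    if merge_predictions:
        predictions = merge_matches(predictions)
    hits, covered = classify_hits(predictions, annotations)
    n_hits = sum(hits)
    n_miss = len(hits) - n_hits
    n_nls = len(annotations)
    n_nls_covered = sum(covered)
    if n_hits + n_miss == 0:
        warnings.warn("no predictions: precision reported as 0", stacklevel=2)
        precision = 0.0
    else:
        precision = n_hits / (n_hits + n_miss)
    recall = n_nls_covered / n_nls
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    apc_values = []
    for p, is_hit in zip(predictions, hits):
        if not is_hit:
            continue
        apc_values.append(
            max(
                apc(p.start, p.end, a.start, a.end)
                for a in annotations
                if a.seq_id == p.seq_id
                and _overlap(p.start, p.end, a.start, a.end)
            )
        )
    mean_apc = float(np.mean(apc_values)) if apc_values else float("nan")
    return EvalReport(
        n_hits=n_hits,
        n_miss=n_miss,
        n_nls=n_nls,
        n_nls_covered=n_nls_covered,
        precision=precision,
        recall=recall,
        f1=f1,
        apc_values=apc_values,
        mean_apc=mean_apc,
    )


def roc_auc(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> float:
    """AUC by the Mann-Whitney U formulation; ties count one half."""
    if not scores_pos or not scores_neg:
        raise ValueError("need at least one score per class")
    u, _ = mannwhitneyu(scores_pos, scores_neg, alternative="two-sided")
    return float(u) / (len(scores_pos) * len(scores_neg))
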