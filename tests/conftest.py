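import warnings
from pathlib import Path

import numpy as np
import pytest

from seqnls import (
    ResidueTrack,
    ScoringConfig,
    SequenceRecord,
    SimulationSpec,
    train_linear_motif_model,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def toy_pssm_path() -> Path:
    return DATA_DIR / "toy.pssm"


@pytest.fixture
def seq(request):
    return SequenceRecord("s1", request.param)


def make_seq(residues: str, seq_id: str = "s1") -> SequenceRecord:
    return SequenceRecord(seq_id, residues)


def constant_track(seq_id: str, kind: str, value: float, n: int) -> ResidueTrack:
    return ResidueTrack(seq_id, kind, [value] * n)


@pytest.fixture(scope="session")
def high_low_disorder_model():
    """RBF model trained on clearly separated disorder medians (high vs low).

    Positives live on tracks near disorder 0.85, negatives near 0.15, so the
    probed range [0, 1] is bracketed by the training clusters.
    """
    rng = np.random.default_rng(42)
    n_seg, seg_len = 60, 11
    disorder = {}
    pos, neg = [], []
    for i in range(n_seg):
        hi = np.clip(rng.normal(0.85, 0.05, seg_len), 0, 1)
        lo = np.clip(rng.normal(0.15, 0.05, seg_len), 0, 1)
        disorder[f"hi{i}"] = ResidueTrack(f"hi{i}", "disorder", hi.tolist())
        disorder[f"lo{i}"] = ResidueTrack(f"lo{i}", "disorder", lo.tolist())
        pos.append((f"hi{i}", 0, seg_len))
        neg.append((f"lo{i}", 0, seg_len))
    model = train_linear_motif_model(pos, neg, disorder, ScoringConfig(), seed=0)
    return model


@pytest.fixture(scope="session")
def small_benchmark():
    """Seeded synthetic benchmark shared by the slower end-to-end tests."""
    from seqnls import (
        collect_patterns,
        sample_negative_segments,
        simulate_query_set,
        simulate_training_corpus,
    )

    spec = SimulationSpec(seed=1)
    corpus, truth = simulate_training_corpus(spec)
    patterns = collect_patterns(corpus)
    queries = simulate_query_set(spec)
    pos = [(a.seq_id, a.start, a.end) for a in queries.annotations]
    neg = sample_negative_segments(queries.annotations, queries.sequences, seed=7)
    model = train_linear_motif_model(pos, neg, queries.disorder, seed=0)
    return spec, corpus, truth, patterns, queries, model
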