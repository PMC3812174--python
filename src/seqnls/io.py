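"""File formats: FASTA, annotation tables, per-residue score tracks, PSSMs.

All on-disk coordinates are 1-based inclusive; everything in memory is
0-based half-open. This module is the only place the conversion happens.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

#: The 20 standard amino acids, in alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Column order of the PSI-BLAST ASCII PSSM log-odds block.
PSSM_COLUMNS = "ARNDCQEGHILKMFPSTWYV"

TRACK_KINDS = ("disorder", "rsa", "conservation")


@dataclass(frozen=True)
class SequenceRecord:
    """A named protein sequence (upper-case one-letter residues)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for id {self.id!r}")
        bad = set(self.residues) - set(AMINO_ACIDS) - {"X"}
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-amino-acid letters: "
                f"{sorted(bad)}"
            )
        if "X" in self.residues:
            warnings.warn(
                f"sequence {self.id!r} contains 'X' residues; they never "
                "match any word or bipartite position",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class NlsAnnotation:
    """An annotated NLS interval, stored 0-based half-open."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id!r}"
            )


@dataclass
class ResidueTrack:
    """Per-residue scores (disorder, RSA or conservation) for one sequence."""

    seq_id: str
    kind: str
    values: list[float]

    def __post_init__(self) -> None:
        if self.kind not in TRACK_KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}")
        if self.kind in ("disorder", "rsa"):
            for i, v in enumerate(self.values):
                if not 0.0 <= v <= 1.0:
                    raise ValueError(
                        f"{self.kind} score {v} at position {i + 1} of "
                        f"{self.seq_id!r} outside [0, 1]"
                    )

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class Pssm:
    """Position-specific scoring matrix (log-odds block of a PSI-BLAST PSSM)."""

    seq_id: str
    residues: str
    scores: list[dict[str, int]] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.residues):
            raise ValueError(
                f"PSSM for {self.seq_id!r} has {len(self.scores)} rows for "
                f"{len(self.residues)} residues"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA into SequenceRecords; ids are headers up to first space."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# Annotations (TSV: seq_id, start, end[, label]; 1-based inclusive on disk)


def read_annotations(path: str | Path) -> list[NlsAnnotation]:
    anns: list[NlsAnnotation] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "seq_id":
                continue
            seq_id, start, end = row[0], int(row[1]), int(row[2])
            if start < 1 or end < start:
                raise ValueError(
                    f"invalid 1-based annotation {start}-{end} on {seq_id!r}"
                )
            anns.append(NlsAnnotation(seq_id, start - 1, end))
    return anns


def write_annotations(
    annotations: Iterable[NlsAnnotation], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["seq_id", "start", "end"])
        for a in annotations:
            w.writerow([a.seq_id, a.start + 1, a.end])


# ---------------------------------------------------------------------------
# Score tracks (TSV: seq_id, 1-based position, score)


def read_track(path: str | Path, kind: str) -> dict[str, ResidueTrack]:
    """Read per-residue score tracks keyed by sequence id.

    Positions must be contiguous from 1 within each sequence; rows for one
    sequence may appear in any order but a missing position is an error.
    """
    if kind not in TRACK_KINDS:
        raise ValueError(f"unknown track kind {kind!r}")
    by_seq: dict[str, dict[int, float]] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "seq_id":
                continue
            seq_id, pos, score = row[0], int(row[1]), float(row[2])
            by_seq.setdefault(seq_id, {})[pos] = score
    tracks: dict[str, ResidueTrack] = {}
    for seq_id, rows in by_seq.items():
        n = max(rows)
        missing = [p for p in range(1, n + 1) if p not in rows]
        if missing:
            raise ValueError(
                f"track for {seq_id!r} missing positions {missing} "
                f"(expected contiguous 1..{n})"
            )
        tracks[seq_id] = ResidueTrack(
            seq_id, kind, [rows[p] for p in range(1, n + 1)]
        )
    return tracks


def write_track(
    tracks: Iterable[ResidueTrack] | dict[str, ResidueTrack],
    path: str | Path,
) -> None:
    if isinstance(tracks, dict):
        tracks = list(tracks.values())
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for t in tracks:
            for i, v in enumerate(t.values):
                w.writerow([t.seq_id, i + 1, repr(float(v))])


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM


def read_pssm(path: str | Path, seq_id: str | None = None) -> Pssm:
    """Parse the ``-out_ascii_pssm`` dialect of PSI-BLAST.

    Only the first 20 (log-odds) columns are used; the 20 weighted-percentage
    columns and trailing information-content columns are ignored.
    """
    path = Path(path)
    if seq_id is None:
        seq_id = path.stem
    columns: list[str] | None = None
    residues: list[str] = []
    rows: list[dict[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if columns is None:
                # header: 40 single-letter labels (log-odds then percentages)
                if len(fields) >= 20 and all(
                    f in PSSM_COLUMNS for f in fields[:20]
                ):
                    columns = fields[:20]
                continue
            if not fields:
                break  # blank line ends the matrix block
            if not fields[0].isdigit():
                break  # footer (K/Lambda lines)
            if len(fields) < 22:
                raise ValueError(
                    f"{path}:{lineno}: malformed PSSM row "
                    f"({len(fields)} fields, expected >= 22)"
                )
            residues.append(fields[1])
            try:
                values = [int(v) for v in fields[2:22]]
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer log-odds value"
                ) from exc
            rows.append(dict(zip(columns, values)))
    if columns is None or not rows:
        raise ValueError(f"{path}: no PSSM matrix found")
    return Pssm(seq_id, "".join(residues), rows)


def write_pssm(pssm: Pssm, path: str | Path) -> None:
    """Write a PSSM in the PSI-BLAST ASCII dialect (round-trips read_pssm)."""
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted, and "
            "scaled\n"
        )
        fh.write(
            "            "
            + "   ".join(PSSM_COLUMNS)
            + "   "
            + "   ".join(PSSM_COLUMNS)
            + "\n"
        )
        for i, (res, row) in enumerate(zip(pssm.residues, pssm.scores)):
            logodds = " ".join(f"{row[c]:3d}" for c in PSSM_COLUMNS)
            pcts = " ".join(f"{0:3d}" for _ in PSSM_COLUMNS)
            fh.write(f"{i + 1:5d} {res} {logodds}  {pcts}  0.00 0.00\n")
        fh.write("\n")


def conservation_from_pssm(pssm: Pssm) -> ResidueTrack:
    """Per-residue conservation: the log-odds of each position's own residue.

    Residue 'X' has no own column and scores 0 (with a warning).
    """
    values: list[float] = []
    for i, res in enumerate(pssm.residues):
        if res not in PSSM_COLUMNS:
            warnings.warn(
                f"residue {res!r} at position {i + 1} of {pssm.seq_id!r} has "
                "no PSSM column; conservation set to 0",
                stacklevel=2,
            )
            values.append(0.0)
        else:
            values.append(float(pssm.scores[i][res]))
    return ResidueTrack(pssm.seq_id, "conservation", values)


def interval_to_1based(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    return start + 1, end


def interval_from_1based(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    return start - 1, end
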