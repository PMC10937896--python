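"""Sequence I/O and the DNA <-> numeric codec.

All promoter-design stages exchange :class:`SequenceDataset` objects:
ordered, fixed-length DNA sequences over the strict four-letter alphabet,
optionally paired with real-valued activities.  This module is the single
source of truth for the encoding convention: columns are ordered
``A=0, C=1, G=2, T=3`` and positions are 0-based.

Ambiguity codes (``N`` and friends) are rejected outright rather than
randomly resolved — the generative models downstream are defined over a
4-letter categorical alphabet, and silent resolution would corrupt the
training distribution.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

__all__ = [
    "ALPHABET",
    "BASE_INDEX",
    "SequenceFormatError",
    "SequenceRecord",
    "SequenceDataset",
    "read_sequences",
    "attach_activities",
    "write_design_outputs",
    "one_hot",
    "one_hot_many",
    "decode",
    "decode_many",
]


class SequenceFormatError(ValueError):
    """Raised for any malformed sequence or activity input."""


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    seq: str
    activity: Optional[float] = None

    def __post_init__(self):
        if not self.id:
            raise SequenceFormatError("record id must be non-empty")
        _validate_seq(self.seq, self.id)


def _validate_seq(seq: str, label: str) -> None:
    if not seq:
        raise SequenceFormatError(f"record {label!r}: empty sequence")
    for pos, ch in enumerate(seq):
        if ch not in BASE_INDEX:
            raise SequenceFormatError(
                f"record {label!r}: invalid character {ch!r} at position {pos} "
                f"(alphabet is A/C/G/T; ambiguity codes are not accepted)"
            )


@dataclass(frozen=True)
class SequenceDataset:
    """Ordered collection of equal-length records."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self):
        if self.records:
            L = len(self.records[0].seq)
            ids = set()
            for r in self.records:
                if len(r.seq) != L:
                    raise SequenceFormatError(
                        f"record {r.id!r} has length {len(r.seq)}, expected {L}"
                    )
                if r.id in ids:
                    raise SequenceFormatError(f"duplicate record id {r.id!r}")
                ids.add(r.id)

    @property
    def length(self) -> int:
        if not self.records:
            raise SequenceFormatError("empty dataset has no length")
        return len(self.records[0].seq)

    @property
    def has_activity(self) -> bool:
        return bool(self.records) and all(r.activity is not None for r in self.records)

    @property
    def sequences(self) -> list[str]:
        return [r.seq for r in self.records]

    @property
    def activities(self) -> np.ndarray:
        if not self.has_activity:
            raise SequenceFormatError("dataset has no activities attached")
        return np.array([r.activity for r in self.records], dtype=float)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @classmethod
    def from_sequences(cls, seqs: Iterable[str], activities=None,
                       id_prefix: str = "seq") -> "SequenceDataset":
        seqs = list(seqs)
        if activities is None:
            activities = [None] * len(seqs)
        width = max(4, len(str(len(seqs))))
        recs = tuple(
            SequenceRecord(f"{id_prefix}_{i + 1:0{width}d}", s.upper(), a)
            for i, (s, a) in enumerate(zip(seqs, activities))
        )
        return cls(recs)


def read_sequences(path, fmt: str = None) -> SequenceDataset:
    """Read promoter sequences from FASTA or one-sequence-per-line TXT.

    The format is inferred from the extension when ``fmt`` is None
    (``.fa/.fasta/.fna`` -> fasta, else txt).  Input is uppercased; file
    order is preserved; TXT records receive ids ``seq_0001`` style.
    Blank lines and comments are rejected (the dialect is strict).
    """
    path = Path(path)
    if fmt is None:
        fmt = "fasta" if path.suffix.lower() in {".fa", ".fasta", ".fna"} else "txt"
    if fmt not in {"fasta", "txt"}:
        raise ValueError(f"unknown format {fmt!r} (expected 'fasta' or 'txt')")
    if fmt == "fasta":
        recs = []
        for rec in SeqIO.parse(str(path), "fasta"):
            recs.append(SequenceRecord(rec.id, str(rec.seq).upper()))
        ds = SequenceDataset(tuple(recs))
    else:
        recs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                s = line.strip()
                if not s:
                    raise SequenceFormatError(
                        f"{path}: blank line {lineno} (one sequence per line required)"
                    )
                try:
                    rec = SequenceRecord(f"seq_{lineno:04d}", s.upper())
                except SequenceFormatError as e:
                    raise SequenceFormatError(f"{path}: line {lineno}: {e}") from None
                if recs and len(rec.seq) != len(recs[0].seq):
                    raise SequenceFormatError(
                        f"{path}: line {lineno}: length {len(rec.seq)} differs "
                        f"from length {len(recs[0].seq)} of line 1"
                    )
                recs.append(rec)
        ds = SequenceDataset(tuple(recs))
    if not ds.records:
        raise SequenceFormatError(f"{path}: no sequences found")
    return ds


def attach_activities(ds: SequenceDataset, path) -> SequenceDataset:
    """Pair an activity file (one real per line, same order) with ``ds``."""
    path = Path(path)
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            try:
                v = float(s)
            except ValueError:
                raise SequenceFormatError(
                    f"{path}: line {lineno}: cannot parse activity {s!r}"
                ) from None
            if not np.isfinite(v):
                raise SequenceFormatError(
                    f"{path}: line {lineno}: non-finite activity {s!r}"
                )
            values.append(v)
    if len(values) != len(ds):
        raise SequenceFormatError(
            f"{path}: {len(values)} activities for {len(ds)} sequences"
        )
    recs = tuple(replace(r, activity=v) for r, v in zip(ds.records, values))
    return SequenceDataset(recs)


def write_design_outputs(ds: SequenceDataset, fasta_path, csv_path) -> None:
    """Write designed promoters as FASTA plus a CSV of predicted activities.

    CSV header is ``id,sequence,predicted_activity``; activities are
    rendered with 6 significant digits.
    """
    fasta_path, csv_path = Path(fasta_path), Path(csv_path)
    if ds.records and not ds.has_activity:
        raise SequenceFormatError("CSV output requires predicted activities")
    bio = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in ds.records]
    with open(fasta_path, "w") as fh:
        SeqIO.write(bio, fh, "fasta-2line")
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["id", "sequence", "predicted_activity"])
        for r in ds.records:
            w.writerow([
                r.id, r.seq,
                np.format_float_positional(
                    r.activity, precision=6, unique=False, fractional=False
                ),
            ])


# -- codec -------------------------------------------------------------


def one_hot(seq: str) -> np.ndarray:
    """Encode a DNA string as an L x 4 one-hot matrix (A,C,G,T columns)."""
    try:
        idx = np.array([BASE_INDEX[b] for b in seq], dtype=np.intp)
    except KeyError as e:
        raise SequenceFormatError(f"invalid character {e.args[0]!r}") from None
    m = np.zeros((len(seq), 4), dtype=np.float64)
    m[np.arange(len(seq)), idx] = 1.0
    return m


def one_hot_many(seqs: Iterable[str]) -> np.ndarray:
    """Stack one-hot matrices for equal-length sequences: (n, L, 4)."""
    seqs = list(seqs)
    return np.stack([one_hot(s) for s in seqs]) if seqs else np.zeros((0, 0, 4))


def decode(m: np.ndarray) -> str:
    """Decode an L x 4 matrix to DNA by row argmax (ties -> lowest index)."""
    m = np.asarray(m)
    if m.ndim != 2 or m.shape[1] != 4:
        raise ValueError(f"expected L x 4 matrix, got shape {m.shape}")
    return "".join(ALPHABET[i] for i in np.argmax(m, axis=1))


def decode_many(m: np.ndarray) -> list[str]:
    return [decode(row) for row in np.asarray(m)]
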