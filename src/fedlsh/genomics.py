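"""Genome ingestion and slicing into fixed-length numeric feature vectors.

Variable-length nucleotide records are turned into equal-length vectors the
LSH pipeline can index:

1. numericize:  A→0, T→1, C→2, G→3; any other symbol → −1 (same sentinel as
   padding, since the encoding defines only the four-letter map and the −1
   fill — a distinct sentinel is available via ``other_code``).
2. slice: windows of ``sequence_length`` bases starting every
   ``sequence_length − overlap`` positions, so consecutive windows share
   ``overlap`` bases; the final short window is right-padded with −1.
3. identify: each slice gets a deterministic content-derived UUID so
   duplicate fragments can be skipped without cross-client coordination.

The ordinal codes {0..3} feed the projections directly as a
d = sequence_length feature vector.  This imposes an artificial A<T<C<G
geometry on mismatches — a documented caveat of the encoding, kept because
it is what the pipeline defines.
"""

from __future__ import annotations

import math
import uuid
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import InvalidConfigError, ParseError

__all__ = [
    "GenomeRecord",
    "SliceRecord",
    "SlicingConfig",
    "NUCLEOTIDE_CODES",
    "read_fasta",
    "write_fasta",
    "numericize",
    "slice_sequence",
    "n_chunks",
    "make_slice_records",
    "dedup_slices",
    "write_slice_table",
    "read_slice_table",
    "slices_to_feature_matrix",
]

NUCLEOTIDE_CODES = {"A": 0, "T": 1, "C": 2, "G": 3}
PAD = -1

# namespace for content-derived slice identifiers (uuid5 over the vector bytes)
_SLICE_NS = uuid.UUID("6ba7b812-9dad-11d1-80b4-00c04fd430c8")  # RFC 4122 OID ns


@dataclass(frozen=True)
class GenomeRecord:
    """One FASTA record: header token and upper-cased sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"record {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class SlicingConfig:
    """Window size and overlap, in bases, for consecutive slices."""

    sequence_length: int = 3072
    overlap: int = 100

    def __post_init__(self) -> None:
        if self.sequence_length < 1:
            raise InvalidConfigError("sequence_length must be >= 1")
        if not (0 <= self.overlap < self.sequence_length):
            raise InvalidConfigError(
                f"need 0 <= overlap < sequence_length, got overlap={self.overlap}, "
                f"sequence_length={self.sequence_length}"
            )

    @property
    def step(self) -> int:
        return self.sequence_length - self.overlap


@dataclass(frozen=True)
class SliceRecord:
    """One fixed-length slice with provenance.

    ``source_index`` is the ordinal of the originating record (the pairing of
    a slice with its source record's count), ``chunk_index`` its position
    within that record, and ``uuid`` a deterministic function of the vector
    content only.
    """

    uuid: str
    source_index: int
    chunk_index: int
    vector: tuple[int, ...]


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Parse a (possibly multi-line, mixed-case) FASTA file, order-preserving."""
    path = Path(path)
    text_lines = path.read_text().splitlines()
    stripped = [(n, line.strip()) for n, line in enumerate(text_lines, start=1)]
    nonblank = [(n, line) for n, line in stripped if line]
    if not nonblank:
        raise ParseError(f"{path}: empty FASTA file")
    first_n, first = nonblank[0]
    if not first.startswith(">"):
        raise ParseError(f"{path}:{first_n}: expected a '>' header, got {first[:30]!r}")
    for n, line in nonblank:
        if line.startswith(">") and len(line) == 1:
            raise ParseError(f"{path}:{n}: empty FASTA header")

    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(GenomeRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for start in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[start : start + width] + "\n")


def numericize(sequence: str, other_code: int = PAD) -> np.ndarray:
    """Map A→0, T→1, C→2, G→3; any other symbol to ``other_code``."""
    if not sequence:
        raise ParseError("cannot numericize an empty sequence")
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, other_code, dtype=np.int64)
    for base, code in NUCLEOTIDE_CODES.items():
        out[arr == ord(base)] = code
    return out


def n_chunks(length: int, cfg: SlicingConfig) -> int:
    """Number of windows covering a sequence of the given length."""
    return max(1, math.ceil((length - cfg.overlap) / cfg.step))


def slice_sequence(vec: np.ndarray, cfg: SlicingConfig) -> list[np.ndarray]:
    """Cut *vec* into windows of ``sequence_length`` starting every ``step``.

    The final window is right-padded with −1 up to ``sequence_length``; every
    input position is covered by at least one window.
    """
    vec = np.asarray(vec, dtype=np.int64)
    chunks = []
    for k in range(n_chunks(len(vec), cfg)):
        start = k * cfg.step
        window = vec[start : start + cfg.sequence_length]
        if len(window) < cfg.sequence_length:
            window = np.concatenate(
                [window, np.full(cfg.sequence_length - len(window), PAD, dtype=np.int64)]
            )
        chunks.append(window)
    return chunks


def _slice_uuid(vector: np.ndarray) -> str:
    return str(uuid.uuid5(_SLICE_NS, np.asarray(vector, dtype=np.int64).tobytes().hex()))


def make_slice_records(
    records: Sequence[GenomeRecord], cfg: SlicingConfig
) -> list[SliceRecord]:
    """Numericize and slice every record; slices carry (vector, source) pairs."""
    out: list[SliceRecord] = []
    for source_index, rec in enumerate(records):
        vec = numericize(rec.sequence)
        for chunk_index, chunk in enumerate(slice_sequence(vec, cfg)):
            out.append(
                SliceRecord(
                    uuid=_slice_uuid(chunk),
                    source_index=source_index,
                    chunk_index=chunk_index,
                    vector=tuple(int(v) for v in chunk),
                )
            )
    return out


def dedup_slices(slices: Iterable[SliceRecord]) -> list[SliceRecord]:
    """Keep the first occurrence of each content UUID, preserving order."""
    seen: set[str] = set()
    out = []
    for sl in slices:
        if sl.uuid in seen:
            continue
        seen.add(sl.uuid)
        out.append(sl)
    return out


def write_slice_table(slices: Sequence[SliceRecord], path: str | Path) -> None:
    """TSV: uuid, source_index, chunk_index, then one column per position."""
    if not slices:
        raise InvalidConfigError("refusing to write an empty slice table")
    width = len(slices[0].vector)
    rows = []
    for sl in slices:
        if len(sl.vector) != width:
            raise InvalidConfigError("all slices must share one sequence_length")
        rows.append((sl.uuid, sl.source_index, sl.chunk_index) + sl.vector)
    cols = ["uuid", "source_index", "chunk_index"] + [f"p{i}" for i in range(width)]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_slice_table(path: str | Path) -> list[SliceRecord]:
    df = pd.read_csv(path, sep="\t")
    fixed = ["uuid", "source_index", "chunk_index"]
    if list(df.columns[:3]) != fixed:
        raise ParseError(f"{path}: expected leading columns {fixed}, got {list(df.columns[:3])}")
    vec_cols = list(df.columns[3:])
    if not vec_cols:
        raise ParseError(f"{path}: no vector columns found")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SliceRecord(
                uuid=str(row.uuid),
                source_index=int(row.source_index),
                chunk_index=int(row.chunk_index),
                vector=tuple(int(v) for v in row[3:]),
            )
        )
    return out


def slices_to_feature_matrix(slices: Sequence[SliceRecord]):
    """Stack slice vectors into an m×d FeatureMatrix keyed by slice UUID."""
    from .blinding import FeatureMatrix

    if not slices:
        raise InvalidConfigError("no slices to convert")
    values = np.stack([np.asarray(sl.vector, dtype=float) for sl in slices])
    return FeatureMatrix(values=values, row_ids=[sl.uuid for sl in slices])
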