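"""Sequence input/output, alphabet normalization and background composition.

The package works internally in the RNA alphabet with the fixed nucleotide
order A, C, G, U; DNA input is transcribed (T -> U) on load.  Sequences are
held in lightweight frozen dataclasses rather than ``Bio.SeqRecord`` objects
so that downstream numerical code can rely on their invariants, but FASTA
parsing and writing go through Biopython.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlphabetError,
    BackgroundError,
    DuplicateIdError,
    EmptyInputError,
    ZeroLengthRecordError,
)

logger = logging.getLogger(__name__)

#: Fixed nucleotide ordering used by every matrix and report in the package.
RNA_ALPHABET = "ACGU"

#: IUPAC ambiguity codes that a permissive reader may encounter and drop.
AMBIGUITY_CODES = frozenset("RYSWKMBDHVN")

_INDEX = {c: i for i, c in enumerate(RNA_ALPHABET)}

# byte-level lookup table: residue ordinal -> alphabet index (255 = invalid)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _c, _i in _INDEX.items():
    _ENCODE[ord(_c)] = _i


@dataclass(frozen=True)
class SequenceRecord:
    """One nucleotide sequence in the RNA alphabet.

    Parameters
    ----------
    id:
        Record identifier (first whitespace-delimited token of the FASTA
        header).
    residues:
        Upper-case string over ``{A, C, G, U}``.
    description:
        Full FASTA header, retained for provenance.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise ZeroLengthRecordError(f"record {self.id!r} has no residues")
        bad = encode(self.residues)
        if (bad == 255).any():
            pos = int(np.argmax(bad == 255))
            raise AlphabetError(
                f"record {self.id!r}: residue {self.residues[pos]!r} at "
                f"position {pos + 1} is outside the alphabet {RNA_ALPHABET}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SequenceSet:
    """Ordered collection of :class:`SequenceRecord` with unique ids."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise EmptyInputError("sequence set has no records")
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise DuplicateIdError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def total_length(self) -> int:
        return sum(rec.length for rec in self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rec.id for rec in self.records)

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(rec.length for rec in self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, k: int) -> SequenceRecord:
        return self.records[k]

    def encoded(self) -> list[np.ndarray]:
        """Residues of every record as uint8 index arrays (A=0..U=3)."""
        return [encode(rec.residues) for rec in self.records]


@dataclass(frozen=True)
class BackgroundComposition:
    """Pooled nucleotide composition of a sequence set.

    ``counts`` follows the fixed A, C, G, U order; ``freqs`` are the
    maximum-likelihood frequencies ``counts / total``.  Fractional counts are
    allowed so that pseudocount-smoothed compositions can reuse the type.
    """

    counts: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise BackgroundError(f"negative background count in {self.counts}")
        if self.total <= 0:
            raise BackgroundError("background composition has zero total")

    @property
    def total(self) -> float:
        return float(sum(self.counts))

    @property
    def freqs(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / self.total

    def as_dict(self) -> dict[str, float]:
        return dict(zip(RNA_ALPHABET, self.freqs))


def encode(residues: str) -> np.ndarray:
    """Map an RNA string to uint8 indices; invalid residues map to 255."""
    return _ENCODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


def decode(indices: Iterable[int]) -> str:
    """Inverse of :func:`encode`."""
    return "".join(RNA_ALPHABET[i] for i in indices)


def transcribe_residues(residues: str) -> str:
    """Replace every T by U, validating the DNA/RNA alphabet.

    Idempotent: applying it to an RNA string returns the string unchanged.
    """
    up = residues.upper()
    for pos, ch in enumerate(up):
        if ch not in "ACGTU":
            raise AlphabetError(
                f"residue {ch!r} at position {pos + 1} is outside "
                "the alphabet ACGTU"
            )
    return up.replace("T", "U")


def transcribe(seqs: SequenceSet) -> SequenceSet:
    """Transcribe every record of a set to the RNA alphabet."""
    return SequenceSet(
        tuple(
            SequenceRecord(r.id, transcribe_residues(r.residues), r.description)
            for r in seqs
        )
    )


def read_fasta(path: str | Path, *, permissive: bool = False) -> SequenceSet:
    """Read a multi-FASTA file into a :class:`SequenceSet`.

    Sequences are upper-cased and transcribed to the RNA alphabet.  Record
    order follows the file; the id is the first whitespace-delimited header
    token and the full header is kept as the description.

    Parameters
    ----------
    permissive:
        When True, records containing IUPAC ambiguity codes are dropped with
        a logged warning instead of raising :class:`AlphabetError`.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for bio in SeqIO.parse(str(path), "fasta"):
        raw = str(bio.seq).upper()
        if len(raw) == 0:
            raise ZeroLengthRecordError(f"record {bio.id!r} in {path} is empty")
        if permissive and any(c in AMBIGUITY_CODES for c in raw):
            logger.warning(
                "dropping record %r: contains ambiguity codes", bio.id
            )
            continue
        records.append(
            SequenceRecord(bio.id, transcribe_residues(raw), bio.description)
        )
    if not records:
        raise EmptyInputError(f"no usable FASTA records in {path}")
    return SequenceSet(tuple(records))


def write_fasta(seqs: SequenceSet, path: str | Path, *, width: int = 70) -> None:
    """Write a sequence set as standard multi-FASTA."""
    bio_records = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description or "")
        for r in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio_records)


def background_composition(seqs: SequenceSet) -> BackgroundComposition:
    """Pool nucleotide counts over all records of a set.

    Invariant under permutation of the records; frequencies sum to 1.
    """
    counts = np.zeros(4, dtype=np.int64)
    for idx in seqs.encoded():
        counts += np.bincount(idx, minlength=4)[:4]
    return BackgroundComposition(tuple(float(c) for c in counts))


def composition_table(bg: BackgroundComposition):
    """Background composition as a Code/Count/Freq DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "Code": list(RNA_ALPHABET),
            "Count": list(bg.counts),
            "Freq": list(bg.freqs),
        }
    )
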