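"""Transcript representation and HGVS c. coordinate arithmetic.

A :class:`TranscriptModel` holds a contiguous mRNA sequence (leader + CDS,
single exon as presented) together with the length of its 5' UTR.  All
external coordinates use the HGVS c. convention: c.1 is the A of the start
codon (sAUG), negative positions count into the leader, and position 0 does
not exist (c.-1 abuts c.1).  Internally everything is 0-based, half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

logger = logging.getLogger(__name__)

_DNA = set("ACGT")
_DNA_N = set("ACGTN")


class CoordinateError(ValueError):
    """A c. position or sequence index falls outside the transcript."""


class TranscriptValidationError(ValueError):
    """The transcript sequence violates a model invariant."""


def _check_cpos(pos: int) -> int:
    """Validate an HGVS c. position (non-zero signed integer)."""
    pos = int(pos)
    if pos == 0:
        raise CoordinateError("HGVS c. coordinates have no position 0")
    return pos


@dataclass(frozen=True)
class TranscriptModel:
    """An mRNA leader + CDS with a declared start codon.

    Parameters
    ----------
    id : str
        Record label (FASTA id or any tag).
    sequence : str
        Nucleotides over {A,C,G,T,N}, uppercase DNA (U is mapped to T on
        load).  ``sequence[utr5_length:utr5_length+3]`` must be ``ATG``.
    utr5_length : int
        Number of leader nucleotides L; equal to the 0-based index of the
        A of the start codon.
    """

    id: str
    sequence: str
    utr5_length: int

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - _DNA_N
        if bad:
            raise TranscriptValidationError(
                f"{self.id}: ambiguity codes other than N not supported: "
                f"{sorted(bad)}"
            )
        if self.utr5_length < 0:
            raise TranscriptValidationError(f"{self.id}: negative 5' UTR length")
        if len(seq) < self.utr5_length + 3:
            raise TranscriptValidationError(
                f"{self.id}: sequence shorter than leader + start codon"
            )
        if seq[self.utr5_length : self.utr5_length + 3] != "ATG":
            raise TranscriptValidationError(
                f"{self.id}: no ATG at declared CDS start (index "
                f"{self.utr5_length}, found "
                f"{seq[self.utr5_length:self.utr5_length + 3]!r})"
            )
        if "N" in seq[: self.utr5_length]:
            warnings.warn(
                f"{self.id}: N in leader; positions containing N are excluded "
                "from AUG/stop matching",
                stacklevel=2,
            )

    @property
    def cds_start_index(self) -> int:
        """0-based index of the A of the sAUG (== utr5_length)."""
        return self.utr5_length

    @property
    def leader(self) -> str:
        return self.sequence[: self.utr5_length]


def c_to_index(model: TranscriptModel, pos: int) -> int:
    """Convert an HGVS c. position to a 0-based sequence index.

    c.-N maps to L-N; c.+M maps to L+M-1 (L = leader length).
    """
    pos = _check_cpos(pos)
    L = model.utr5_length
    if pos < 0:
        idx = L + pos
        if idx < 0:
            raise CoordinateError(
                f"c.{pos} upstream of transcript {model.id} (5' UTR length {L})"
            )
    else:
        idx = L + pos - 1
        if idx >= len(model.sequence):
            raise CoordinateError(
                f"c.{pos} beyond end of transcript {model.id} "
                f"(length {len(model.sequence)}, 5' UTR length {L})"
            )
    return idx


def index_to_c(model: TranscriptModel, index: int) -> int:
    """Convert a 0-based sequence index to an HGVS c. position (never 0)."""
    if not 0 <= index < len(model.sequence):
        raise CoordinateError(
            f"index {index} out of bounds for transcript {model.id} "
            f"(length {len(model.sequence)})"
        )
    L = model.utr5_length
    return index - L if index < L else index - L + 1


def format_cpos(pos: int) -> str:
    """Render a c. position as an HGVS-style token, e.g. ``c.-263``."""
    return f"c.{_check_cpos(pos)}"


def load_transcript(
    fasta_path: str | Path,
    *,
    utr5_length: int | None = None,
    cds_start: int | None = None,
    record_id: str | None = None,
) -> TranscriptModel:
    """Load a transcript from FASTA with a declared CDS start.

    Exactly one of ``utr5_length`` (leader length) or ``cds_start``
    (1-based position of the A of the start codon) must be given; they are
    related by ``cds_start = utr5_length + 1``.  With multiple records,
    ``record_id`` selects one.
    """
    if (utr5_length is None) == (cds_start is None):
        raise ValueError("give exactly one of utr5_length or cds_start")
    if utr5_length is None:
        if cds_start < 1:
            raise ValueError("cds_start is 1-based and must be >= 1")
        utr5_length = cds_start - 1

    records = {r.id: r for r in SeqIO.parse(str(fasta_path), "fasta")}
    if not records:
        raise TranscriptValidationError(f"no FASTA records in {fasta_path}")
    if record_id is None:
        if len(records) > 1:
            raise TranscriptValidationError(
                f"{fasta_path} has {len(records)} records; select one by id"
            )
        record = next(iter(records.values()))
    else:
        try:
            record = records[record_id]
        except KeyError:
            raise TranscriptValidationError(
                f"record {record_id!r} not found in {fasta_path}"
            ) from None
    return TranscriptModel(
        id=record.id, sequence=str(record.seq), utr5_length=utr5_length
    )
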