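"""uAUG detection and upstream ORF delineation.

The ribosome-scanning model motivates three outcomes for an ORF initiated
at an upstream AUG:

* it terminates at an in-frame stop wholly within the leader (a uORF, which
  generally represses downstream initiation);
* it is in frame with the main ORF and reads through to the sAUG with no
  intervening stop (an N-terminal extension of the main protein);
* it is out of frame and runs past the sAUG into the coding sequence
  (an overlapping oORF), terminating at the first downstream stop.

All positions reported by this module are HGVS c. coordinates.  Distances
to the sAUG are computed under both conventions seen in the literature:
from the last base of the stop (bases strictly between stop and c.1) and
from its first base (through c.-1 inclusive); for one stop they always
differ by 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .transcript import (
    CoordinateError,
    TranscriptModel,
    c_to_index,
    format_cpos,
    index_to_c,
)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class OrfKind(str, Enum):
    UORF = "uORF_terminating_in_leader"
    INFRAME_EXTENSION = "inframe_readthrough_extension"
    OVERLAPPING_OORF = "overlapping_oORF"


@dataclass(frozen=True)
class UpstreamAUG:
    """An AUG in the 5' UTR: position of its A (negative c.) and frame.

    ``frame_offset`` is ``|start| mod 3``; 0 means in frame with the mORF.
    """

    start: int
    frame_offset: int
    created_by: str | None = None


@dataclass(frozen=True)
class ORFRecord:
    """A delineated upstream ORF with its geometry relative to the sAUG.

    Codon counts are given both including and excluding the terminating
    stop: published uORF sizes use either convention.  ``stop_first`` /
    ``stop_last`` are the c. positions of the first and last base of the
    terminating stop (``None`` for a readthrough extension, or for an oORF
    that runs off the end of the modelled sequence).
    """

    start: int
    kind: OrfKind
    frame_offset: int
    stop_first: int | None = None
    stop_last: int | None = None
    length_nt: int | None = None
    codons_incl_stop: int | None = None
    codons_excl_stop: int | None = None
    dist_stop_end_to_saug: int | None = None
    dist_stop_start_to_saug: int | None = None
    extension_codons: int | None = None


@dataclass(frozen=True)
class StopChange:
    """A leader stop codon gained/lost in the frame of an existing uAUG."""

    aug: int  # c. position of the uAUG whose frame is affected
    stop_first: int
    stop_last: int

    def __str__(self) -> str:  # e.g. "c.-254_-252 (frame of c.-263)"
        return (
            f"{format_cpos(self.stop_first)}_{self.stop_last} "
            f"(frame of {format_cpos(self.aug)})"
        )


@dataclass(frozen=True)
class UAUGDiff:
    """Set differences of leader AUGs (and their in-frame leader stops)
    between a reference transcript and an equal-length variant sequence."""

    created: tuple[UpstreamAUG, ...]
    destroyed: tuple[UpstreamAUG, ...]
    uorf_stop_created: tuple[StopChange, ...]
    uorf_stop_destroyed: tuple[StopChange, ...]

    def is_empty(self) -> bool:
        return not (
            self.created
            or self.destroyed
            or self.uorf_stop_created
            or self.uorf_stop_destroyed
        )


def find_augs(sequence: str, start: int = 0, end: int | None = None) -> list[int]:
    """Every index i in [start, end) with sequence[i:i+3] == 'ATG', ascending.

    Overlapping matches are all reported.  Codons containing N never match.
    """
    if end is None:
        end = len(sequence)
    if not 0 <= start <= end <= len(sequence):
        raise CoordinateError(f"region [{start}, {end}) outside sequence")
    return [i for i in range(start, end) if sequence[i : i + 3] == "ATG"]


def find_leader_augs(
    model: TranscriptModel, sequence: str | None = None
) -> list[int]:
    """c. positions of every AUG whose first base lies in the leader.

    ``sequence`` (default: the model's own) lets the same model coordinate
    frame be scanned after in-silico mutagenesis.
    """
    seq = model.sequence if sequence is None else sequence
    return [index_to_c(model, i) for i in find_augs(seq, 0, model.utr5_length)]


def frame_offset(start: int) -> int:
    """Frame of a uAUG at negative c. position relative to the mORF.

    0 iff |start| is divisible by 3 (the AUG is in frame with the sAUG).
    """
    if start >= 0:
        raise ValueError(f"frame_offset is defined for uAUGs only, got {start}")
    return (-start) % 3


def delineate_orf(
    model: TranscriptModel, start: int, sequence: str | None = None
) -> ORFRecord:
    """Walk codon by codon from the AUG at c. position ``start``.

    The first stop in {TAA, TAG, TGA} wholly within the leader terminates a
    uORF; reaching c.1 in frame with no stop is an in-frame readthrough
    extension of ``|start|/3`` codons; otherwise the ORF overlaps the mORF
    out of frame and continues to the first downstream stop.
    """
    seq = model.sequence if sequence is None else sequence
    if len(seq) != len(model.sequence):
        raise ValueError("sequence length differs from model")
    L = model.utr5_length
    start_idx = c_to_index(model, start)
    if seq[start_idx : start_idx + 3] != "ATG":
        raise ValueError(
            f"no ATG at {format_cpos(start)} "
            f"(found {seq[start_idx:start_idx + 3]!r})"
        )
    offset = frame_offset(start)

    i = start_idx
    while i + 3 <= len(seq):
        if i == L and offset == 0:
            # reached the sAUG in frame with no intervening stop
            return ORFRecord(
                start=start,
                kind=OrfKind.INFRAME_EXTENSION,
                frame_offset=0,
                extension_codons=(-start) // 3,
            )
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            stop_first = index_to_c(model, i)
            stop_last = index_to_c(model, i + 2)
            length_nt = i + 2 - start_idx + 1
            in_leader = i + 3 <= L
            return ORFRecord(
                start=start,
                kind=OrfKind.UORF if in_leader else OrfKind.OVERLAPPING_OORF,
                frame_offset=offset,
                stop_first=stop_first,
                stop_last=stop_last,
                length_nt=length_nt,
                codons_incl_stop=length_nt // 3,
                codons_excl_stop=length_nt // 3 - 1,
                dist_stop_end_to_saug=(-stop_last - 1) if in_leader else None,
                dist_stop_start_to_saug=(-stop_first) if in_leader else None,
            )
        i += 3
    # ran off the modelled sequence without a stop (out of frame)
    return ORFRecord(start=start, kind=OrfKind.OVERLAPPING_OORF, frame_offset=offset)


def _leader_frame_stops(sequence: str, aug_idx: int, L: int) -> set[int]:
    """Indices of stop codons wholly in the leader, in frame with aug_idx,
    downstream of the AUG."""
    return {
        i
        for i in range(aug_idx + 3, L - 2, 3)
        if sequence[i : i + 3] in STOP_CODONS
    }


def diff_uaug_events(
    model: TranscriptModel, alt_sequence: str, created_by: str | None = None
) -> UAUGDiff:
    """Compare leader AUG content of the reference model vs a variant sequence.

    For each AUG present in both leaders, in-frame leader stop codons
    downstream of it are also diffed, so variants that shorten, lengthen or
    abolish an existing uORF are detected.  Sequences must be equal length
    (SNV-only contract).
    """
    ref_seq = model.sequence
    if len(alt_sequence) != len(ref_seq):
        raise ValueError(
            f"sequence length mismatch ({len(ref_seq)} vs {len(alt_sequence)}); "
            "only substitutions are supported"
        )
    L = model.utr5_length
    ref_augs = set(find_augs(ref_seq, 0, L))
    alt_augs = set(find_augs(alt_sequence, 0, L))

    def _as_uaug(i: int) -> UpstreamAUG:
        c = index_to_c(model, i)
        return UpstreamAUG(start=c, frame_offset=frame_offset(c), created_by=created_by)

    created = tuple(_as_uaug(i) for i in sorted(alt_augs - ref_augs))
    destroyed = tuple(_as_uaug(i) for i in sorted(ref_augs - alt_augs))

    stop_created: list[StopChange] = []
    stop_destroyed: list[StopChange] = []
    for i in sorted(ref_augs & alt_augs):
        aug_c = index_to_c(model, i)
        ref_stops = _leader_frame_stops(ref_seq, i, L)
        alt_stops = _leader_frame_stops(alt_sequence, i, L)
        for s in sorted(alt_stops - ref_stops):
            stop_created.append(
                StopChange(aug=aug_c, stop_first=index_to_c(model, s),
                           stop_last=index_to_c(model, s + 2))
            )
        for s in sorted(ref_stops - alt_stops):
            stop_destroyed.append(
                StopChange(aug=aug_c, stop_first=index_to_c(model, s),
                           stop_last=index_to_c(model, s + 2))
            )
    return UAUGDiff(
        created=created,
        destroyed=destroyed,
        uorf_stop_created=tuple(stop_created),
        uorf_stop_destroyed=tuple(stop_destroyed),
    )
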