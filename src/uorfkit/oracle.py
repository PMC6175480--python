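"""Brute-force reference for upstream ORF delineation.

Deliberately independent of :mod:`uorfkit.orf`: instead of walking codon by
codon, it enumerates every stop-codon triplet in the sequence up front and
classifies an AUG-initiated ORF by set arithmetic on those positions.  Used
to label spiked test variants and to cross-check the production scanner.
"""

from __future__ import annotations

_STOPS = ("TAA", "TAG", "TGA")


def all_stop_indices(sequence: str) -> list[int]:
    """First-base indices of every stop triplet in the sequence."""
    return [i for i in range(len(sequence) - 2) if sequence[i : i + 3] in _STOPS]


def oracle_delineate(sequence: str, utr5_length: int, aug_index: int) -> dict:
    """Classify the ORF initiated at ``aug_index`` by triplet enumeration.

    Returns a dict with ``kind`` in {"uORF", "extension", "oORF"}, the stop
    index (first base, or None), and the codon/extension counts.
    """
    L = utr5_length
    if sequence[aug_index : aug_index + 3] != "ATG":
        raise ValueError(f"no ATG at index {aug_index}")
    in_frame = [
        s
        for s in all_stop_indices(sequence)
        if s > aug_index and (s - aug_index) % 3 == 0
    ]
    if (L - aug_index) % 3 == 0:
        leader_stops = [s for s in in_frame if s + 3 <= L]
        if leader_stops:
            s = min(leader_stops)
            return {
                "kind": "uORF",
                "stop_index": s,
                "codons_incl_stop": (s + 3 - aug_index) // 3,
            }
        return {
            "kind": "extension",
            "stop_index": None,
            "extension_codons": (L - aug_index) // 3,
        }
    if in_frame:
        s = min(in_frame)
        if s + 3 <= L:
            return {
                "kind": "uORF",
                "stop_index": s,
                "codons_incl_stop": (s + 3 - aug_index) // 3,
            }
        return {"kind": "oORF", "stop_index": s}
    return {"kind": "oORF", "stop_index": None}


def leader_aug_indices(sequence: str, utr5_length: int) -> list[int]:
    """Indices of every ATG whose first base lies in the leader."""
    hits, i = [], sequence.find("ATG")
    while 0 <= i < utr5_length:
        hits.append(i)
        i = sequence.find("ATG", i + 1)
    return hits


def leader_frame_stop_indices(
    sequence: str, utr5_length: int, aug_index: int
) -> set[int]:
    """Stops wholly in the leader, in frame with and downstream of the AUG."""
    return {
        s
        for s in all_stop_indices(sequence)
        if s > aug_index and (s - aug_index) % 3 == 0 and s + 3 <= utr5_length
    }
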