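"""Synthetic transcripts: the TWIST1-like fixture, random leaders, spiked SNVs.

The fixture is a GC-rich leader + short CDS in which every position that the
worked examples depend on is pinned:

* a reference CTG at c.-263..-261 (C>A at -263 creates an AUG) and GTG at
  c.-255..-253 (G>A at -255 creates an AUG);
* the natural TGA stop at c.-62..-60 that terminates the -263 uORF;
* stop-ready triplets for the engineered constructs: T at c.-252 (T>A
  completes TGA at c.-254_-252) and CGA at c.-246..-244 and c.-75..-73
  (C>T completes TGA);
* Kozak determinants: G at -3 of all three candidate starts (c.-266, c.-258,
  c.-3), G at +4 of the -263 uAUG (c.-260) and a non-G +4 for the sAUG
  (c.4=C); the -263 context window is additionally pinned to the consensus
  hexamer so its score strictly exceeds the sAUG's;
* C at c.-282 and c.-280 so that no substitution at c.-281 can complete an
  AUG;
* engineered TAA stops at c.37_39, c.41_43 and c.45_47 (one per frame) so
  overlapping-ORF delineation always terminates inside the modelled CDS.

Unpinned positions are filled GC-rich; a deterministic repair pass then
removes any chance AUG in the leader, any stop in the -263 frame between
c.-263 and c.-63 or in the -255 frame between c.-255 and c.-1, and any stop
in the first 30 nt of the CDS, by setting one unpinned base of the offending
triplet to C (C occurs in neither AUG nor any stop codon, so repair strictly
converges).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import oracle
from .consequence import Classification
from .transcript import TranscriptModel, c_to_index, format_cpos, index_to_c
from .variants import CVariant

_BASES = np.array(list("ACGT"))


class FixtureError(ValueError):
    """The requested fixture dimensions cannot satisfy the constraints."""


@dataclass(frozen=True)
class FixtureSpec:
    """Dimensions and seed for the TWIST1-like fixture transcript."""

    utr5_length: int = 300
    cds_length: int = 51
    gc_fraction: float = 0.6
    seed: int = 1
    id: str = "TWIST1like"


@dataclass(frozen=True)
class ConstraintCheck:
    name: str
    passed: bool
    detail: str = ""


# pinned leader bases, keyed by HGVS c. position ------------------------------
_LEADER_PINS: dict[int, str] = {
    -282: "C", -281: "G", -280: "C",
    # -263 uAUG Kozak window -6..-1 pinned to consensus (R at -3 -> G)
    -269: "G", -268: "C", -267: "C", -266: "G", -265: "C", -264: "C",
    -263: "C", -262: "T", -261: "G",   # reference CTG; C>A creates AUG
    -260: "G",                          # +4 of the -263 uAUG
    -258: "G",                          # -3 of the -255 uAUG
    -255: "G", -254: "T", -253: "G",   # reference GTG; G>A creates AUG
    -252: "T",                          # T>A completes TGA at -254_-252
    -246: "C", -245: "G", -244: "A",   # CGA; C>T completes TGA
    -75: "C", -74: "G", -73: "A",      # CGA; C>T completes TGA
    -62: "T", -61: "G", -60: "A",      # natural uORF stop
    -3: "G",                            # purine at -3 of the sAUG
}

_CDS_PINS: dict[int, str] = {
    1: "A", 2: "T", 3: "G",            # the sAUG
    4: "C",                             # +4 of the sAUG, deliberately not G
    37: "T", 38: "A", 39: "A",         # first stop, frame 0
    41: "T", 42: "A", 43: "A",         # frame 1
    45: "T", 46: "A", 47: "A",         # frame 2
}

_MIN_CDS_FIRST_STOP_C = 31  # first CDS stop starts at c.31 or later

# single-base construct edits (c. position -> alt base) and the AUG each is
# allowed to create; no edit may create any other leader AUG
_CONSTRUCT_EDITS: dict[int, tuple[str, frozenset[int]]] = {
    -263: ("A", frozenset({-263})),
    -255: ("A", frozenset({-255})),
    -252: ("A", frozenset()),
    -246: ("T", frozenset()),
    -75: ("T", frozenset()),
}


def _pin_indices(spec: FixtureSpec) -> dict[int, str]:
    L = spec.utr5_length
    pins = {L + c: b for c, b in _LEADER_PINS.items()}
    pins.update({L + c - 1: b for c, b in _CDS_PINS.items()})
    return pins


def build_fixture(
    spec: FixtureSpec = FixtureSpec(), fasta_path: str | Path | None = None
) -> TranscriptModel:
    """Construct the fixture transcript; optionally write it as FASTA.

    Deterministic for a given spec (same seed -> identical sequence).
    Raises :class:`FixtureError` when the leader is too short to host the
    pinned positions (c.-282 is the most 5' pin) or the CDS too short for
    the engineered stops.
    """
    L, ncds = spec.utr5_length, spec.cds_length
    if L < 282:
        raise FixtureError(
            f"leader of {L} nt cannot host constraints up to c.-282"
        )
    if ncds < 47:
        raise FixtureError(f"CDS of {ncds} nt cannot host the engineered stops")
    rng = np.random.default_rng(spec.seed)
    p_gc = spec.gc_fraction
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]  # A C G T
    seq = list(rng.choice(_BASES, size=L + ncds, p=probs))
    pins = _pin_indices(spec)
    for i, b in pins.items():
        seq[i] = b

    _repair(seq, L, pins)

    # top up leader GC to the requested fraction; C is always safe to add
    leader_at = [
        i for i in range(L) if i not in pins and seq[i] in "AT"
    ]
    rng.shuffle(leader_at)
    need = int(np.ceil(p_gc * L)) - sum(seq[i] in "GC" for i in range(L))
    for i in leader_at[: max(need, 0)]:
        seq[i] = "C"

    model = TranscriptModel(id=spec.id, sequence="".join(seq), utr5_length=L)
    failures = [c for c in validate_fixture(model) if not c.passed]
    if failures:  # pragma: no cover - construction guarantees success
        raise FixtureError(f"constraint repair failed: {failures}")
    if fasta_path is not None:
        Path(fasta_path).write_text(
            f">{model.id} synthetic TWIST1-like transcript, "
            f"5'UTR={L}nt seed={spec.seed}\n{model.sequence}\n"
        )
    return model


def _violating_windows(seq: list[str], L: int) -> list[int]:
    """First-base indices of triplets violating any sequence constraint."""
    s = "".join(seq)
    bad = [i for i in range(L) if s[i : i + 3] == "ATG"]
    # no stop in the -263 frame between c.-263 and c.-63
    for i in range(L - 263, L - 64, 3):
        if s[i : i + 3] in oracle._STOPS:
            bad.append(i)
    # no stop in the -255 frame between c.-255 and c.-1
    for i in range(L - 255, L - 2, 3):
        if s[i : i + 3] in oracle._STOPS:
            bad.append(i)
    # no stop starting within the first 30 nt of the CDS (any frame)
    for i in range(L, L + _MIN_CDS_FIRST_STOP_C - 1):
        if s[i : i + 3] in oracle._STOPS:
            bad.append(i)
    # no construct edit may create an AUG beyond its intended one
    for cpos, (alt, allowed) in _CONSTRUCT_EDITS.items():
        idx = L + cpos
        edited = s[:idx] + alt + s[idx + 1 :]
        for i in range(L):
            if edited[i : i + 3] == "ATG" and (i - L) not in allowed:
                bad.append(i)
    return bad


def _repair(seq: list[str], L: int, pins: dict[int, str]) -> None:
    for _ in range(10 * len(seq)):
        bad = _violating_windows(seq, L)
        if not bad:
            return
        for i in bad:
            free = [j for j in range(i, i + 3) if j not in pins]
            if not free:  # pragma: no cover - pin layout precludes this
                raise FixtureError(f"fully pinned violating triplet at {i}")
            seq[free[0]] = "C"
    raise FixtureError("repair did not converge")  # pragma: no cover


def validate_fixture(model: TranscriptModel) -> list[ConstraintCheck]:
    """Check every fixture constraint on an emitted transcript."""
    checks: list[ConstraintCheck] = []
    L = model.utr5_length
    seq = model.sequence

    def triplet(c: int) -> str:
        return seq[c_to_index(model, c) : c_to_index(model, c) + 3]

    def base(c: int) -> str:
        return seq[c_to_index(model, c)]

    def add(name: str, ok: bool, detail: str = "") -> None:
        checks.append(ConstraintCheck(name, bool(ok), detail if not ok else ""))

    add("ref CTG at c.-263..-261", triplet(-263) == "CTG", triplet(-263))
    add("ref GTG at c.-255..-253", triplet(-255) == "GTG", triplet(-255))
    add("T at c.-252", base(-252) == "T", base(-252))
    add("CGA at c.-246..-244", triplet(-246) == "CGA", triplet(-246))
    add("CGA at c.-75..-73", triplet(-75) == "CGA", triplet(-75))
    add("TGA stop at c.-62..-60", triplet(-62) == "TGA", triplet(-62))
    add("G at c.-281", base(-281) == "G", base(-281))
    for alt in "TA":  # neither documented dialect of the -281 variant makes an AUG
        mutated = list(seq)
        mutated[c_to_index(model, -281)] = alt
        hits = oracle.leader_aug_indices("".join(mutated), L)
        add(
            f"c.-281G>{alt} creates no AUG",
            not hits,
            ", ".join(format_cpos(index_to_c(model, i)) for i in hits),
        )
    for c in (-266, -258, -3):
        add(f"G at {format_cpos(c)} (-3 purine)", base(c) == "G", base(c))
    add("G at c.-260 (+4 of -263 uAUG)", base(-260) == "G", base(-260))
    add("c.4 not G (sAUG +4 weaker)", base(4) != "G", base(4))

    for cpos, (alt, allowed) in _CONSTRUCT_EDITS.items():
        idx = c_to_index(model, cpos)
        edited = seq[:idx] + alt + seq[idx + 1 :]
        extra = [
            format_cpos(index_to_c(model, i))
            for i in oracle.leader_aug_indices(edited, L)
            if index_to_c(model, i) not in allowed
        ]
        add(
            f"{format_cpos(cpos)}>{alt} creates no unintended AUG",
            not extra,
            ", ".join(extra),
        )

    hits = oracle.leader_aug_indices(seq, L)
    add(
        "no AUG in WT leader",
        not hits,
        ", ".join(format_cpos(index_to_c(model, i)) for i in hits),
    )
    stops_263 = [
        format_cpos(index_to_c(model, i))
        for i in range(L - 263, L - 64, 3)
        if seq[i : i + 3] in oracle._STOPS
    ]
    add("no stop in -263 frame before c.-63", not stops_263, ", ".join(stops_263))
    stops_255 = [
        format_cpos(index_to_c(model, i))
        for i in range(L - 255, L - 2, 3)
        if seq[i : i + 3] in oracle._STOPS
    ]
    add("no stop in -255 frame before c.-1", not stops_255, ", ".join(stops_255))
    for f in range(3):
        firsts = [
            index_to_c(model, i)
            for i in range(L + f, len(seq) - 2, 3)
            if seq[i : i + 3] in oracle._STOPS
        ]
        ok = bool(firsts) and firsts[0] >= _MIN_CDS_FIRST_STOP_C
        add(
            f"first CDS stop in frame {f} at c.>={_MIN_CDS_FIRST_STOP_C}",
            ok,
            str(firsts[:1]),
        )
    gc = sum(b in "GC" for b in model.leader) / L
    add(f"leader GC >= 60% (got {gc:.1%})", gc >= 0.60 - 1e-9)
    return checks


# ---------------------------------------------------------------------------
# randomized transcripts and spiked variants for property tests


def random_transcript(
    utr_len: int,
    gc_fraction: float,
    seed: int,
    forbid_leader_aug: bool = False,
    cds_len: int = 30,
    rejection_budget: int = 10_000,
) -> TranscriptModel:
    """A seeded random transcript: leader + ATG + random CDS tail.

    With ``forbid_leader_aug`` the leader is rejection-sampled until it
    contains no ATG (including the junction with the start codon).
    """
    if utr_len < 0 or not 0 < gc_fraction < 1:
        raise ValueError("utr_len must be >= 0 and 0 < gc_fraction < 1")
    rng = np.random.default_rng(seed)
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    cds_tail = "".join(rng.choice(_BASES, size=cds_len, p=p))
    for _ in range(rejection_budget):
        leader = "".join(rng.choice(_BASES, size=utr_len, p=p))
        if not forbid_leader_aug or not oracle.leader_aug_indices(
            leader + "ATG", utr_len
        ):
            return TranscriptModel(
                id=f"random-{seed}",
                sequence=leader + "ATG" + cds_tail,
                utr5_length=utr_len,
            )
    raise FixtureError(f"no AUG-free leader of {utr_len} nt in {rejection_budget} draws")


_ORACLE_KIND_TO_CLASS = {
    "uORF": Classification.UAUG_CREATED_UORF,
    "extension": Classification.UAUG_CREATED_INFRAME_EXTENSION,
    "oORF": Classification.UAUG_CREATED_OVERLAPPING_OORF,
}


def _oracle_label(model: TranscriptModel, variants: list[CVariant]) -> str:
    """Expected classification of a cis SNV set, from the brute-force oracle."""
    L = model.utr5_length
    seq = list(model.sequence)
    for v in variants:
        idx = c_to_index(model, v.pos)
        if seq[idx] != v.ref:
            raise ValueError(f"oracle: ref mismatch at {v.hgvs}")
        seq[idx] = v.alt
    alt_seq = "".join(seq)
    ref_augs = set(oracle.leader_aug_indices(model.sequence, L))
    alt_augs = set(oracle.leader_aug_indices(alt_seq, L))
    if alt_augs - ref_augs:
        a = min(alt_augs - ref_augs)
        return _ORACLE_KIND_TO_CLASS[oracle.oracle_delineate(alt_seq, L, a)["kind"]]
    if ref_augs - alt_augs:
        return Classification.UAUG_DESTROYED
    created = destroyed = False
    for a in sorted(ref_augs & alt_augs):
        ref_stops = oracle.leader_frame_stop_indices(model.sequence, L, a)
        alt_stops = oracle.leader_frame_stop_indices(alt_seq, L, a)
        created = created or bool(alt_stops - ref_stops)
        destroyed = destroyed or bool(ref_stops - alt_stops)
    if created:
        return Classification.UORF_STOP_CREATED
    if destroyed:
        return Classification.UORF_STOP_DESTROYED
    return Classification.NO_UAUG_CHANGE


def spike_variants(
    model: TranscriptModel, n: int, seed: int
) -> list[tuple[list[CVariant], str]]:
    """``n`` labeled variant sets with oracle-derived expected classifications.

    Single leader SNVs are enumerated exhaustively and bucketed by oracle
    label; a few multi-SNV cis plants that rewrite a leader triplet into ATG
    are added so that every reachable ORF kind is represented.  Cases are
    then drawn round-robin across the non-empty buckets with a seeded RNG,
    so the mixture covers every classification the model's leader admits.
    """
    if n == 0:
        return []
    L = model.utr5_length
    rng = np.random.default_rng(seed)
    buckets: dict[str, list[list[CVariant]]] = {}

    for idx in range(L):
        ref = model.sequence[idx]
        if ref == "N":
            continue
        for alt in "ACGT":
            if alt == ref:
                continue
            vs = [CVariant(pos=index_to_c(model, idx), ref=ref, alt=alt)]
            buckets.setdefault(_oracle_label(model, vs), []).append(vs)

    # targeted plants: rewrite a leader triplet into ATG (cis set of <=3 SNVs)
    for start in range(L - 3, -1, -1):
        triplet = model.sequence[start : start + 3]
        if "N" in triplet or triplet == "ATG":
            continue
        vs = [
            CVariant(pos=index_to_c(model, start + k), ref=triplet[k], alt=b)
            for k, b in enumerate("ATG")
            if triplet[k] != b
        ]
        label = _oracle_label(model, vs)
        if len(buckets.get(label, [])) < 3:
            buckets.setdefault(label, []).append(vs)

    for cases in buckets.values():
        rng.shuffle(cases)
    out: list[tuple[list[CVariant], str]] = []
    order = sorted(buckets)
    while len(out) < n:
        progressed = False
        for label in order:
            if buckets[label]:
                out.append((buckets[label].pop(), label))
                progressed = True
                if len(out) == n:
                    break
        if not progressed:  # pragma: no cover - ample cases at any usable L
            raise FixtureError(f"only {len(out)} distinct spike cases available")
    return out
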