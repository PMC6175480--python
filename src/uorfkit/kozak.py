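"""Kozak translation-initiation context extraction and scoring.

The context window spans positions -6..+4 around an AUG (ten bases, with
the AUG itself at window offsets 6..8).  Classification follows the classic
rule: a purine at -3 and a G at +4 are the dominant determinants, giving
*strong* (both), *adequate* (exactly one) or *weak* (neither) contexts.  A
transparent additive position-weight scheme provides a numeric score whose
only promises are (i) the consensus GCCACCATGG is maximal and (ii) the
score never decreases when -3 gains a purine or +4 gains a G.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

CONSENSUS = "GCCACCATGG"  # gccRccAUGG rendered with R -> A

# Window offsets: 0..5 are -6..-1, 6..8 are the AUG, 9 is +4.
_MINUS3 = 3
_PLUS4 = 9

#: Default per-position weights. -3 and +4 carry dominant weight 3; the
#: remaining consensus positions score 1 for a match. N scores 0 anywhere.
DEFAULT_WEIGHTS: dict[int, dict[str, float]] = {
    0: {"G": 1.0},          # -6
    1: {"C": 1.0},          # -5
    2: {"C": 1.0},          # -4
    3: {"A": 3.0, "G": 3.0},  # -3: purine, dominant
    4: {"C": 1.0},          # -2
    5: {"C": 1.0},          # -1
    9: {"G": 3.0},          # +4: dominant
}


class KozakError(ValueError):
    pass


@dataclass(frozen=True)
class KozakModel:
    """Additive scoring table over the -6..-1 and +4 context positions."""

    weights: Mapping[int, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_WEIGHTS
    )

    @property
    def max_score(self) -> float:
        return sum(max(w.values()) for w in self.weights.values())

    @classmethod
    def from_config(cls, table: Mapping[str, Mapping[str, float]]) -> "KozakModel":
        """Build from a config mapping keyed by context position label
        ('-6'..'-1', '+4') to base->weight maps."""
        label_to_offset = {f"{p}": p + 6 for p in range(-6, 0)} | {"+4": 9, "4": 9}
        weights: dict[int, dict[str, float]] = {}
        for label, base_w in table.items():
            if str(label) not in label_to_offset:
                raise KozakError(f"unknown context position {label!r}")
            weights[label_to_offset[str(label)]] = {
                b.upper(): float(w) for b, w in base_w.items()
            }
        return cls(weights=weights)


@dataclass(frozen=True)
class KozakResult:
    """Scored context for one AUG."""

    context: str
    score: float
    strength: str  # strong | adequate | weak
    minus3: str
    plus4: str


def extract_context(sequence: str, aug_index: int) -> str:
    """The 10-mer spanning [aug_index-6, aug_index+4), N-padded at edges."""
    if sequence[aug_index : aug_index + 3] != "ATG":
        raise KozakError(f"no ATG at index {aug_index}")
    chars = []
    for i in range(aug_index - 6, aug_index + 4):
        chars.append(sequence[i] if 0 <= i < len(sequence) else "N")
    return "".join(chars)


def kozak_evaluate(context: str, model: KozakModel | None = None) -> KozakResult:
    """Score a 10-mer context and classify its strength.

    Strength depends only on -3 and +4: purine at -3 and G at +4 -> strong;
    exactly one -> adequate; neither -> weak.  N contributes weight 0 and
    counts as a non-match for the strength rule.
    """
    if model is None:
        model = KozakModel()
    if len(context) != 10 or any(c not in "ACGTN" for c in context):
        raise KozakError(f"malformed context {context!r}")
    score = sum(
        model.weights.get(i, {}).get(base, 0.0) for i, base in enumerate(context)
    )
    minus3, plus4 = context[_MINUS3], context[_PLUS4]
    good3 = minus3 in "AG"
    good4 = plus4 == "G"
    strength = "strong" if (good3 and good4) else ("adequate" if (good3 or good4) else "weak")
    return KozakResult(
        context=context, score=score, strength=strength, minus3=minus3, plus4=plus4
    )


def evaluate_aug(
    sequence: str, aug_index: int, model: KozakModel | None = None
) -> KozakResult:
    """Convenience: extract and score the context of one AUG."""
    return kozak_evaluate(extract_context(sequence, aug_index), model)
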