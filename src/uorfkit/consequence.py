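"""Per-variant(-set) classification of predicted translational consequence.

This module combines uAUG events, ORF geometry and Kozak context into one
report per cis variant set, mirroring the interpretive logic used for
uAUG-creating 5' UTR variants: a created uAUG initiating a sizeable uORF
close to the sAUG predicts repression of main-ORF translation; a short uORF
far from the sAUG permits efficient reinitiation and is predicted tolerated;
an in-frame readthrough uAUG predicts either an unstable N-terminally
extended protein or suppressed sAUG initiation, and is flagged repressive.

The repression thresholds are explicit, tunable heuristics of this package
(see AnnotationConfig), not biological constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import kozak as _kozak
from .orf import ORFRecord, OrfKind, UAUGDiff, delineate_orf, diff_uaug_events
from .transcript import TranscriptModel, c_to_index, format_cpos
from .variants import CVariant, apply_variants


class Classification:
    NO_UAUG_CHANGE = "NO_UAUG_CHANGE"
    UAUG_CREATED_UORF = "UAUG_CREATED_UORF"
    UAUG_CREATED_INFRAME_EXTENSION = "UAUG_CREATED_INFRAME_EXTENSION"
    UAUG_CREATED_OVERLAPPING_OORF = "UAUG_CREATED_OVERLAPPING_OORF"
    UAUG_DESTROYED = "UAUG_DESTROYED"
    UORF_STOP_CREATED = "UORF_STOP_CREATED"
    UORF_STOP_DESTROYED = "UORF_STOP_DESTROYED"


_KIND_TO_CLASS = {
    OrfKind.UORF: Classification.UAUG_CREATED_UORF,
    OrfKind.INFRAME_EXTENSION: Classification.UAUG_CREATED_INFRAME_EXTENSION,
    OrfKind.OVERLAPPING_OORF: Classification.UAUG_CREATED_OVERLAPPING_OORF,
}


@dataclass(frozen=True)
class AnnotationConfig:
    """Tunable thresholds for the repression heuristic.

    min_repressive_uorf_codons
        A uORF at least this long (codons, stop inclusive) is predicted
        repressive regardless of its distance to the sAUG.
    min_safe_reinit_distance_nt
        A uORF whose stop ends closer than this to the sAUG is predicted
        repressive (too little room to reacquire initiation competence).
    avg_residue_mass_da
        Average amino-acid residue mass used to convert an N-terminal
        extension length into a predicted mass increase.
    """

    min_repressive_uorf_codons: int = 10
    min_safe_reinit_distance_nt: int = 200
    avg_residue_mass_da: float = 110.0
    kozak_model: _kozak.KozakModel = field(default_factory=_kozak.KozakModel)

    def __post_init__(self) -> None:
        if (
            self.min_repressive_uorf_codons <= 0
            or self.min_safe_reinit_distance_nt <= 0
            or self.avg_residue_mass_da <= 0
        ):
            raise ValueError("AnnotationConfig thresholds must be positive")


@dataclass(frozen=True)
class ConsequenceReport:
    """One classified annotation unit (a cis set of SNVs)."""

    variants: tuple[str, ...]
    classification: str
    orf: ORFRecord | None = None
    kozak_uaug: _kozak.KozakResult | None = None
    kozak_saug: _kozak.KozakResult | None = None
    repression_flag: str = "not_applicable"
    extension_mass_kda: float | None = None
    notes: str = ""

    def to_dict(self) -> dict:
        """Flat dict in the fixed report-column order."""
        orf = self.orf
        return {
            "variants": ",".join(self.variants),
            "classification": self.classification,
            "uaug_pos": format_cpos(orf.start) if orf else None,
            "frame": orf.frame_offset if orf else None,
            "stop_first": format_cpos(orf.stop_first)
            if orf and orf.stop_first is not None
            else None,
            "stop_last": format_cpos(orf.stop_last)
            if orf and orf.stop_last is not None
            else None,
            "length_nt": orf.length_nt if orf else None,
            "codons_incl_stop": orf.codons_incl_stop if orf else None,
            "codons_excl_stop": orf.codons_excl_stop if orf else None,
            "dist_stop_end": orf.dist_stop_end_to_saug if orf else None,
            "dist_stop_start": orf.dist_stop_start_to_saug if orf else None,
            "extension_codons": orf.extension_codons if orf else None,
            "extension_mass_kda": self.extension_mass_kda,
            "kozak_uaug_strength": self.kozak_uaug.strength if self.kozak_uaug else None,
            "kozak_saug_strength": self.kozak_saug.strength if self.kozak_saug else None,
            "repression_flag": self.repression_flag,
            "notes": self.notes,
        }


REPORT_COLUMNS = (
    "variants",
    "classification",
    "uaug_pos",
    "frame",
    "stop_first",
    "stop_last",
    "length_nt",
    "codons_incl_stop",
    "codons_excl_stop",
    "dist_stop_end",
    "dist_stop_start",
    "extension_codons",
    "extension_mass_kda",
    "kozak_uaug_strength",
    "kozak_saug_strength",
    "repression_flag",
    "notes",
)


def predicted_extension_mass(
    extension_codons: int, config: AnnotationConfig | None = None
) -> tuple[float, int]:
    """Predicted mass added by an N-terminal extension: (raw kDa, nearest int)."""
    if extension_codons <= 0:
        raise ValueError("extension_codons must be positive")
    cfg = config or AnnotationConfig()
    kda = extension_codons * cfg.avg_residue_mass_da / 1000.0
    return kda, round(kda)


def _uorf_repression_flag(orf: ORFRecord, cfg: AnnotationConfig) -> str:
    if (
        orf.codons_incl_stop >= cfg.min_repressive_uorf_codons
        or orf.dist_stop_end_to_saug < cfg.min_safe_reinit_distance_nt
    ):
        return "predicted_repressive"
    return "predicted_tolerated"


def classify_variant_set(
    model: TranscriptModel,
    variants: list[CVariant],
    config: AnnotationConfig | None = None,
) -> ConsequenceReport:
    """Apply a cis set of SNVs and classify the predicted consequence.

    The classification is the highest-impact event: a created uAUG outranks
    a destroyed one, which outranks stop-codon changes within an existing
    uORF frame, which outrank no change.  When several uAUGs are created,
    the most 5' one is classified (scanning ribosomes reach it first) and
    the remainder are listed in the notes.
    """
    cfg = config or AnnotationConfig()
    labels = tuple(v.label for v in variants)
    alt_seq = apply_variants(model, variants)
    diff = diff_uaug_events(model, alt_seq)
    saug_kozak = _kozak.evaluate_aug(alt_seq, model.cds_start_index, cfg.kozak_model)

    if diff.created:
        uaug = diff.created[0]  # most 5' (diff reports ascending positions)
        orf = delineate_orf(model, uaug.start, sequence=alt_seq)
        uaug_kozak = _kozak.evaluate_aug(
            alt_seq, c_to_index(model, uaug.start), cfg.kozak_model
        )
        notes: list[str] = []
        if len(diff.created) > 1:
            others = ", ".join(format_cpos(u.start) for u in diff.created[1:])
            notes.append(f"additional created uAUG(s) at {others}")
        mass_kda: float | None = None
        if orf.kind is OrfKind.UORF:
            flag = _uorf_repression_flag(orf, cfg)
        elif orf.kind is OrfKind.INFRAME_EXTENSION:
            raw, rounded = predicted_extension_mass(orf.extension_codons, cfg)
            mass_kda = raw
            flag = "predicted_repressive"
            notes.append(
                f"in-frame readthrough adds {orf.extension_codons} codons "
                f"(~{rounded} kDa); mechanism unresolved: unstable N-terminally "
                "extended protein vs suppressed initiation at the sAUG"
            )
        else:  # overlapping oORF
            flag = "predicted_repressive"
            notes.append(
                "uAUG-initiated ORF overlaps the mORF out of frame; "
                "reinitiation at the sAUG is not possible"
            )
        return ConsequenceReport(
            variants=labels,
            classification=_KIND_TO_CLASS[orf.kind],
            orf=orf,
            kozak_uaug=uaug_kozak,
            kozak_saug=saug_kozak,
            repression_flag=flag,
            extension_mass_kda=mass_kda,
            notes="; ".join(notes),
        )

    if diff.destroyed:
        gone = ", ".join(format_cpos(u.start) for u in diff.destroyed)
        return ConsequenceReport(
            variants=labels,
            classification=Classification.UAUG_DESTROYED,
            kozak_saug=saug_kozak,
            repression_flag="not_applicable",
            notes=f"uAUG(s) lost at {gone}; existing upstream initiation removed",
        )

    if diff.uorf_stop_created or diff.uorf_stop_destroyed:
        created = diff.uorf_stop_created
        cls = (
            Classification.UORF_STOP_CREATED
            if created
            else Classification.UORF_STOP_DESTROYED
        )
        changes = created or diff.uorf_stop_destroyed
        # re-delineate the affected uORF on the mutated sequence
        orf = delineate_orf(model, changes[0].aug, sequence=alt_seq)
        if orf.kind is OrfKind.UORF:
            flag = _uorf_repression_flag(orf, cfg)
        else:
            flag = "predicted_repressive"
        uaug_kozak = _kozak.evaluate_aug(
            alt_seq, c_to_index(model, changes[0].aug), cfg.kozak_model
        )
        return ConsequenceReport(
            variants=labels,
            classification=cls,
            orf=orf,
            kozak_uaug=uaug_kozak,
            kozak_saug=saug_kozak,
            repression_flag=flag,
            notes="; ".join(str(c) for c in changes),
        )

    return ConsequenceReport(
        variants=labels,
        classification=Classification.NO_UAUG_CHANGE,
        kozak_saug=saug_kozak,
        repression_flag="not_applicable",
    )
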