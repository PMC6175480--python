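"""HGVS c. SNV parsing, genomic-to-transcript mapping, and in-silico mutagenesis.

Only single-nucleotide substitutions are supported: every variant the
annotation logic reasons about is an SNV, and anything else (indels, dups,
intronic offsets) is rejected loudly rather than mis-annotated.  Variants
listed together form one cis unit and are applied jointly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from .transcript import TranscriptModel, c_to_index, format_cpos

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Unicode hyphen/minus lookalikes accepted in input (U+2010, U+2011, U+2012,
# U+2013, U+2014, U+2212) and normalized to ASCII '-'.
_DASHES = "‐‑‒–—−"
_HGVS_RE = re.compile(r"^c\.(-?\d+)([ACGT])>([ACGT])$")


class HgvsParseError(ValueError):
    """Input token is not a supported HGVS c. SNV."""


class VariantApplicationError(ValueError):
    """A variant cannot be applied to the given transcript."""


class GenomicMapError(ValueError):
    """A genomic SNV cannot be mapped onto the transcript."""


@dataclass(frozen=True)
class CVariant:
    """A single-nucleotide substitution in HGVS c. coordinates."""

    pos: int  # signed, non-zero
    ref: str
    alt: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.pos == 0:
            raise HgvsParseError("HGVS c. coordinates have no position 0")
        if self.ref not in "ACGT" or self.alt not in "ACGT":
            raise HgvsParseError(
                f"alleles must be single bases in ACGT: {self.ref}>{self.alt}"
            )
        if self.ref == self.alt:
            raise HgvsParseError(f"ref equals alt at {format_cpos(self.pos)}")
        if not self.label:
            object.__setattr__(self, "label", self.hgvs)

    @property
    def hgvs(self) -> str:
        return f"{format_cpos(self.pos)}{self.ref}>{self.alt}"

    def inverted(self) -> "CVariant":
        """The substitution that undoes this one (alt>ref)."""
        return CVariant(pos=self.pos, ref=self.alt, alt=self.ref)


def parse_hgvs_c(text: str) -> CVariant:
    """Parse an HGVS c. SNV such as ``c.-263C>A``.

    Whitespace and unicode hyphen variants are tolerated.  Position 0,
    indel/dup/del syntax and intronic offsets raise :class:`HgvsParseError`
    identifying the offending token.
    """
    original = text
    cleaned = text.strip()
    for d in _DASHES:
        cleaned = cleaned.replace(d, "-")
    cleaned = re.sub(r"\s+", "", cleaned).upper().replace("C.", "c.", 1)
    m = _HGVS_RE.match(cleaned)
    if not m:
        if re.search(r"(DEL|DUP|INS|_)", cleaned, re.IGNORECASE) or re.search(
            r"\d[+-]\d", cleaned
        ):
            raise HgvsParseError(
                f"unsupported variant type (only SNVs accepted): {original!r}"
            )
        raise HgvsParseError(f"cannot parse HGVS c. SNV: {original!r}")
    pos = int(m.group(1))
    if pos == 0:
        raise HgvsParseError(f"HGVS has no position 0: {original!r}")
    return CVariant(pos=pos, ref=m.group(2), alt=m.group(3))


@dataclass(frozen=True)
class GenomicMap:
    """Strand-aware affine map between genomic and transcript c. coordinates.

    A single anchor (one genomic base paired with its c. position) suffices
    for a contiguous single-exon mapping.  On the minus strand, alleles are
    complemented and genomic position decreases as c. position increases.
    """

    chrom: str
    anchor_gpos: int
    anchor_cpos: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GenomicMapError(f"strand must be + or -: {self.strand!r}")
        if self.anchor_cpos == 0:
            raise GenomicMapError("anchor c. position cannot be 0")


def _c_to_linear(c: int) -> int:
    # Collapse the missing position 0: c.-1 -> -1, c.1 -> 0.
    return c if c < 0 else c - 1


def _linear_to_c(lin: int) -> int:
    return lin if lin < 0 else lin + 1


def map_genomic_to_c(
    gpos: int, ref: str, alt: str, gmap: GenomicMap, chrom: str | None = None
) -> CVariant:
    """Map a genomic SNV onto transcript c. coordinates.

    On the minus strand the c. position increases as the genomic position
    decreases and both alleles are complemented.
    """
    if chrom is not None and chrom != gmap.chrom:
        raise GenomicMapError(f"chromosome {chrom!r} != map {gmap.chrom!r}")
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT":
        raise GenomicMapError(f"only SNVs mappable: {ref}>{alt}")
    step = gpos - gmap.anchor_gpos
    if gmap.strand == "-":
        step = -step
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    cpos = _linear_to_c(_c_to_linear(gmap.anchor_cpos) + step)
    return CVariant(pos=cpos, ref=ref, alt=alt)


def map_c_to_genomic(variant: CVariant, gmap: GenomicMap) -> tuple[str, int, str, str]:
    """Inverse of :func:`map_genomic_to_c`; returns (chrom, gpos, ref, alt)."""
    step = _c_to_linear(variant.pos) - _c_to_linear(gmap.anchor_cpos)
    ref, alt = variant.ref, variant.alt
    if gmap.strand == "-":
        step = -step
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    return gmap.chrom, gmap.anchor_gpos + step, ref, alt


def apply_variants(model: TranscriptModel, variants: list[CVariant]) -> str:
    """Apply SNVs in cis to the transcript sequence; the model is unchanged.

    Every variant's ref must match the sequence at its position (this guards
    input/transcript consistency) and positions must be distinct.  Returns a
    mutated sequence of identical length.
    """
    seen: set[int] = set()
    seq = list(model.sequence)
    for v in variants:
        if v.pos in seen:
            raise VariantApplicationError(
                f"duplicate position {format_cpos(v.pos)} in cis group"
            )
        seen.add(v.pos)
        idx = c_to_index(model, v.pos)
        observed = model.sequence[idx]
        if observed != v.ref:
            raise VariantApplicationError(
                f"reference mismatch at {format_cpos(v.pos)}: variant expects "
                f"{v.ref}, transcript {model.id} has {observed}"
            )
        seq[idx] = v.alt
    return "".join(seq)


# ---------------------------------------------------------------------------
# Input file readers


def read_variant_lines(path: str | Path) -> list[list[CVariant]]:
    """Read an HGVS variant list: one cis annotation unit per line,
    comma-separated SNVs, ``#`` comments and blank lines ignored."""
    units: list[list[CVariant]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        units.append([parse_hgvs_c(tok) for tok in line.split(",") if tok.strip()])
    return units


def read_genomic_map(path: str | Path) -> GenomicMap:
    """Read a one-row map TSV: chrom, anchor_gpos, anchor_cpos, strand."""
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        chrom, gpos, cpos, strand = line.split("\t")
        return GenomicMap(
            chrom=chrom,
            anchor_gpos=int(gpos),
            anchor_cpos=int(cpos),
            strand=strand,
        )
    raise GenomicMapError(f"no map row in {path}")


def read_genomic_tsv(
    path: str | Path, gmap: GenomicMap
) -> list[list[CVariant]]:
    """Read genomic SNVs from a 4-column TSV (chrom, gpos, ref, alt).

    Comma-separated gpos entries on one line would be ambiguous, so each row
    is one annotation unit unless rows share a trailing 5th ``group`` column.
    """
    units: dict[str, list[CVariant]] = {}
    order: list[str] = []
    for i, raw in enumerate(Path(path).read_text().splitlines()):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise GenomicMapError(f"{path}:{i + 1}: expected >= 4 columns")
        chrom, gpos, ref, alt = fields[:4]
        group = fields[4] if len(fields) > 4 else f"__row{i}"
        cv = map_genomic_to_c(int(gpos), ref, alt, gmap, chrom=chrom)
        if group not in units:
            units[group] = []
            order.append(group)
        units[group].append(cv)
    return [units[g] for g in order]


def read_vcf(path: str | Path, gmap: GenomicMap) -> list[list[CVariant]]:
    """Minimal VCF ingestion: SNV records only, one annotation unit each.

    Genotypes are ignored; multi-allelic records contribute one unit per
    SNV alt allele; non-SNV alleles are skipped.
    """
    import pysam

    units: list[list[CVariant]] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1 or alt not in "ACGT":
                    continue
                units.append(
                    [map_genomic_to_c(rec.pos, rec.ref, alt, gmap, chrom=rec.chrom)]
                )
    return units
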