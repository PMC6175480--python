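# uorfkit

Interpretation of single-nucleotide variants in 5′ untranslated regions
(5′ UTRs) that create upstream AUG (uAUG) translation-initiation codons.

## The problem

Most eukaryotic mRNAs are translated by cap-dependent scanning: the 43S
preinitiation complex loads at the 5′ cap and walks the leader until it meets
the first AUG in an acceptable context. A point mutation that creates an AUG
*upstream* of the annotated start codon (the sAUG) can therefore divert
ribosomes away from the main open reading frame (mORF) and silence a gene
without touching a single coding base. For haploinsufficient genes — *TWIST1*
in Saethre–Chotzen syndrome being the motivating case — such 5′ UTR variants
are a clinically important but under-screened class of loss-of-function
alleles.

Given a transcript leader and a set of SNVs, `uorfkit` answers, purely from
sequence geometry:

* Does the variant create (or destroy) a uAUG? Where, and in which reading
  frame relative to the mORF?
* What ORF does the new uAUG initiate — a upstream ORF (uORF) terminating at
  an in-frame stop within the leader, an in-frame readthrough that would add
  an N-terminal extension of |start|/3 residues to the protein, or an
  out-of-frame ORF overlapping the mORF (oORF)?
* How strong is the initiation context (Kozak consensus `gccRccAUGG`; purine
  at −3 and G at +4 are the dominant determinants)?
* Is the event predicted to repress main-ORF translation? Reinitiation after
  a uORF degrades with uORF length and improves with intercistronic
  distance, so the heuristic flags a uORF as repressive when it is long
  (≥ 10 codons, stop-inclusive) **or** its stop sits close to the sAUG
  (< 200 nt); both thresholds are explicit configuration, not constants of
  nature.

All coordinates use HGVS c. notation (c.1 = A of the start codon; negative
positions count into the leader; there is no position 0).

## Worked example

No public transcript download is needed: the package ships a generator for a
TWIST1-like fixture transcript (300 nt leader + 51 nt CDS) in which every
position the published variant interpretations depend on is pinned — the
reference CTG at c.-263..-261 and GTG at c.-255..-253, the natural TGA stop
at c.-62..-60, the stop-ready triplets used by the engineered reporter
constructs, and the Kozak determinants of all three candidate starts.

```bash
uorfkit fixture --out-dir demo --seed 1
uorfkit annotate --transcript demo/twist1_like.fa --utr5-length 300 \
                 --variants demo/constructs.txt
```

Selected columns of the report:

```text
variants             classification                  codons_incl_stop dist_stop_end extension_codons repression_flag
c.-281G>T,c.-263C>A  UAUG_CREATED_UORF               68               59            .                predicted_repressive
c.-281G>T            NO_UAUG_CHANGE                  .                .             .                not_applicable
c.-263C>A            UAUG_CREATED_UORF               68               59            .                predicted_repressive
c.-263C>A,c.-252T>A  UAUG_CREATED_UORF               4                251           .                predicted_tolerated
c.-255G>A            UAUG_CREATED_INFRAME_EXTENSION  .                .             85               predicted_repressive
c.-255G>A,c.-246C>T  UAUG_CREATED_UORF               4                243           .                predicted_tolerated
c.-255G>A,c.-75C>T   UAUG_CREATED_UORF               61               72            .                predicted_repressive
```

Reading the numbers: `c.-263C>A` turns the CTG at c.-263 into an AUG that is
out of frame with the mORF (263 mod 3 ≠ 0) and reads to the TGA at c.-62_-60
— a 204 nt / 68-codon uORF whose stop ends 59 nt (and starts 62 nt) upstream
of the sAUG, predicted repressive. Introducing an early stop at c.-254_-252
shrinks it to 4 codons and pushes the intercistronic distance to 251 nt,
flipping the prediction to tolerated. `c.-255G>A` creates an AUG in frame
with the mORF (255 = 85 × 3): readthrough would extend the protein by 85
residues, ≈ 9.35 kDa at 110 Da per residue. `c.-281G>T` changes no AUG
content at all.

The Kozak context of the created −263 AUG matches the full consensus and
outranks the sAUG's own context (G at +4 versus a non-G):

```bash
uorfkit scan --transcript demo/twist1_like.fa --utr5-length 300 --apply 'c.-263C>A'
# uaug_pos  frame  kind                        kozak_context  kozak_score  kozak_strength
# c.-263    2      uORF_terminating_in_leader  GCCGCCATGG     11           strong
```

Variants can also be supplied as genomic SNVs (4-column TSV or minimal VCF)
together with a one-line strand-aware anchor map; for the minus-strand
*TWIST1* locus, `chr7 19117602 -281 -` maps `chr7:19117584G>T` to
`c.-263C>A` with allele complementation.

As a library:

```python
from uorfkit import build_fixture, classify_variant_set, parse_hgvs_c

model = build_fixture()
report = classify_variant_set(model, [parse_hgvs_c("c.-263C>A")])
print(report.orf.codons_incl_stop, report.orf.dist_stop_end_to_saug)  # 68 59
```

## Layout

| Module | Role |
| --- | --- |
| `uorfkit.transcript` | transcript model, HGVS c. ↔ index arithmetic, FASTA loading |
| `uorfkit.variants` | HGVS c. SNV parsing, genomic↔transcript mapping, cis application |
| `uorfkit.orf` | AUG scanning, ORF delineation, uAUG/stop event diffing |
| `uorfkit.kozak` | context extraction, PWM scoring, strength classification |
| `uorfkit.consequence` | per-variant-set classification and repression heuristic |
| `uorfkit.synthetic` | fixture generator, random transcripts, oracle-labeled spikes |
| `uorfkit.oracle` | independent brute-force ORF delineation (test reference) |
| `uorfkit.cli` | `uorfkit annotate / scan / fixture` |

See `docs/methods.md` for the model, the heuristic's rationale and known
limitations.
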