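# Methods

## Coordinate model

A transcript is a contiguous leader + CDS string (single exon as modelled;
intron-containing c. syntax such as `c.-75+3G>A` is rejected rather than
mis-handled). Internally all arithmetic is 0-based half-open; externally
only HGVS c. coordinates appear. With leader length L, c.-N maps to index
L−N and c.+M to L+M−1; the missing position 0 is collapsed onto a linear
axis for genomic↔transcript conversion, which makes the strand-aware affine
map exact and invertible (round-trip identities are property-tested on both
strands). On the minus strand alleles are complemented.

Input normalisation: sequences are uppercased and U→T so DNA and RNA inputs
behave identically; IUPAC ambiguity codes other than N are rejected; N is
tolerated with a warning and never matches an AUG or stop triplet.

## ORF delineation

From an upstream AUG the scanner walks codon by codon:

1. first stop ∈ {TAA, TAG, TGA} wholly within the leader → a **uORF**;
2. the walk reaches c.1 in frame (|start| ≡ 0 mod 3) with no stop → an
   **in-frame readthrough extension** of |start|/3 codons;
3. otherwise the ORF overlaps the mORF out of frame (**oORF**) and continues
   to the first downstream stop; if the modelled CDS ends first the record
   carries no stop fields.

Reported geometry, for a uORF with stop first/last bases s₁/s₂ (negative
c.): `length_nt = |start| − |s₂| + 1`, `codons_incl_stop = length_nt/3`,
`codons_excl_stop = codons_incl_stop − 1`. Both published codon-count
conventions are first-class because the literature uses both for the same
construct (a "4-codon" uORF is a 3-codon peptide plus its stop).

Two stop-to-sAUG distance conventions exist for the same stop and both are
reported: `dist_stop_end = |s₂| − 1` (bases strictly between the stop and
c.1 — the convention used for "59 bp") and `dist_stop_start = |s₁|` (from
the first stop base through c.-1 — the "62 bp" convention). They always
differ by 3, the stop codon's own length. The repression heuristic uses the
stop-end convention.

Event detection (`diff_uaug_events`) compares equal-length reference and
mutated sequences: set differences of leader AUG positions give
created/destroyed uAUGs; for AUGs present in both, set differences of
in-frame leader stops give uORF-stop creation/destruction (so a variant
that shortens, lengthens or abolishes an existing uORF is detected even
when no AUG changes).

A deliberately independent reference implementation
(`uorfkit.oracle`) enumerates every stop triplet in the sequence up front
and classifies by set arithmetic instead of walking; the two
implementations are cross-checked on 1000 seeded random transcripts, and
the oracle — not the pipeline — labels the spiked variants used in
classification-recovery tests.

## Kozak context

The context is the 10-mer covering −6..+4 around the AUG (N-padded at
sequence edges). Strength is the classic categorical rule: purine at −3 and
G at +4 → strong; exactly one → adequate; neither → weak. The numeric score
is an additive position-weight table: weight 3 for a purine at −3 and for G
at +4, weight 1 for matching the remaining consensus positions
(GCC··CC of `gccRccAUGG`), 0 otherwise and for N. The consensus GCCACCATGG
scores the maximum (11) and the score is monotone in the −3/+4
improvements; both properties are tested. The table is configurable
(`kozak_weights` in the YAML config); only orderings, never absolute
scores, should be interpreted, which is why external initiation-site
predictors' numeric outputs are not reproduced.

## Consequence classification and the repression heuristic

Variants listed together are applied in cis; classification takes the
highest-impact event: created uAUG > destroyed uAUG > uORF-stop created >
uORF-stop destroyed > nothing. When several uAUGs are created the most 5′
one is classified (scanning ribosomes reach it first) and the rest are
listed in the notes.

Repression flag for a created uORF:

* `predicted_repressive` if `codons_incl_stop ≥ min_repressive_uorf_codons`
  (default 10) **or** `dist_stop_end < min_safe_reinit_distance_nt`
  (default 200);
* `predicted_tolerated` otherwise.

The rationale is the reinitiation model: ribosomes terminating a short uORF
can rebind initiation factors and reinitiate at the sAUG if given enough
leader to scan, whereas long uORFs and short intercistronic distances both
suppress reinitiation. The defaults were chosen so that the four reporter
construct outcomes they codify (repressive: 68 codons/59 nt and 61
codons/72 nt uORFs, plus the in-frame readthrough; tolerated: 4-codon uORFs
243–251 nt from the sAUG) are separated with wide margins; they are tunable
configuration, not biological constants, and the single rule-else-tolerated
form keeps the prediction monotone: lengthening a uORF (moving its stop
3 nt downstream) can never flip repressive → tolerated.

In-frame readthrough extensions are flagged `predicted_repressive` with an
explanatory note: reporter data for this variant class show strongly
reduced protein output, and whether the mechanism is an unstable
N-terminally extended protein or suppressed initiation at the sAUG is
unresolved — the note says so rather than pretending to know. The predicted
extension mass is `extension_codons × avg_residue_mass_da / 1000`
(default 110 Da/residue, the standard average residue mass; 85 codons →
9.35 kDa ≈ 9 kDa). Overlapping oORFs are likewise flagged repressive:
termination downstream of the sAUG makes reinitiation at the sAUG
impossible, leaving only leaky scanning. Destroyed uAUGs carry
`not_applicable` — removing upstream initiation does not repress.

The package predicts molecular consequence only. It does not predict
knockdown magnitude (reporter percentages are wet-lab measurements with no
sequence-computable counterpart), penetrance or phenotype.

## The synthetic fixture

The reference transcript of the motivating study is not distributed with
the package, so tests and the acceptance script run on a generated
TWIST1-like transcript: a 300 nt leader (any L ≥ 282 works; 300 comfortably
hosts the most 5′ constrained position and is otherwise arbitrary) plus a
51 nt CDS. Every base the worked interpretations depend on is pinned (see
`uorfkit.synthetic`), including: the editable CTG/GTG triplets, the natural
c.-62_-60 TGA, stop-ready triplets for the engineered constructs (CGA→TGA
via C>T at c.-246 and c.-75; the c.-254_-252 stop completed by T>A at its
third base, matching how those constructs are named), −3 purines for all
three candidate starts, G at +4 of the −263 uAUG and a non-G +4 for the
sAUG, a full consensus hexamer upstream of the −263 site so its Kozak score
strictly exceeds the sAUG's, flanking Cs around c.-281 so no substitution
there can complete an AUG, and one TAA per frame early in the CDS so oORF
delineation always terminates inside the modelled sequence.

Unpinned positions are filled GC-rich (60%, echoing the GC-rich character
of such leaders; the exact value is a free choice) and a deterministic
repair pass enforces the global constraints — no AUG anywhere in the WT
leader, no premature stop in the −263 frame before c.-63 or in the −255
frame before c.-1, no CDS stop in the first 30 nt, and no unintended AUG
creatable by any construct edit — by setting one unpinned base of an
offending triplet to C. C occurs in neither AUG nor any stop codon, so each
repair strictly removes a violation without creating one and the pass
provably converges; this replaces rejection sampling, which at these
lengths would succeed with probability ~10⁻⁴ per draw. The derived geometry
(204 nt, 68/4/61 codons, 59/62/251 nt distances, 85-codon extension) is
fixed by the pins and therefore identical for every seed; the seed only
varies the neutral fill. `validate_fixture` re-checks every constraint on
the emitted sequence and the `fixture` CLI writes the check report beside
the FASTA.

What the fixture does *not* claim: it is not the real NM_000474.3 sequence;
its leader length, GC fill and CDS are synthetic. Tests passing on it show
that the geometry, scoring and classification logic reproduce the published
arithmetic exactly — not that any particular novel transcript's annotation
is clinically correct. Real leaders add complications the model ignores:
secondary structure, internal ribosome entry, near-cognate (non-AUG)
starts, and transcript-isoform heterogeneity. A configuration hook for
near-cognate starts is deliberately left out of scope.

Randomised inputs for property tests come from `random_transcript` (seeded
base sampling at a requested GC fraction, optional rejection sampling to an
AUG-free leader) and `spike_variants`, which enumerates all leader SNVs,
labels each with the brute-force oracle, adds a few multi-SNV cis plants
that rewrite a triplet into ATG so every reachable ORF kind appears, and
draws a seeded round-robin mixture across the label buckets. On an AUG-free
leader the destruction and stop-change classes are unreachable by
construction, so recovery tests run both on the clean fixture and on a
uAUG-bearing mutant baseline.

## Numerical and edge-case choices

* Problem sizes in tests: 1000 random transcripts (leaders 50–400 nt) for
  oracle equivalence and 50+ spiked variants per baseline; the whole suite
  runs in seconds.
* Ties and ordering: AUG lists and event tuples are always in ascending
  transcript order; reports are byte-identical across reruns for fixed
  inputs (no unseeded randomness anywhere in annotation).
* Degenerate inputs: empty variant files produce an empty report and exit
  0 with a warning; per-record failures (e.g. reference-allele mismatch,
  which usually means the variant list and transcript disagree) yield an
  ERROR row and a nonzero exit only when every record fails.
* `apply_variants` requires distinct positions and matching reference
  alleles, preserves length by construction (SNVs only), and never mutates
  the input model; applying the inverse SNV restores the original sequence.
* Thresholds, Kozak weights and the residue mass are overridable via a YAML
  config; the TSV report echoes the effective values in `##` header lines
  so outputs are self-describing.

## Known limitations

* SNVs only; indels in leaders can also create or destroy uORFs but change
  coordinates and are rejected loudly instead of being mis-annotated.
* The repression heuristic is a two-threshold geometric rule; it ignores
  initiation-context strength of the uAUG, uORF peptide effects, and
  ribosome shunting/IRES mechanisms, and its output is categorical by
  design.
* Kozak scores are ordinal, not probabilities; comparing scores across
  different weight tables is meaningless.
* The single-exon model means genomic coordinates must lie within one
  contiguous mapped segment; spliced 5′ UTRs need per-exon anchors, which
  are out of scope.
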