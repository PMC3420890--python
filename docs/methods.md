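# Methods

## Model and conventions

A plasmid is a circular double-stranded DNA. Coordinates are 0-based,
half-open, on the *sense* strand, defined as the strand deposited in the
reference FASTA; the published plasmid maps use coordinates informally and
never state a convention, so feature orientation is reported relative to
that strand. Origin-spanning features are encoded with `end > length` and
read modulo the plasmid length; this keeps rotation of the origin a pure
re-labelling (tested as an invariant). Ambiguity codes are rejected at
load time: the whole analysis is exact-match based, and a reference
containing N cannot support it.

## Read processing

**Trimming.** The 3′ adapter is found as the leftmost read suffix equal to
a prefix of the adapter, requiring at least 3 exactly matching nt (the
full adapter when the suffix is longer than it). "Leftmost" maximises the
removed adapter when several suffixes qualify, which is the intent of
3′-adapter removal; matches are suffix-anchored because the adapter is
ligated at the 3′ end. Two consequences are worth knowing:

* an insert of `raw_len−1` or `raw_len−2` nt leaves a 1–2 nt adapter
  remnant that no ≥3-nt rule can remove; such reads cannot map and end up
  unannotated (the generator's truth table makes this measurable —
  roughly 1.4% of reads under the default length law);
* a read whose insert happens to end in ≥3 nt equal to the adapter start
  is over-trimmed. The remaining prefix still maps at the true position,
  so position-level results are unaffected; lengths shift down rarely.

Reads containing N are excluded before mapping (exact matching cannot
place them), counted and logged. Quality scores are carried but unused;
the procedure is sequence-only. Kept reads are 18–50 nt after trimming.

**Exact mapping.** Implemented as substring search over the doubled
reference sequence, which realises circularity exactly; hits at positions
≥ L are duplicates and discarded. Antisense placements search the
reverse-complemented read. The implementation contract is behavioural:
`plasmidseq.bruteforce` contains an intentionally naive full
rotation-scan mapper with no shared machinery, and tests plus the
acceptance script require exact hit-set agreement on hundreds of random,
planted, origin-spanning and antisense reads.

**Once-per-read annotation.** A read is removed from the dataset when a
stage annotates it. Where a read matches several loci the assignment is
deterministic — lowest sense coordinate, sense before antisense — and the
multi-hit tally is reported; `drop_multihit=True` instead leaves such
reads unannotated and bars them from later rescue stages. The published
procedure states the once-only rule but not the tie policy, so both
behaviours are provided and the default documented. Conservation
(`perfect + polyA + mismatch + unannotated == filtered input`) is
asserted inside every pipeline run, not only in tests.

**Poly(A) rescue.** Only reads that failed exact mapping are scanned. The
maximal terminal A-run is stripped unconditionally — including
reference-templated A's — because partial trimming cannot be decided
read-by-read; as a documented consequence, junctions downstream of a
templated A-run migrate to the run's 5′ edge. Each junction therefore
carries a `templated` count (how many trimmed A's the reference would
account for) so signal-level analyses can correct the shift. Remainders
must exceed 17 nt to be remapped. The junction coordinate is the last
transcribed base: 3′ end of the alignment for sense reads, the lowest
covered sense coordinate (reported with strand) for antisense reads. The
reporting threshold on supporting reads defaults to 1; rescue of reads is
never undone by the threshold.

**Editing remap.** Remaining reads are aligned at minimal Hamming
distance over all circular positions and both strands, capped at five
substitutions, no indels (the analysis counts nucleotide changes only).
Mismatches are stored in reference-sense orientation as
`(offset, ref, read)` and re-derivable from the reference (soundness is
an asserted invariant). For conversion counting they are flipped to
transcript orientation: deamination acts on the transcribed strand, so an
edited antisense read must count as A→G, not T→C. Length classes:
"short" 21–26 nt, "long" = full-length (50 nt) reads; 27–49 nt reads are
tallied separately as "other". The positional profile of edited reads
uses the independent 20–24 nt window, with both a per-base density and a
start-position representation emitted and labelled, since either reading
of a read-distribution plot is defensible. Multi-conversion counts use
at-least-k semantics (k = 2, 3, 4); exactly-k is recoverable by
differencing.

## Quantification

RPKM = count·10⁹/(L·N), RPM = count·10⁶/N with N the number of reads
mapping perfectly to genome or plasmid; the genome-mapped count enters as
an external parameter because genome alignment is outside this package's
scope. Coverage tracks are per-base by default (start-position mode
available) with CPM = raw·10⁶/denominator; the denominator defaults to
the same N as RPKM, with a plasmid-mapped-only option, and is recorded in
the track metadata, making tracks comparable across samples. A display
cut-off is applied only at bedGraph export. Feature attribution uses a
≥50% aligned-base overlap rule (configurable to full containment); the
published table does not state its rule.

The shipped published table (`data/table1.tsv`) is used as an arithmetic
fixture: back-deriving each sample's library size from the Hprt1 row and
recomputing every other row from its raw count reproduces all 43 printed
values within 0.2% relative error, so the anchor-derivation is exact to
printed rounding. The running text accompanying that table quotes RPKM
figures (e.g. EGFP 28,354) that are inconsistent with the table under any
single denominator; the table is taken as normative and the in-text
figures are not reproduced.

## Synthetic data

The generator writes FASTA/BED/FASTQ plus a per-read truth table. The
default scenario mirrors a reporter-vector co-transfection on a 4,700-nt
plasmid: a 798-nt sense-only reporter CDS (weight 0.69 of feature reads),
a 795-nt cassette transcribed equally on both strands and flagged as
dsRNA (0.16), an 861-nt antisense-biased backbone cluster (0.10) and a
600-nt ori-like cluster (0.06); 5% unmappable background; 3% of reads are
poly(A)-junction reads from the reporter's 3′ end. Read lengths follow a
mixture law on [18, 50]: a small-RNA mode centred at 22 nt (65%), a broad
uniform component (25%) and a full-length spike at 50 nt (10%). Editing
is injected per transcript-orientation adenosine at rate 0.1 inside dsRNA
features only, before sequencing error (rate 0.002 per base, uniform over
the three alternatives); tails (geometric, p = 0.35, ≥1) and the adapter
are appended afterwards and are therefore error-free — a deliberate
simplification. Junction sites are planted where neither the junction
base nor its two successors is A, so trimmed tails remap unambiguously;
the templated-run edge case is exercised separately with a planted
templated A-run. Reads are drawn fully inside their feature (features
must therefore be at least one read-length long), background reads are
uniform random sequence (their only role is to exercise the unannotated
bin — they are not a genome model), and the same seed yields
byte-identical output.

What the generator does not emulate: platform-specific (color-space)
error profiles, ligation/library-preparation bias, the read-position
bias visible in real coverage of reporter mRNAs, or genome-derived reads
with real sequence. Passing recovery tests therefore demonstrate the
correctness of the pipeline's logic under the stated statistical
conditions, not robustness to those real-data artefacts.

## Problem sizes and numerical choices

The analysis drivers use 20,000 reads; the acceptance checks run the
default scenario at 100,000 reads — enough that the short-class A→G cell
dominates by an order of magnitude while one full run stays under a
minute. Oracle-agreement checks use a 300-nt random circular reference
and 150–500 reads, where the brute-force scans are affordable. Mismatch
remapping is vectorised over all circular windows per read; memory stays
at O(L·k) per read length via a strided view of the doubled reference.
Ties in minimal-mismatch placement are broken identically to exact
mapping. Degenerate inputs are defined: empty read lists produce valid
empty outputs; reads longer than the plasmid raise; a zero or missing
library size is an error whenever normalisation is requested.

## Known limitations

* Substitution-only alignment: an indel-bearing read is unmappable here.
* The adapter sequence must be supplied; it is not discovered.
* Junctions shifted by templated A-runs are flagged, not corrected.
* The editing profile window (20–24 nt) and spectrum window (21–26 nt)
  follow two different published figures by design; comparing their
  outputs directly requires matching the windows in the configuration.
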