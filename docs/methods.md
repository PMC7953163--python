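# Methods

This note documents the models, conventions and numerical choices behind
`ssrscape`, in the order the pipeline applies them.

## Canonical motif classes

The motif space is every string over {A,C,G,T} of length 1–6 that is
*primitive* (not expressible as k ≥ 2 exact copies of a shorter unit);
there are 5356 of these among the 5460 possible strings. Two primitive
units are equivalent when one is a circular rotation of the other or of
its reverse complement — a tandem array can be read at any phase and on
either strand — which partitions the space into 501 classes (2, 4, 10,
33, 102 and 350 classes for unit lengths 1–6). Each class is named by its
lexicographically smallest member under A < C < G < T, matching the
field's (A)n/(AC)n/(AAT)n notation. The table is rebuilt at first use
from the 5460-string enumeration (sub-millisecond) rather than shipped as
a data file, eliminating any staleness risk; `ssrscape motifs --out`
exports it for inspection. Non-primitive units are rejected rather than
silently reduced; `primitive_root` performs the reduction explicitly
where a caller wants it.

## Perfect-SSR detection

Within each maximal N-free window, the scanner reports maximal tandem
runs of complete unit copies whose primitive unit length is 1–6 and whose
copy count reaches the per-length minimum. Defaults follow the common
genome-survey convention: 12 copies for mononucleotides, 7 for di, 5 for
tri and 4 for tetra/penta/hexa. Scanning is greedy left-to-right: at the
first qualifying position the shortest qualifying primitive unit wins,
the locus consumes its span, and scanning resumes one base past its end.
Trailing partial units are excluded, so locus length is always
unit_length × copies. Only the forward strand is scanned; strand symmetry
is recovered through canonical classes. (Exact coordinates are *not*
strand-symmetric in general: when a flanking base happens to continue the
pattern on one strand only, the greedy leftmost start shifts by less than
one unit between strands. The test suite asserts class/copy identity with
sub-unit coordinate slack.)

The production scanner vectorizes the per-lag equality run-lengths with
numpy; an intentionally naive quadratic reference scanner re-derives the
same semantics by direct string comparison and serves as the independent
arbiter in tests (200 random 5 kb sequences, zero tolerated
discrepancies).

Ambiguous bases are masked, not excised: loci never span an N, reported
coordinates stay on the original assembly, and the effective genome size
used for abundance/density denominators is the non-N length.

## Compound merging

Perfect loci on one sequence separated by gaps of at most d_MAX bp
(default 10) merge transitively into compound loci, irrespective of motif
class. Members are removed from the perfect tally so the P and C
categories stay disjoint; a compound's span runs from its first member's
start to its last member's end, and inter-member gaps are recorded.

## Imperfect-SSR detection

Seeds are perfect runs with at least 3 complete copies covering at least
8 bp. From each seed the scanner extends left and right one base at a
time against the repeating template: a matching base scores +1; at a
mismatch it prefers, in order, an insertion (the next sequence base
matches the currently expected template base; −2), a deletion (the
current base matches the next template base; −2, template advances
without consuming sequence), or a substitution (−1). A direction aborts
after more than 2 consecutive edited positions, and the maximal-scoring
checkpoint — always at a match, so trailing edits never count — bounds
the reported locus. Loci need a total score ≥ 10, a span ≥ 12 bp and at
least one edit (pure perfect arrays are left to the perfect scanner);
reported imperfect loci never overlap each other, enforced by processing
seeds left to right. All penalties and floors are configurable and echoed
into output headers for provenance.

Because classification at a mismatch is greedy, an edit planted as one
type can be detected as another of equal cost (e.g. a substitution inside
a mononucleotide run is indistinguishable from an insertion); the total
edit count is preserved, and validation compares totals. A perfect locus
whose flank happens to extend profitably can also be reported as an
imperfect locus overlapping it; category accounting treats P/C as
disjoint but makes no exclusivity claim between I and the others.

## Genic compartments

GFF3 (parsed with gffutils into an in-memory database, after a structural
pass that reports malformed rows with their line number) yields
per-sequence interval trees for gene spans, exons, CDS and introns, the
latter derived per transcript as gaps between its sorted exons and
unioned per sequence. Exons escaping their gene span are clamped with a
warning. A locus is classified by its **start position**: CDS implies
exon; a position exonic in any isoform is exonic (exon priority over
intron); intergenic means outside every gene span. Start-position
assignment keeps boundary-spanning loci unambiguous and makes the
genic/intergenic split a total function. Compartment tallies report
counts and within-compartment proportions by unit length; the exon
compartment is a superset of CDS positions (they are reported as
separate, non-complementary columns), while intergenic is exclusive.
Empty compartments report missing values, never zeros. A genic position
covered by neither exon nor derived intron (feature-sparse annotations)
falls back to the intron label for primary accounting.

## Landscape statistics

* Abundance = loci / (effective genome Mb); density = locus bp /
  (effective genome Mb).
* Category proportions divide each motif-length category's perfect-locus
  count by the organism's total perfect count; the dominant category is
  the argmax, ties broken toward the shorter unit and flagged.
* Top motifs rank canonical classes by perfect-locus frequency, ties
  broken lexicographically.
* GC content per category is base-weighted over loci (for a perfect
  locus this equals the motif's GC, which the tests spot-check).
* The repeat-copy-number CV uses the sample (n−1) standard deviation —
  the usual small-sample convention — and is undefined (missing, never
  zero) for groups of fewer than two loci.
* Pearson correlations use the two-sided t test with n−2 degrees of
  freedom, t = r·√((n−2)/(1−r²)), via scipy; constant vectors and n < 3
  raise rather than returning NaN.

## Enrichment score matrix

Per organism, classes with perfect-locus frequency below 10 score −2 and
leave the ranking universe (a floor against sampling noise). Remaining
classes are ranked by density, descending, ties broken by representative
so output is platform-stable. The rank bands are nested prefixes — 1–5 ⇒
3, 6–20 ⇒ 2, 21–35 ⇒ 1 — the bottom 20 surviving ranks score −1 (never
overriding a positive band, which can only collide when ≤ 55 classes
survive), and everything else scores 0. The bottom band is computed
within the surviving universe, consistent with applying the frequency
floor first. The matrix keeps organisms in metadata order; an optional
deterministic column ordering by mean score provides an
"enrichment-first" view in place of clustering, which is out of scope as
a purely visual step.

A class is clade-specific when its frequency reaches the presence
threshold (default 10, aligned with the matrix floor and configurable
down to 1 for a presence/absence reading) in at least one species of
exactly one clade. Carrier species are reported per class.

## Synthetic genomes

The generator emulates what the analysis assumes about real assemblies:
i.i.d. background at a chosen GC (default 0.42, a typical mammalian
value), N blocks standing in for assembly gaps, and planted loci of known
class, copy number and edit structure separated by spacers of at least
2·d_MAX + 1 bp so planted loci can never interact. Repeat copy numbers are
the per-length minimum plus a truncated geometric tail (p = 0.35, cap
+12), mimicking the empirical decay of repeat lengths; a fixed-copies
mode supports constructions where repeat bp must be exactly proportional
to genome size. Default planting rates (400 perfect, 60 compound, 140
imperfect loci per Mb) give landscapes dense enough for class-level
statistics while leaving > 95% of the sequence as background.

Spacers are certified: a vectorized screen re-samples any span containing
a tandem run of ≥ 3 copies over ≥ 8 bp (the seed criterion, a strict
superset of the perfect-locus criterion), so background can neither
contain perfect loci nor seed imperfect extensions. Junctions are
repaired by re-sampling up to 6 flanking bases until the brute-force
reference scanner recovers exactly the planted perfect loci in a local
window; for imperfect plants the window must additionally contain no
perfect-qualifying run and be recovered by the imperfect search with the
planted span and edit count. The perfect-side certification deliberately
uses the reference scanner, keeping fixture validity independent of the
production code it is used to test; the imperfect-side check uses the
production search itself, since span-exact agreement between two
independent greedy aligners is not a well-defined target — the
consequence is that imperfect-recovery tests certify the construction,
while perfect-recovery tests remain a fully independent check.

Annotations realize each locus's intended compartment with a nested
gene/mRNA/exon/CDS arrangement laid out in the spacer territory around
the locus (pads never reach half the flanking spacer, so genes cannot
collide or swallow neighbours); a round-trip through the annotation
module verifies every intended compartment.

Panels derive one sub-seed per organism by SHA-256 over the master seed
and organism id (kept below 2³¹), so organisms are independent and any
single organism is reproducible in isolation. Clade plans set motif-class
weights (mono-dominant and di-dominant profiles ship as presets),
exclusive classes planted only in that clade, and genome sizes.

What the generator does **not** emulate: chromosome-scale length
distributions, transposable elements and other interspersed repeats,
local GC heterogeneity (isochores), and phylogenetically correlated motif
evolution within clades. Passing recovery tests therefore demonstrate
correctness of the detection and accounting machinery under the stated
repeat model, not performance on the full complexity of real assemblies;
in particular, real genomes contain vastly more borderline arrays near
thresholds than the certified spacers do.

## Problem sizes and determinism

The validation suite uses 200 × 5 kb sequences for scanner/reference
agreement, a six-organism panel of 1 Mb genomes for planted recovery, and
150–420 kb genomes for the comparative panels — sizes at which every
class-level statistic is well populated while the whole suite runs in
minutes. All randomness flows from explicit integer seeds; pipeline
outputs pin column order, row sorting and float formatting (6 significant
digits), so identical inputs produce byte-identical TSVs and identical
SHA-256 digests in the run manifest.

## Known limitations

* Greedy unit-wise extension is not an optimal alignment; a Needleman–
  Wunsch-style banded aligner would classify some edit clusters
  differently. The greedy rule is deterministic, fast, and matches the
  seed-and-extend convention of the tool lineage this follows.
* Strand-exact coordinates for reverse-complement scans differ by
  sub-unit phase shifts (see above).
* Compartment labels are strand-agnostic positions; UTR-specific
  compartments and promoter windows are not modelled.
* The bottom-20 band of the score matrix assumes the freq ≥ 10 universe;
  with 55 or fewer surviving classes the −1 band is guarded against
  overwriting positive bands rather than being redefined.
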