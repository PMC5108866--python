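# Methods

This note records the models behind each signature, the defaults and why
they were chosen, what the synthetic data generator does and does not
emulate, and the numerical conventions that make runs reproducible.

## Sequence model and validation

Records are uppercase IUPAC nucleotide strings; `U` is mapped to `T` on
input so RNA-style FASTA files are accepted losslessly. Ambiguity codes
other than `N` are accepted and counted, and each module states its own
policy: GC computations exclude them from numerator and denominator (a
flag keeps them in the denominator instead), the CGR walk skips them
without resetting its state, FCGR drops k-mers spanning them, molecular
weight refuses them unless told to substitute the mean base weight, and
complete deletion removes any column containing one.

## Synthetic strain families

The generator emulates a family of five nearly identical ~1.5 kb 16S rDNA
fragments (GC ≈ 53–54%, pairwise identity ≥ 97%) plus one more divergent
outgroup. Model:

- The ancestor is a random permutation of **exact** target base counts.
  At 1.5 kb, i.i.d. sampling would scatter realized GC with a standard
  deviation of ~1.3 percentage points across seeds; exact-count
  construction is what keeps every family within a fraction of a point of
  the target, which the rest of the pipeline (integer GC tables, FCGR
  signatures) relies on.
- Base frequencies default to A 0.2325, C 0.2575, G 0.2775, T 0.2325:
  GC 53.5% with guanine above cytosine, the composition pattern 16S genes
  show and the one that makes the CC/GG FCGR cells the darkest. It also
  puts the mean per-site molecular weight near 327.4 Da, the band published
  strain tables exhibit.
- `divergence` is the expected pairwise substitution rate **between two
  ingroup strains**: each strain mutates independently from the ancestor at
  `divergence/2` (defaults: 0.01 ingroup, 0.03 ingroup-to-outgroup, i.e.
  ~99% and ~97% identity). Replacement bases are drawn from the stationary
  composition restricted to the other three bases, which keeps GC
  approximately stationary at these rates.
- Length variation comes from trimming the termini down to a target drawn
  from `length_range`, not from internal indels: resubmitted 16S fragments
  of one strain family differ almost entirely in read/submission
  boundaries, and internal indels at this identity level would depress
  alignment identity far below the regime being emulated. At
  `divergence=0` no trimming is applied, so ingroup records are identical.

What the generator does **not** emulate: conserved/variable region
structure along the gene (substitutions are position-independent),
sequencing error and ambiguity codes, intragenomic 16S copy variation, and
compositional biases beyond the single stationary vector. Tests passing on
these fixtures therefore demonstrate the correctness of the computations,
not the biological typicality of any particular real family.

## Composition

GC% is `100·(G+C)/(A+C+G+T)`, rounded to the nearest integer (half away
from zero) only for reporting. The sliding-window profile (default window
50 nt, step 1) is never rounded; 50 nt is short enough that a ~1.5 kb gene
shows the familiar 40–70% swing while the mean band sits at the gene's GC.
Window starts are reported 1-based.

Molecular weight uses average masses of free
2'-deoxynucleoside-5'-monophosphates (A 331.22, C 307.20, G 347.22,
T 322.21 Da) and no terminal adjustment, giving ~327.4 Da per site at this
composition; residue (water-subtracted) masses would give ~313 Da per site
and are incompatible with published per-site weights for such tables.
`calibrate_weight_table` fits the four weights plus an optional terminal
adjustment by least squares from observed (composition, weight) pairs —
note the adjustment is only identifiable when sequence lengths vary.

As a stand-in for external hybridization-style genome-distance services
(whose algorithms are unpublished), the package provides only the plain
|ΔGC| comparator `gc_difference`.

## CGR and FCGR

The chaos game starts at the centre of the unit square and moves halfway
toward the corner of each base; corners default to A=(0,0), C=(0,1),
G=(1,1), T=(1,0) and the map is configurable and stamped into every
output. After reading a k-mer the walk lands in that k-mer's depth-k
subsquare, so binning points at resolution `2^k` equals direct k-mer
counting; both routes exist and their equivalence is asserted for k ≤ 6 in
tests (exact in floating point because coordinates are dyadic). Matrix
row/column 0 sit at the A corner; renderers draw that cell bottom-left.
Default k=2 because the dinucleotide blocks (CC, GG vs AA, TT) carry the
GC-signature contrast.

## QR signatures

The payload is the versioned text format
`SEQDIGIT/1|<id>|<description>|<residues>` (separator forbidden in id and
description), which is injective and parses back to its fields. Symbols
use byte mode with the smallest sufficient version (1–40) at the chosen
error-correction level (default L, maximising capacity: 2,953 bytes at
version 40, enough for any 16S-length record in one symbol). Longer
payloads are split into fixed-header parts carrying (index, total) that
reassemble exactly in any order.

Because no QR library is part of the package's dependency set, the
symbology is implemented internally: Reed–Solomon over GF(256) (primitive
polynomial 0x11d), the published error-correction block tables, the eight
mask patterns with standard penalty selection, and BCH-protected
format/version words. Two structural safeguards apply: the block tables
are asserted at import time to tile the geometrically computed free-module
count of every version exactly, and a matrix-level decoder (format
read-back, unmasking, de-interleaving, syndrome verification, bitstream
parsing) provides the independent return path used by the round-trip
tests. The decoder verifies rather than corrects: it is meant for
losslessly stored matrices, not camera captures.

## Alignment and identity

Pairwise identity uses affine-gap global alignment (match 5, mismatch −4,
gap open 10, gap extend 0.5 — EDNAFULL-like, with a gap of length L
costing open + L·extend). Identity is reported over all alignment columns
by default; the `ungapped` mode (matches over aligned residue pairs) is the
BLAST-style reading and is the one that tracks `100·(1−divergence)` on
end-trimmed families, since all-columns identity additionally charges the
trimmed termini.

The progressive aligner builds a UPGMA guide tree on `1 − shared-4-mer
fraction` and merges profiles leaf-to-root with profile–profile
Needleman–Wunsch (linear gap cost open+extend per column at the profile
stage; the in-row recurrence is a max-plus prefix scan, so each DP row is
vectorised). This is deliberately simple: it is adequate above ~95%
identity, the regime this toolkit targets, and is cross-checked against a
production aligner in the test suite. Complete deletion then removes every
column containing a gap or non-ACGT symbol and reports the retained
1-based positions.

## Distances, NJ and bootstrap

Closed forms: p-distance; JC69 `−(3/4)ln(1−4p/3)`; K2P from transition and
transversion proportions; TN93 from A↔G, C↔T and transversion proportions
with base frequencies averaged over the pair. Any non-positive logarithm
argument raises a saturation error naming the pair — infinities are never
propagated.

The composite-likelihood variant (`mcl`) assumes all pairs share one TN93
rate matrix: base frequencies and substitution-pattern counts are pooled
over every pair, the two transition/transversion rate ratios are estimated
once by maximum likelihood on the pooled counts (likelihood evaluated
through the eigendecomposition of the rate matrix, normalised to one
expected substitution per site per unit time), and each pair then receives
a one-parameter ML distance under the shared rates. Pooling stabilises
rate estimates for small sets of near-identical sequences; in that regime
`mcl` and per-pair TN93 agree closely (asserted in tests), and per-pair
TN93 remains available as the fallback model. Distances above 5
substitutions/site are treated as saturated.

Neighbor joining is Saitou–Nei with the Studier–Keppler Q criterion.
Negative intermediate branch lengths are clamped to zero with the deficit
moved to the sister edge (their sum is preserved); ties in Q are broken by
the smallest leaf label under each candidate node, making the topology
invariant to input ordering. Bootstrap resamples columns with replacement
(single integer seed; replicate streams drawn sequentially from one
generator), rebuilds the NJ tree per replicate, and reports for each
internal edge of the point-estimate tree the percentage of successful
replicates containing the same bipartition (bipartition-based, since the
tree is unrooted). Replicates with saturated distances are dropped and
counted; more than 10% dropped is an error. Note that a family of strains
that diverged independently from one ancestor is star-like, so internal
edges of such families legitimately receive low support — high support
appears only where a genuine deep split exists.

Newick I/O stores branch lengths and integer support values as internal
node labels; parsing is delegated to dendropy.

## Ordination

PCA input is the record-by-k-mer matrix of normalised FCGR frequencies
(default k=3, 64 features; rows sum to 1). This alignment-free choice is
self-contained — no external alignment service is involved — and an
alignment-column mode can be layered on by feeding one-hot encoded MSA
columns as features. The column-centred matrix is factorised by SVD;
components are ordered by variance and each component's sign is fixed so
its largest-magnitude loading is positive, making scores reproducible.
All-identical inputs raise an error saying so rather than returning noise.

## Reporting conventions

All sequence positions in outputs are 1-based inclusive. The
machine-readable report is canonical JSON (sorted keys, floats rounded to
six significant decimals at the reporting layer only), so identical inputs
and seed give byte-identical reports. Every stage failure is recorded
under its stage name; independent stages still run.

## Problem sizes used in automated checks

The test-suite and acceptance-script simulations are sized for
single-machine runs: ~600 nt families for alignment/tree/bootstrap
exercises (200 bootstrap replicates), 250–300 nt records for the
100-symbol QR round trip, 1,000 random sequences for the CGR/FCGR
equivalence sweep, and 20 seeds/trees for calibration and NJ-consistency
checks. These sizes are choices of the package, not limits of the methods;
all defaults in the library itself remain at full scale (e.g. 1,000
bootstrap replicates).

## Known limitations

- The progressive aligner has no iterative refinement and linear gap costs
  at the profile stage; it is not intended for divergent families.
- The composite-likelihood distance assumes homogeneous rates across pairs
  and no rate variation across sites (no gamma correction).
- The QR decoder verifies, it does not error-correct.
- PCA coordinates depend on the chosen feature representation; only
  relative configuration (e.g. which strain is extreme) is meaningful.
- Published per-accession values that require the original accession
  sequences (exact GC/MW rows, identity percentages, retained-position
  count, total branch length) can only be checked once those sequences are
  supplied locally; the repository ships no third-party sequence data.
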