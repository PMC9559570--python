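# Methods

## The model

A plant chloroplast genome (plastome, cpDNA) is a circular molecule organized
as four elementary regions, `LSC-IR1-SSC-IR2`: a large single-copy region
(~80 kb in rice), a small single-copy region (~12 kb), and two inverted
repeats (~21 kb each) with IR2 the reverse complement of IR1. Intramolecular
recombination between the two IRs inverts the whole SSC, so a plant — even a
single individual — carries a mixture of the two orientation haplotypes:
SSC-F (`LSC-IR1-SSC-IR2`) and SSC-R (`LSC-IR1-ssc-IR2`, lowercase denoting
reverse complement). This frequent, reversible inversion is called *SSC
switching* (symmetric recombination). A rarer, irreversible *asymmetric*
recombination exchanges unequal segments between two molecules, producing one
molecule with a duplicated IR (a deletion `d1` from the 3' end of IR1
replaced by an insert `prefix + i1 + IR1`, where `i1` is a segment of LSC)
and a reciprocal molecule lacking one IR.

Because the IRs are near-identical, short and intermediate reads cannot phase
the SSC orientation. Long reads can: a *junction read* spans an entire IR
copy plus flanking single-copy sequence on both sides, and therefore connects
the LSC side to a specific SSC orientation. Counting junction reads by
orientation estimates the SSC-F : SSC-R mixture.

## Quadripartite partitioning (`structure`)

IR detection seeds exact k-mers (default k = 15) of the sequence against its
reverse complement on the doubled (circular) sequence. A true inverted-repeat
pair `(a, b, L)` places all of its internal seed matches on a single
anti-diagonal `C = a + b + L - 1`, so seeded anti-diagonals are scanned
exhaustively: the per-position complementarity vector is computed and the
longest window with at most `ceil(rate * L)` mismatches is extracted
(two-pointer over the mismatch cumulative sum, budgets iterated from 0 up to
`rate * n/2`). Window bounds enforce that the two copies are disjoint on the
circle with at least one base of single-copy gap on each side. Candidates are
ranked longest-first, then fewest mismatches, then smallest start offset; a
candidate whose copies are adjacent on the circle falls through to the next.
The two gaps become LSC (the longer) and SSC; equal gaps raise an
"unresolvable" error rather than guessing. Default `max_mismatch_rate` is 0
in the CLI examples here and the near-identity of real plastome IRs makes
small values (≤ 0.001) appropriate in practice.

Failure modes are structured: no pair at all → a "no-IR" error (IR-lacking
plastomes exist in nature); only self-overlapping (palindromic) matches → a
distinct diagnostic.

The canonical linearization puts the first base of LSC at offset 0 with IR1
immediately following; `rotation` records where that origin sits in the
input, and `canonicalize` is idempotent. Internally all coordinates are
0-based half-open; every report converts to 1-based inclusive and says so in
its header.

`find_hsp` (local alignment, used for recombination-site inspection and SSC
body orientation) delegates to `Bio.Align.PairwiseAligner` with match +2,
mismatch −3, and affine gaps scoring −5 for the first gap column and −2 for
each additional column (Biopython's native convention; the test oracle uses
the same convention). `N` matches nothing, implemented via an explicit ACGTN
substitution matrix. Ties among equal-scoring optima break toward the
smallest start in the first sequence, then the second, enumerating at most
256 co-optimal alignments.

## Junction-read classification (`classify`)

The built-in mapper is deliberately simple and deterministic: exact k-mer
anchors against the circularly doubled reference (both read strands; the
strand with more anchors wins), anchors clustered by circular diagonal within
a band (default 100 bp), clusters split where consecutive anchors are more
than 200 bp apart on the read (two repeat copies can share a diagonal across
an unaligned gap — without the split, a block would silently bridge the
SSC), each cluster extended outward by exact matching, and per-block identity
computed with edlib. Real PacBio alignments enter through the SAM import
path instead (pysam; primary + supplementary records merged per read and
reference, soft/hard clips excluded from the aligned fraction).

A haplotype satisfies the junction criteria iff the read aligns with
**more than 90%** of its length (strictly, reading "more than" literally),
covers **100% of IR1**, and has **≥ 200 aligned bases** flanking IR1 into
LSC and into SSC/ssc. Overhangs are measured in aligned *reference* bases
contiguous with the IR1 boundaries, so clipped bases never count as spanning
evidence. The read is labelled `forward` if only the SSC-F haplotype
satisfies the criteria, `reverse` if only SSC-R, `ambiguous` if both (such
reads are excluded from proportions — the conservative choice for a case the
classification rule does not define), `non_junction` otherwise. The rule
uses IR1 only by default; `use_ir2` extends it to the SSC-IR2-LSC junction.
The >20 kb read-length screen of the full-scale workflow is available as
`min_read_len` (`ClassifyParams.paper_preset()`), off by default at
simulation scale. Reads are counted as given — if an input FASTQ contains
multiple subreads per molecule they are counted independently.

The orientation report gives counts, proportions over classified reads, the
full-precision ratio, and a "printed-style" ratio computed from proportions
rounded to two decimals (82/99 forward/reverse → 0.45/0.55 → 0.82), plus a
Wilson score interval (statsmodels) for the forward proportion at a
configurable level (default 95%).

## Signature screening and chimera detection (`signature`)

The rice IR1-SSC junction signatures are 24-nt strings: `TGGAAAAAATCG` (IR1
3' end) followed by `GCAAATAGGAAA` (SSC-F) or `CGGAAAACCGAA` (SSC-R). Both
motifs are parameters; the defaults are rice-specific. Both strands are
scanned circularly with a mismatch budget (default 0). One motif type found
anywhere → that verdict. A coherent quadripartite genome, however,
necessarily contains *both* motifs — the F motif at the IR1-SSC junction on
one strand implies the R motif at the SSC-IR2 junction read on the other
strand — so when both types are present the verdict is read from the
presented (plus) strand: the F/R call is meaningful only relative to the LSC
orientation in which the assembly is submitted, exactly as when reading the
junction off a published linearization. Strand symmetry of the verdict
therefore holds when the motif evidence is strand-unique (motif in a
non-quadripartite context), and deliberately not for full genomes, where
reverse-complementing the assembly genuinely swaps which junction follows
the presented LSC.

Chimera calling compares the junction verdict with the SSC *body*
orientation: the assembly's SSC region is locally aligned (same scoring as
`find_hsp`, score-only) against a reference SSC of known forward orientation
and against its reverse complement; the higher score wins if it leads by at
least 10% (otherwise the body is `unknown` and no chimera is called). An
assembly is chimeric iff junction type and body orientation are both known
and disagree — the pattern of an SSC assembled from reads of both
orientation haplotypes.

## STR detection and CNV calling (`strcnv`)

Tandem repeats with unit lengths 1–6 are found by the shift-match scan
(`seq[i] == seq[i-u]` runs); a locus must contain at least 6 copies for
homopolymers and 3 for longer units, is reported at its leftmost full-unit
start (1-based), and is maximal by construction. Runs whose unit is itself
periodic are suppressed (12 A's are `[A]12`, never `[AA]6`). Units
canonicalize to the lexicographically least rotation for comparison.

Copy numbers are counted per read between *anchored flanks* — the 10
reference bases on each side of the locus located in the (reference-oriented)
read, exactly or with one edit — rather than from alignment gap placement,
which aligners shuffle freely inside homopolymers. The inter-flank segment is
counted as `len/unit` copies when it is a clean repeat, or the rounded
quotient when within 20% edit distance of one. A copy number needs support
from ≥ 3 reads (the package's choice of threshold); the supported minimum and
maximum become the locus range, `copy_min < copy_max` is a CNV call, and a
locus with no surviving observation is reported uncallable rather than
silently dropped. The machine notation flattens the subscript typography:
`11291[T]7-8`.

## Synthetic data (`simulate`)

Defaults are the study conditions at roughly 1/10 scale: regions
8,000 / 2,000 / 1,200 bp (vs 80,553 / 20,805 / 12,346), SSC-R molecule
fraction `p_reverse = 0.55` (the observed mixture), 200 molecules, 2,000
reads with lognormal lengths (median 3,000 bp, σ = 0.4), zero error rates
unless asked for, and a scaled IR-duplication geometry (d1 = 32, i1 = 200,
prefix `ATTTT`). `paper_scale_config()` switches to the real region lengths,
a 25 kb read median, and the real SV geometry (d1 = 319, i1 = 2,000).

Single-copy regions and IR1 are i.i.d. uniform ACGT; IR2 is the exact
reverse complement of IR1. Motif embedding writes the F signature across the
IR1-SSC boundary and chooses the last 12 nt of SSC so that flipping the SSC
produces the R signature at the same boundary. Planted STRs are written with
guard bases so the planted run is maximal; polymorphic planted STRs must lie
in the LSC so per-molecule copy-number edits commute with SSC flipping.
Orientation and IR duplication are independent per-molecule Bernoulli draws;
reads pick a molecule uniformly, a uniform circular start, a truncated
lognormal length, a uniform strand, then positionally uniform substitutions,
insertions, and deletions. Every generator is deterministic given a seed.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: homopolymer-biased and context-dependent PacBio
errors (the error model is positionally uniform), ZMW/subread structure and
adapters, quality values that carry information (quality strings are
constant), non-uniform genomic composition (real plastomes have skewed base
composition and gene structure), and assembly artifacts other than the
junction/body chimera explicitly constructed in tests.

## Problem sizes and numerical choices

The test suite runs everything at simulation scale: IR-detection equivalence
against the exhaustive oracle uses 1,000 random planted-IR circles ≤ 300 nt;
classification accuracy uses 2,000 error-free provenance-tracked reads; the
Wilson-coverage check uses 50 replicates of 300 reads on a 6,800 bp genome
(~30–40 junction reads per replicate, chosen from the lognormal/geometry
calculation so each replicate's interval has meaningful width); CNV recovery
uses 350–400 reads. The acceptance script detects the IR pair on a synthetic
genome at the full 134,509 bp scale and classifies 3,000 reads from a pool
of 1,000 molecules.

Degenerate inputs are handled explicitly: empty classified sets yield
undefined (None) proportions rather than exceptions; reads without anchors
yield empty alignments; `d1 = i1 = 0` with an empty prefix reduces the IR
duplication to an exact in-place duplication; `apply_ir_loss` removes IR2 (a
fixed, documented choice — which copy is lost is not observable from the
product's organization).

## Known limitations

- The built-in mapper assumes anchors every ≲200 bp; at error rates well
  above ~5% per base it will fragment alignments. Use external alignments
  via SAM import for real noisy data.
- Junction classification treats each input read independently; molecules
  sampled by several reads are counted several times.
- Signature screening with the default zero mismatch budget misses junctions
  carrying any variant within the 24-nt window; raise `max_mismatch` for
  divergent material.
- STR copy counting requires both flanks within the read; loci closer than
  the flank size to a junction or contig end are uncallable.
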