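# Methods

## The search model

A [Dn,n+1] stwintron is described by two `SpliceElementSpec`s (one per
constituent intron) and a hybrid-motif construction rule. Each element spec
holds a set of concrete 6-mer donors, a 6-character IUPAC branch-point (BP)
consensus, a 3-character IUPAC acceptor consensus, and two closed
spacer-length ranges. The compiled model is a chain of five motifs:

| # | motif          | content                                   | width ([D1,2]) |
|---|----------------|-------------------------------------------|------|
| 1 | 5′ hybrid      | external donor head (n nt) + internal donor | 7 |
| 2 | internal BP    | `DYTRAY`                                   | 6 |
| 3 | 3′ hybrid      | internal acceptor `HAG` + external donor tail | 8 |
| 4 | external BP    | `DYTRAY` (preset D: `CCTRAY`)              | 6 |
| 5 | acceptor       | `HAG`                                      | 3 |

Spacer distances count the nucleotides strictly between consecutive
elements, matching the `.{lo,hi}` runs of the rendered pattern; the stated
minimum BP-acceptor distance of 4 nt is therefore a `.{4,20}` run. The
alternative convention (counting from the branch adenosine) was rejected
because it breaks that equivalence. With preset ranges the shortest
reportable [D1,2] is 7+25+6+4+8+25+6+4+3 = 88 nt, and each constituent
intron is at least 44 nt, above the 42-nt canonical minimum.

The preset donor set contains 24 of the 64 possible `GTNNGN` hexamers —
those common among filamentous-fungal U2 donors — all starting `GT` with
`G` at position 5. Presets B, C and D each change exactly one variable of
preset A; all other variables are shared. [A2,3] geometry (external donor,
external BP, `HA`+internal donor hybrid, internal BP, internal
acceptor+`G`) is supported by the same machinery for custom models.

Subject sequences are DNA over `{A,C,G,T,N}`; `N` never matches a motif
position, and a candidate whose span contains `N` anywhere (spacers
included) is suppressed, so assembly gaps cannot produce phantom
candidates.

## Scanning modes

*Greedy* mode compiles the model into a grouped regular expression
(spacers restricted to `[ACGT]`) and reports leftmost non-overlapping
matches with greedy spacer runs — the behaviour of the conventional
pattern engines used for published whole-genome screens. *Exhaustive* mode
precomputes, per motif, the list of matching positions and joins the lists
under the spacer constraints (binary search per level), yielding every
distinct motif placement, overlaps included. Exhaustive output is verified
in the test suite against an independent brute-force enumerator that
shares no code with the scanner; greedy output is a subset of exhaustive
output by construction and by test. Minus-strand scanning operates on the
reverse complement and reports + strand genomic spans with a strand flag;
candidates found by several models are deduplicated on
(contig, strand, span) keeping all model labels.

Note that the four presets are pairwise disjoint in their single varied
variable (e.g. `DYTRAY` and `CCTRAY` share no hexamer), so one planted
stwintron cannot legitimately carry two preset labels; multi-model
deduplication is exercised with custom overlapping models.

## Splicing geometry

`splice()` removes the internal intron (validating that a donor-universe
6-mer is reconstituted at the start of the external intron), then the
external intron. The one-step mis-splice keeps the external-donor head
(the G₁ for [D1,2]) exonic, giving `len(one_step) = len(mature) + 1` and a
+1 frameshift; a split-point parameter generalises this to [D5,6]-morphed
geometry. The [A2,3] alternative reading shifts the intervening sequence
one nucleotide 3′ and exists exactly when the first downstream exonic base
is G; the implementation asserts the resulting mature mRNA is identical.

Read validation emulates a perfect-match screen of 100-nt RNA reads: a
60-nt query centred on a junction is supported when some read (either
orientation) contains, as an exact substring, the query window spanning
the junction by at least k nt on each side (k = 10 by default; the
original screens did not state a minimum, and 10 prevents one-sided
matches). No alignment is performed because only perfect matches count.

## Symmetry profiling

A stwintron able to fold into a hairpin resembles its own reverse
complement. `self_align` runs a global affine-gap pairwise alignment
(Biopython `PairwiseAligner`) of s against reverse_complement(s) and
classifies every column: identical letters are a Watson–Crick pair
(MATCH); columns (G,A) or (T,C) are wobble pairs (WOBBLE), because with
r = revcomp(s) the column (sᵢ, comp(sⱼ)) represents the fold pair sᵢ·sⱼ,
and G·U / U·G pairs surface exactly as those two letter combinations;
other mismatches are unpaired (NONE); gapped columns are GAP. Terminal gap
runs are reported as 5′/3′ overhangs. Free end gaps were deliberately not
used: they collapse random sequences to a tiny perfectly matching core
with enormous "overhangs" and a meaningless match fraction.

Because aligning s to revcomp(s) is a self-mirror problem, the mirror
image of any optimal path is itself optimal and residual asymmetry is
tie-break noise; the profile is therefore symmetrised by taking, per
column, the more conservative of the class and its mirror (rank
MATCH > WOBBLE > NONE > GAP). When no scoring is supplied, a three-point
scoring grid (match +2 throughout; mismatch −1/−1/−2 with gap open
−6/−10/−16) is run and the most parsimonious profile kept — fewest
internal gap openings, then smallest gap extent, then fewest unpaired
columns, then mildest gap-open. This grid-and-parsimony rule is this
package's explicit stand-in for a per-sequence choice among alignment
matrices; schematic profiles are therefore qualitatively, not bit-exactly,
comparable with profiles from other aligners.

Palindrome detection expands around every inter-base centre and reports
maximal even-length windows equal to their own reverse complement.
Terminal-inverted-repeat calling compares the 5′ arm with the reverse
complement of the 3′ arm, ungapped, over a window of arm lengths (default
45–55 nt) and maximises matches − mismatches with identity as tie-break,
returning no call below the identity floor (default 65%).

## Cohort statistics

AU permillage is 1000·(A+T)/length on the DNA sequence, kept unrounded
(rounding to integer permille happens only for histogram binning). The
moving average is centred with an odd window (default nine single-permille
steps); edges average over the available span, so interior bins reproduce
the exact 1/9 convolution and series ends are not padded. The
fraction-ordered AU curve applies the same smoothing to the sorted AU
values; the value at fraction 0.5 is reported alongside the arithmetic
mean because the two need not coincide.

The junction logo stacks, per stwintron, 15 nt of 5′ exon, the
concatenated five motifs (30 nt for [D1,2]) and 15 nt of 3′ exon.
Frequencies ignore the pad symbol used for contig-edge flanks shorter than
15 nt; information content is 2 − H(column) bits with no small-sample
correction by default (the correction is available behind a flag),
matching common logo-server defaults. Column 16 is the invariant G₁ and
carries 2 bits on any compliant cohort. Exon-context tallies count the
AG-upstream∧GT-downstream joint context (a pseudo AG|GT double fusion
site), TAG/CAG upstream, GT/GTA downstream and G downstream (the [A2,3]
trigger).

## Synthetic data and what it does (not) show

The generator draws i.i.d. background of configurable GC content (default
0.45, a typical value for the AT-rich intronic fraction of fungal
genomes), instantiates stwintrons uniformly from a model's element sets
and spacer ranges, and plants them at uniform non-overlapping positions on
either strand. `clean` generation rejection-samples spacer fill until the
stwintron scans to exactly one exhaustive candidate (optionally also until
named other models see nothing), with a 1000-retry cap. Reads are
error-free 100-mers drawn uniformly along an isoform in either
orientation with multinomial mixture counts. A single integer seed drives
all randomness.

Because background is i.i.d. and reads are error-free, passing tests
demonstrate the correctness of the search, splicing and statistics
machinery — not recall on real genomes, where repeats, composition bias
and sequencing error add false positives and missed junction reads.
Synthetic cohort AU values (~550‰ at GC 0.45) reflect the generator's
background, not a biological catalogue.

## Problem sizes

The default test suite scans roughly 300 kb of random sequence against
the brute-force oracle (200 sequences of 1–2 kb plus planted fixtures),
plants 24 stwintrons across the four presets for recall, and runs the
read-validation matrix over 12 genes × 4 isoform mixtures.
`scripts/acceptance.py` uses the same sizes plus a 117-record synthetic
cohort (the size of a real single-genome catalogue, with a fixed 32/53/32
phase composition emulating the observed ~45% phase-one predominance).
These sizes give stable statistics at interactive runtimes.

## Known limitations

* Greedy mode emulates a conventional engine but is not guaranteed to
  reproduce any specific third-party tool's tie-breaking on overlapping
  hits.
* Gene-context splicing is implemented for [D]-class geometry; [A2,3]
  candidates are found by the scanner, but their gene-context products are
  out of scope beyond the [D1,2]/[A2,3] equivalence check.
* The symmetry aligner's scoring grid is a pragmatic stand-in for
  per-sequence matrix selection; midpoints and gap placement can differ
  from other aligners on low-identity sequences.
* RNA secondary-structure prediction (minimum free energy, base-pair
  probabilities) is deliberately out of scope; the symmetry profile is a
  sequence-level proxy only.
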