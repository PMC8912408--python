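# Methods

This note documents the models and conventions behind each stage of
the pipeline, the parameters that matter, and what the synthetic-data
generator does and does not emulate.

## Coordinates and orientation

Internally every coordinate is 0-based, half-open; all report output is
1-based inclusive (the GenBank convention). A junction's *position* is
the first base of the downstream region, which removes the ±1 ambiguity
in distance reports; overlap extents at junctions are measured into the
IR. tRNA symbols are normalized to `trnX-ANT` (amino-acid letter plus
anticodon, U→T) and gene matching is case-insensitive, with a bare
`trnV` matching any anticodon-qualified form.

## Inverted-repeat detection

The IR pair is defined as the maximal-length pair of *disjoint,
exactly* reverse-complementary substrings of the circle, length ≥
`min_ir_length` (default 1,000 bp). Exactness is deliberate: the two IR
copies of a single assembly are identical by construction, and the
exact definition makes maximality well-defined (extending either copy
by one base breaks complementarity).

Implementation: every reverse-complement match of length L lies on one
anti-diagonal (i + j constant), so seeds (20-mers of the doubled
sequence matched against the doubled reverse complement) are grouped by
diagonal and each contiguous seed run is extended once in both
directions, with spans capped at the genome length. A diagonal can hold
several runs because the two wrapped representations of a match
crossing the origin land n apart on the same diagonal; both are
extended. Ties between equally long candidate pairs break toward the
smallest start coordinate.

The partition is canonicalized: LSC (the longer single-copy gap) starts
at 0, regions follow LSC→IRb→SSC→IRa. Between the two strand choices,
the orientation that puts the intact ycf1 copy at or near the SSC/IRa
junction is preferred when annotation is available (that is where the
gene sits in essentially all Apiaceae plastomes); otherwise the
lexicographically smaller LSC sequence decides. Degenerate inputs — no
repeat at threshold, a repeat pair tiling the whole circle, or two
equal single-copy gaps (LSC/SSC labels undefined) — raise typed errors
rather than guessing.

GC content is (G+C)/(A+C+G+T), reported to 0.1%; N is excluded from
the denominator. The gene census counts every feature instance once,
so a gene duplicated in the IR contributes two, and pseudogenes count
within their kind plus a separate protein-pseudogene tally.

## Junction typing and payload genes

For each junction the nearest feature end on either side (circular
distances), any overlapping feature with its extent, and a class label
are reported: `within:<gene>` when the junction position falls in an
exon, `within-intron:<gene>` when it falls between exon intervals of
one feature, else `between:<A>,<B>`. Payload genes are trnH/psbA copies
(full or partial) whose spans lie inside either IR copy, in genomic
order; IR symmetry guarantees each has a mirror twin at the mirrored
offset, and the test suite asserts it.

## Insertion screening

A spacer is the intergenic interval between the closest adjacent
placements of its two named flanking genes. Inside the IR a spacer
exists twice as reverse-complement mirror images; the two instances are
recognized as identical up to reverse complement and the IRb-side copy
is used. An insertion is called when the observed spacer exceeds a
baseline by ≥ `min_excess` (default 200 bp); the baseline is a number,
a reference spacer sequence, or a panel (median length; first sequence
anchors the interval). With a reference sequence, the insertion
interval is delimited by the longest exact prefix/suffix agreement;
with a purely numeric baseline it is centered in the spacer — a stated
convention, since no alignment anchor exists.

Payload fragments are found by local alignment (match +1, mismatch −1,
gap −2, both orientations) and reported when they span ≥ 50 bp at
≥ 70% identity *computed over all alignment columns, gaps included*,
and reach a minimum alignment score (default 30). The score floor is a
significance cutoff: in ~1-kb random spacers, gap-tolerant local
alignments occasionally reach 70%/50 bp by chance (observed ~1 in 10
random insertions), while their scores stay near 20; genuine payload
fragments score in the hundreds. All three thresholds are parameters.

## In-silico PCR

Primer sites are enumerated on both strands of the circle with at most
`max_mismatch` mismatches (default 1) and none in the 3′-terminal 5
bases — the anchor that real polymerases require. Every convergent
plus/minus site pair within `max_product` (default 5,000 bp) is an
amplicon; duplicate products from palindromic primer pairs are emitted
once per distinct (start, end). An empty list is a meaningful negative:
when the downstream primer's target sits on the far side of a junction
in divergent orientation, no product is possible, which is the readout
a junction-state survey relies on.

## Junction depth QC

For each junction the median depth is taken in `window`-bp regions
(default 500) left and right of a 100-bp window centered on the
junction. The junction is *drop-suspect* when the inner median falls
below `drop_threshold` (default 0.3) times the median of the flanking
windows. Medians, not means: isolated mapping spikes should not mask or
fake a dip. All-zero coverage is reported as an explicit
`zero-coverage` status instead of a ratio. The window must fit inside
the smallest region.

## Small inversions

The consensus is the strict per-column majority over unambiguous bases,
ties breaking alphabetically — a deterministic baseline. Per row,
maximal mismatch runs (gaps ≤ 3 matching columns merged) are candidate
blocks; boundaries are refined within ±3 columns to maximize the
reverse-complement advantage, and a block is reported when its
reverse-complement identity beats its forward identity by ≥ `min_gain`
points (default 20) and by ≥ 2 absolute columns. Calls shorter than 10
columns must additionally show a complementary flanking repeat of ≥ 2
bases in the carrier row: the hairpin arms that mediate these
inversions. Without that guard, clusters of 2–3 independent
substitutions mimic 3–5-bp inversions often enough to swamp precision;
with it, measured performance on planted truth (20 inversions of
3–62 bp per 8-taxon, 10-kb replicate, 20 replicates) is ≈98% recall
and ≈99.5% precision. Overlapping calls across carriers merge into one
multi-carrier record.

Correction reverse-complements each carrier's ungapped characters in
place, leaving gap columns untouched, so alignment geometry is
preserved and the operation is an involution.

`find_flanking_ir` is an exhaustive outward scan for the maximal k ≤
`max_flank` (default 200) with left flank equal to the reverse
complement of the right flank; genome-level inversion detection
compares a gene-anchored window between two genomes, takes the maximal
differing middle segment (outside the longest common prefix/suffix)
and calls an inversion when the segment matches in reverse-complement
orientation (exact equality, else a k-mer orientation vote).

## Supermatrix statistics

Masking removes columns whose gap fraction reaches the threshold
(default 0.5: a column gapped in exactly half of the rows is removed,
"less than half" retained). Site classes count only unambiguous bases;
a parsimony-informative column has ≥ 2 states each in ≥ 2 rows.

Fitch parsimony treats gap/N/ambiguity as missing (the full state
set); per-site minimum changes are (observed states − 1). CI and HI
are computed over variable sites by default; a `ci_scope="informative"`
convention (excluding parsimony-uninformative sites, as some classic
packages do) is provided because published HI values rarely state
which convention was used — neither is asserted against any external
number. Data with zero parsimony changes get CI = 1 with an explicit
degenerate flag. Trees are read as unrooted (degree-2 roots are
suppressed), so the length is invariant to rooting; polytomies beyond
the root are not resolved and binary trees are expected for sCF.

Site concordance: for an internal branch with surrounding leaf groups
A, B | C, D, quartets draw one leaf per group (exhaustive when the
universe is ≤ `n_quartets`, default 100, otherwise seeded sampling
without replacement). A site is decisive for a quartet when all four
leaves carry unambiguous bases in a 2+2 pattern supporting one of the
three quartet topologies; sCF is the mean over quartets (with ≥ 1
decisive site) of the fraction supporting the tree's own topology, and
sDF1/sDF2 the two alternatives, so sCF + sDF1 + sDF2 = 100 up to
rounding. Synapomorphies use the strict reading of a bipartition-exact
column: all non-missing taxa on one side share a state, all on the
other side share a different one, ≥ 2 non-missing per side. That
operational definition is one defensible reading of a "putative
synapomorphy" count and is labelled as such.

## Synthetic data

The generator composes a genome as LSC + IRb + SSC + revcomp(IRb) over
i.i.d. random backgrounds with configurable GC (default 37%), with a
stylized ~30-gene layout at scaled canonical positions: psbA/trnH at
the LSC start, the trnE/trnY/trnD cluster mid-LSC, ycf2 and
intron-bearing ndhB in the IR, trnV(GAC)–rrn16 with a realistic spacer,
four rRNAs per IR copy, and ycf1 crossing the SSC/IRa junction so its
mirrored overhang becomes the classical truncated copy at J_SB. Gene
lengths shrink proportionally in regions smaller than the canonical
90/18/17-kb scale so the layout never self-overlaps. Junction
maximality is enforced by breaking complementarity of the single-copy
bases facing each junction.

Events are applied in order at the blueprint level: J_LB
expansion/contraction moves sequence between LSC and IR (features fully
captured become IR-duplicated; straddling features overhang the
junction and acquire a mirrored pseudo-fragment at the opposite
junction — exactly the pseudogene pattern real junction shifts
produce); spacer insertions place payload gene copies (psbA fragment,
trnH, truncated trnV) plus random padding mid-spacer in both IR copies;
inversions write complementary hairpin arms and optionally
reverse-complement the enclosed segment, flipping contained features'
strands. Every genome ships with a truth record (realized region
lengths, census, junction overlaps, planted events) that the pipeline
itself re-verifies in tests.

Alignments evolve on a newick tree under the Jukes–Cantor process
(Poisson substitution events per branch per site, uniform root).
Planted alignment inversions overwrite the block with fresh content in
all rows (a recently inverted, locally conserved segment), rejected
until its reverse complement differs at ≥ 60% of positions and at both
boundary columns, then reverse-complement the carrier rows — this makes
planted truth intervals exact. Depth profiles are negative-binomial
(dispersion 20) around the target mean with 100–300-bp dips scaled by
`drop_factor` at chosen junctions.

What the generator does *not* emulate: real nucleotide composition and
codon structure, indel evolution, rate heterogeneity across sites or
lineages, heteroplasmy, and read-level artifacts. Passing tests
demonstrate the algorithms recover planted structure under the stated
noise models; they do not certify annotation-quality edge cases of
real GenBank records beyond the formats exercised.

## Problem sizes

The test suite and the acceptance script run at desk scale as the
package's own choice of study conditions: full-length genomes
(141–150 kb) for structural statistics, 100 random quadripartite
structures for recovery, 8 taxa × 10 kb × 20 replicates with 20
planted inversions each for the detector, 6-taxon trees for parsimony
(where exhaustive brute-force verification is feasible) and
concordance, and 100 simulated depth profiles per QC rate. The full
suite runs in well under a minute of CPU.

## Known limitations

- Only one IR pair is modelled; genomes with additional long repeats
  at the detection threshold would need the threshold raised.
- The exact-match IR definition will report a shorter IR for
  assemblies whose two copies differ by even one base (real assemblies
  normally do not, since assemblers collapse the copies).
- Insertion-interval anchoring with a numeric baseline is a centering
  convention, not an inference.
- sCF requires a binary branch neighborhood; polytomies are rejected
  rather than resolved.
- The small-inversion detector's hairpin-arm requirement for very
  short calls means a <10-bp inversion without complementary flanks
  (mechanistically unusual) would be missed.
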