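# Methods

## Model and procedure

The package designs guide siRNAs that deliberately exploit near-
complementary silencing. With candidate genes C, excluded genes E, window
length L and mismatch thresholds d_T (most mismatches a guide tolerates
to a silenced target window) and d_N (fewest mismatches required to every
window of every non-target gene), a length-L candidate subsequence r is
qualified iff each gene of its target set T holds a window within d_T of
r and every window of every other gene — candidate or excluded — is at
least d_N away. The guide siRNA is revcomp(r). The constraint L > d_N >
d_T ≥ 0 is enforced; defaults are L=21 (sufficient to trigger RNAi in
plants), d_T=4 (silencing has been demonstrated across four mismatches),
d_N=5.

The pipeline runs in fixed stages, each a single pass over a mark vector
on a neighbor graph computed once over all enumerated windows:

1. **Enumeration.** All N-free length-L windows of C, keyed by
   (gene, offset); duplicate sequences at different loci stay distinct.
2. **Graph.** Pairs at HD ≤ d_T are neighbors, at d_T < HD < d_N
   far_neighbors (boundary semantics taken literally: HD = d_T is a
   neighbor, HD = d_N is no relation). The target set of a window is its
   own gene plus its neighbors' genes.
3. **far_neighbor exam.** A window keeps its mark iff every far_neighbor's
   gene is already in its target set (silencing of a far_neighbor is not
   guaranteed, so it is acceptable only where that gene is a designed
   target anyway).
4. **Powerful-subsequence exam.** P is powerful iff
   ⋃_{v∈N(P)} N(v) ⊆ N(P) ∪ {P}. Non-powerful windows with a *marked*
   powerful neighbor are unmarked: their target sets are subsets of the
   dominator's, so no coverable gene is lost. The mark condition on the
   dominator is deliberate — a powerful window already unmarked by stage 3
   cannot stand in for the windows it dominates, and requiring it is what
   makes the union of marked target sets invariant under this stage
   (verified on every test instance).
5. **Excluded-gene hit exam.** A marked window within < d_N of any
   excluded-gene window is unmarked. Excluded windows containing N are
   scanned with N matching any base (distance contribution 0): the
   conservative reading that can only remove siRNAs, never admit one that
   might silence an excluded transcript. Candidate windows containing N
   are never enumerated at all, so an N-masked candidate region neither
   contributes designs nor joins target sets.
6. **Scoring and redundancy reduction.** Survivors are scored with the
   Reynolds rules (below); within each group sharing a target set the
   survivor is the rule-passing member (if any) with minimal HD-sum, then
   minimal maximum neighbor distance, then smallest
   (qualified_seq, gene, offset). Exactly one siRNA per distinct target
   set survives.
7. **Panel selection.** Greedy set cover over the non-redundant target
   sets: repeatedly pick the siRNA covering most uncovered genes; ties go
   to larger |T| (raises per-gene examination frequency), then higher rule
   score, smaller HD-sum, lexicographic sequence. A final pruning pass
   (reverse selection order, iterated to a fixed point) removes picks
   whose targets ended up covered by the rest, so every panel member is
   essential. Selection is fully deterministic.
8. **Screen planning.** Round 1 runs one pooled experiment per panel
   siRNA. Because either duplex strand can load into RISC, each pool also
   records X_i — genes (candidate or excluded) holding a window within
   d_T of the second strand's complement, i.e. of the guide's own letter
   sequence. A positive pool sends T_i ∪ X_i to round 2, where each gene
   gets a specific siRNA (targets exactly that gene, no outside
   second-strand hits); when none exists the plan emits an explicit
   failure record with the least-off-target alternative, or none at all
   for genes (e.g. excluded transcripts hit via X_i) that no qualified
   siRNA can target — those require manual design.

### Strand logic for X_i

A strand loaded as guide silences transcripts complementary to it. The
duplex's second strand is the qualified (sense) sequence itself, so its
potential targets contain windows near revcomp(sense) — textually the
guide sequence. This complementarity-consistent scan is the default; the
literal alternative (scanning with the sense letters) is available via
`literal=True`.

## Numerical implementation

Windows are 2-bit packed into one `uint64` (L ≤ 32); Hamming distances
are XOR → fold to one indicator bit per base → popcount, vectorised and
chunked so memory stays bounded. The search is exact — no seeding or
filtering heuristics — and the test suite checks it against naive
byte-by-byte all-pairs comparison on 1,000-window instances. Wildcard-N
scanning masks the indicator bits of N positions. The brute-force oracle
(`fixtures.oracle_qualified`) evaluates the definition directly via
per-gene minimum distances over unpacked byte arrays, a structurally
independent route from the graph pipeline it validates; it refuses
instances above ~6,000 candidate windows.

## Design-rule scoring

The Reynolds et al. (2004) rational-design score is computed on the
19-nt scoring frame taken as the first 19 nt of the sense window (the
rules were defined for 19-mer duplexes; the frame convention is fixed and
documented rather than tuned). Criteria: GC 30–52 % (+1); each A/T at
sense positions 15–19 (+1); no internal repeat (+1); A19 (+1); A3 (+1);
T10 (+1); G/C at 19 (−1); G13 (−1); pass at score ≥ 6 (the published
cutoff). The internal-repeat criterion (originally Tm < 20 °C for the
hairpin) is approximated as the absence of any ≥5-nt self-complementary
stretch within the 19-mer, avoiding a thermodynamics dependency. Windows
shorter than 19 nt disable rule scoring (all pass, with a warning).
Hsieh and Takasaki rule sets are registered names that raise an explicit
unsupported-option error; their published descriptions do not pin an
implementable scoring function.

## Pre-filters on real sequence sets

`seqio` reproduces the standard EST-library clean-up: candidate pairs
whose best local alignment has match ratio > 0.95 AND coverage ratio
> 0.85 lose the shorter member (equal lengths: lexicographically later
id); excluded records with coverage ratio > 0.85 OR overlapping ratio
> 0.90 against any candidate are dropped. Alignments use match +1,
mismatch −1, gap −2 (Bio.Align.PairwiseAligner, local mode); the
alignment span — identities + mismatches + internal gaps — is the
denominator of the match ratio and the numerator of the coverage
(÷ longer) and overlapping (÷ shorter) ratios. Published analyses of this
kind used BLAST, whose ratios depend on version and parameters; the
ratios, not the engine, are the specification, so exact reproduction of a
particular historical record count is not guaranteed. All pair decisions
are computed on the full input pair set, making the filters idempotent
and order-insensitive up to the stated tie-break.

## Synthetic study conditions

The generator emulates what makes multi-target design non-trivial in a
real transcript library: subfamilies sharing a conserved ~21-nt footprint
(within d_T of each other, creating multi-target siRNAs), unrelated
uniform-random background, and decoy copies of a planted motif inside
excluded genes at < d_N (excluded-gene hits). Defaults — fixed once as
the package's study conditions — are 15 candidate + 15 excluded genes of
350 nt (≈4,950 candidate windows, inside the oracle's brute-force range),
four 3-member families at 2 planted mismatches, one decoy family at
distance 4, N rate 0. Base composition is uniform; a GC-bias knob is
deliberately absent from the defaults because Reynolds scoring is
GC-sensitive and biased fixtures would entangle two effects.

What the generator does **not** emulate: EST sequencing error profiles,
transcript isoforms, realistic codon/GC structure, paralog families with
indel divergence (family members differ by substitutions only), or
expression-level effects on silencing. Passing tests therefore show the
algorithmic properties — soundness against the definition, exact
neighbor search, coverage preservation, deterministic selection, pooled-
screen decodability — not wet-lab silencing efficacy on any real library.

## Degenerate inputs and tie-breaks

Genes shorter than L are retained but yield no windows; an empty
excluded set disables stage 5; an empty qualified set yields an
all-uncovered panel with a warning rather than an error. Every ordering
ambiguity (dedupe ties, redundancy-group ties, greedy ties) is resolved
by an explicit documented chain ending in a lexicographic key, so reruns
are byte-identical and input permutation cannot change any retained-id
set.

## Known limitations

* Thresholded Hamming distance is a coarse proxy for silencing
  efficacy; thermodynamics, position-specific mismatch effects and
  target-site accessibility are out of scope.
* The greedy tie-break chain operationalises the stated goal of raising
  examination frequency; other frequency-raising modifications of greedy
  set cover exist and may select different (equally covering) panels.
* Round-2 specific siRNAs are drawn from the qualified set only;
  hand-designed hairpins for genes without one are left to the user.
* The brute-force oracle, and hence the soundness checks, are limited to
  desk-scale instances (≈6,000 candidate windows).
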