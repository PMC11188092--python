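# Methods

This note documents the models and algorithms behind `polswap`, the choices
made where the design was genuinely open, and what the synthetic-data
validation does and does not demonstrate.

## ORF complement

Each genome is scanned in all six frames for ATG-initiated, stop-terminated
open reading frames of at least 75 nt, with the stop codon included in the
interval. ORFfinder-style "non-nested" filtering removes any ORF whose
genomic interval is strictly contained in a longer retained ORF's interval,
on either strand; length ties keep the lower start coordinate, and the
filter is a fixed point (re-running it changes nothing). ORFs never wrap
around the genome end, alternative start codons (GTG/TTG) are not used, and
only the standard genetic code is supported; codons containing N translate
to X. Internally all coordinates are 0-based half-open; GFF3 output is
1-based inclusive.

## Pairwise protein alignment and statistics

Homology search uses local Smith–Waterman alignment with BLOSUM62 and
affine gaps, a gap of length k costing 11 + k (the BLAST gap convention).
The all-vs-all best-hit searches use a numba-compiled score-only kernel;
full alignments of the retained pairs (for coverage and identity) go
through Biopython's `PairwiseAligner` configured with identical scoring, so
both routes return the same optimal score (asserted in the tests against an
independent quadratic-time DP implementation).

Raw scores are converted to bit scores with the gapped BLOSUM62 constants
λ = 0.267, K = 0.041, and to E-values with a search space of
(number of subjects) × (mean subject length) × (query length) — a monotone
surrogate for the BLAST search space adequate for thresholding at
E ≤ 1e-4.

Optionally, candidate subject sets can be restricted to those sharing at
least `prefilter_min_kmers` amino-acid 4-mers with the query (the pipeline
default is 3), analogous to BLAST's word seeding. At the divergences the
pipeline targets (≤ ~60% amino-acid distance) true homologs share dozens of
4-mers, so the filter is effectively lossless there while skipping ~95% of
unrelated pairs; the exhaustive mode remains the library default and is
what the oracle tests exercise.

## RBH genome distance

For each genome pair, reciprocal best hits are computed between the two ORF
complements: (x, y) is an RBH iff y is x's unique best bit-score hit and
vice versa (score ties broken by lexicographically lower subject id), and
both directional hits have E ≤ 1e-4 and ≥ 50% query coverage (coverage in
each direction independently, measured as aligned residue columns over
query length). The distance is

    D(A,B) = 1 − (C_AB + C_BA) / (L_A + L_B)

with C_AB the union length (overlaps counted once) of A's RBH-participating
ORF intervals. D is clamped to [0, 1] and the matrix diagonal is fixed at 0:
applied to (A, A) the formula would return the intergenic fraction of the
genome, which is clearly not the intent of a self-distance. Note that D
carries a floor equal to the intergenic fraction even for identical
genomes, which is why the genus-level cut at 0.15 corresponds to quite
similar genomes.

## Genome tree

The tree is built by canonical Saitou–Nei neighbor joining (Q criterion,
negative branch estimates clamped to zero, Q ties broken by the lowest
(i, j) index pair; the Q matrix is symmetrized before the arg-min to guard
against floating-point asymmetry in the row sums). NJ is exact on additive
matrices, which the tests verify on randomly generated trees. Balanced
minimum evolution would be an alternative; at the scales this package
targets the downstream decomposition and swap logic only require a
reasonable additive-tree estimate, and NJ is fully specified and
deterministic.

The unrooted NJ tree is midpoint-rooted (ties between equally long
leaf-to-leaf paths broken by the lexicographically smallest leaf pair) and
then made exactly ultrametric in a single descent: with m(v) the mean path
length from node v to its descendant leaves, the root is assigned height
H = m(root), and each child c with original branch b gets height
H(v)·m(c)/(b + m(c)) (zero for leaves, and zero when b + m(c) = 0) and new
branch H(v) − H(c). This "iterative subtree balancing" preserves topology,
yields max−min leaf depth at machine precision, and keeps the total depth
equal to the mean original root-to-leaf depth; an already-ultrametric tree
is a fixed point.

## Subtree decomposition and swap clades

The ultrametric tree is cut at height 0.15 (≈ genus level, and roughly one
third of the total tree depth in the data regime this method targets):
subtree roots are exactly the nodes with height ≤ 0.15 whose parent is
higher. A subtree is heterogeneous either as type (i), "swap" — at least
two single-DNAP genomes carrying at least two distinct families — or type
(ii), "co-occurrence" — a genome encoding two or more DNAPs of different
families. From each heterogeneous subtree the tree is ascended while the
parent stays below `clade_max_depth` (default 0.45 ≈ total depth) and the
sister subtrees contain at least one DNAP-encoding genome; overlapping
ascents merge into maximal, pairwise-disjoint swap clades.

## DNAP annotation

Family and clade labels are transferred from the best-scoring labeled
reference with E ≤ 1e-4 (ties to the lower reference id). This replaces a
clustering/profile-chaining pipeline that is tool glue around reference
curation: the swap logic itself only needs per-protein family/clade labels,
and externally produced call tables can be supplied to the `detect-swaps`
command instead. Catalytic motifs are screened through the
query-to-reference alignment: a motif is intact when every motif position
aligns to the required residue class (exact residue by default,
configurable classes), degraded when any aligned position mismatches, and
absent when positions fall in gaps or outside the aligned span (mismatch
takes precedence over absence when both occur). The optional "active"
filter retains calls with all Pol motifs intact and ≥ 80% reference
coverage; the pipeline reports motif status but does not drop calls, since
on divergent true polymerases motif-position misalignment would silently
remove genuine DNAPs.

## Parsimony swap inference

Leaf states are composite (family, clade) labels of single-DNAP genomes;
genomes without a DNAP are pruned from the clade tree by default (treating
absence as an explicit state is possible but conflates gene loss with the
replacement process being counted). Sankoff dynamic programming with unit
change cost (inter- and intra-family costs separately configurable) yields
the minimum number of replacement events; backtracking prefers the parent's
state and then lexicographic order, so the reported edge assignment is
deterministic. Events are classified inter-family when the family changes
and intra-family when only the clade changes. Direction is not asserted:
without a supplied root state the events are one minimum-change assignment,
not a claim about which family is ancestral.

## AU topology test

Site log-likelihoods are computed by Felsenstein pruning under an F81-type
20-state model: P_ij(t) = e^(−βt) δ_ij + (1 − e^(−βt)) π_j with
β = 1/(1 − Σπ_k²), π estimated from observed alignment frequencies (with a
pseudocount), gaps and X treated as missing data, and site likelihoods
floored at ln ≈ −745 against underflow. The model has closed-form
transition probabilities and needs no eigendecomposition; it is deliberately
simpler than the rate-heterogeneous models a maximum-likelihood package
would select, and externally computed site-likelihood matrices (TSV) can be
supplied instead.

Branch lengths come from model-corrected pairwise distances
t = −ln(1 − p/b)/β (b = 1 − Σπ², saturated pairs capped), and the
constrained topology from group-wise NJ: each constraint group is resolved
by NJ on its sub-matrix, rooted at its attachment point (located by
including a pseudo-outgroup leaf whose distance to each group member is the
mean distance to all non-group taxa — on additive input this recovers the
exact rooted subtree), and the groups are joined by NJ on between-group
mean distances. When the constrained and unconstrained unrooted topologies
coincide the identical tree is used for both, making the comparison an
exact tie.

The AU p-values follow the multiscale RELL bootstrap: at scale factors
r ∈ {0.5, …, 1.4}, ⌈rn⌉ sites are resampled B = 10,000 times; each
replicate awards one unit split equally among the arg-max topologies;
bp values are clipped to [1/(B+1), 1 − 1/(B+1)] and Φ⁻¹(1 − bp) is
regressed on d√r + c/√r by weighted least squares with binomial variance
weights propagated through the quantile transform; p_AU = 1 − Φ(d − c).
Degenerate topologies (bp 0 or 1 at every scale) short-circuit to the
corresponding clipped extreme. The procedure is bit-reproducible given the
seed.

## ANI

OrthoANI-style reciprocal fragments: genomes are split into consecutive
1000-nt fragments (trailing remainder discarded), each fragment is placed
on the other genome on both strands — candidate window by shared 11-mer
diagonal voting, then local alignment (match +1, mismatch −1, gap of length
k costing 5 + 2k) within the window — and retained at identity ≥ 0.7 over
≥ 70% of its length. Fragments are paired by reciprocal best placement and
ANI is 100 × the mean identity over reciprocal pairs, averaged over both
directions. Pairs with no retained fragments are flagged below detection
rather than given a number. Fragment-based ANI implementations agree with
each other only to within about a percentage point, which is the tolerance
used when comparing against published values.

## Synthetic clades

The generator produces the data regime the pipeline assumes, with full
determinism from one seed (independent substreams for tree, donor pool,
event placement, evolution, and emission):

- **Tree**: Yule (unit birth rate) to n leaves, rescaled so every
  root-to-leaf depth equals `tree_height` exactly. Defaults: 20 genomes,
  height 0.25 amino-acid substitutions per site (within the ~0–60%
  divergence span the method targets).
- **Genes**: 30 genes of 120–300 aa (gene 0 is a structural marker in the
  TerL role, never swapped; a 5-gene replication block sits mid-genome and
  contains exactly one DNAP of 350 aa), intergenic spacers of 60–150 nt.
  Ancestral sequences are i.i.d. from an average protein composition;
  evolution is the same F81 process the likelihood machinery uses, applied
  site-independently (first-position M and DNAP catalytic motif positions
  held invariant, as catalytic residues are in real polymerases).
- **Donors**: per-family random DNAP ancestors (families are mutually
  unrelated), with two clades per family at ~15% divergence from the family
  ancestor. The donor originals are emitted as the labeled reference set
  together with their motif tables.
- **Swaps**: each planted event replaces, below a chosen edge, the DNAP
  (and in en-bloc mode the next k = 2 replication-block genes) with a
  donor-derived sequence evolved down the remaining subtree; gene order and
  count never change. Randomly sampled events are pairwise disjoint, leave
  at least a third of the leaves ancestral, and carry distinct donor
  (family, clade) states — under which the planted event count provably
  equals the parsimony minimum on the true tree, making recovery testable.
- **Emission**: proteins are back-translated with uniform random synonymous
  codons (ATG…TAA), spacers carry a 12-nt cassette (`TTAATTAATTAA`, its own
  reverse complement) at both ends providing stop codons in all six frames,
  so no spurious ORF can span a gene boundary and `find_orfs` recovers
  every planted protein exactly.

What the generator does **not** emulate: nucleotide-level realism
(independent random synonymous codons destroy the high ANI of real close
pairs — simulated siblings sit near ~73% ANI where real swap pairs reach
93–99%), indels and alignment uncertainty, gene gain/loss or rearrangement
other than the planted swaps, codon usage, real polymerase sequence
structure, and genomes at the 40–190 kb scale (simulated genomes are
~20–25 kb; the pipeline is size-agnostic). Passing the end-to-end tests
therefore demonstrates the correctness of the machinery under the model's
assumptions, not performance on real sequence data.

## Problem sizes and calibration of the validation suite

The test and acceptance runs use: 20 end-to-end replicates at 20 genomes ×
30 genes with 1–3 mixed-mode swaps; 100 random 8-leaf additive matrices for
NJ; 50 random trees each for ultrametrization and depth cutting; 200
random ≤ 8-leaf instances against exhaustive Sankoff enumeration; AU
calibration at B = 10,000 with a tie case and a uniform-dominance case, and
20 strong-signal clades (12 genomes, TerL-sized 350–550 aa marker, height
0.3, two same-family donor clades planted on well-separated edges so the
family is genuinely polyphyletic) for the constrained-rejection check; and
20-kb genomes for the ANI expectations. End-to-end replicates succeed when
every genome's (family, clade) call matches the planted truth and the
parsimony minimum equals the planted event count.

## Known limitations

- The en-bloc swap footprint (three genes) measurably inflates the RBH
  distance between swapped and unswapped siblings; with few genes per
  genome (≲ 15) this can split a swapped subclade out of its parent
  subtree at the 0.15 cut and hide the heterogeneity. At the default 30
  genes the footprint is ~10% and detection is reliable.
- The E-value calibration is a surrogate; absolute E-values differ from
  BLAST's, though thresholding behavior at 1e-4 is equivalent in practice.
- The AU implementation reproduces qualitative rejection behavior; its
  p-values are not numerically comparable to those of likelihood packages
  with richer substitution models.
- `constrained_nj` guarantees group monophyly and exactness on
  constraint-compatible additive input, but is a heuristic (not a
  constrained ML search) when the constraint conflicts with the data.
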