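# Methods

## Scope

`thengine` operationalizes taxa as datasets: an individual is a sequence or
specimen record with a persistent identifier (PID), an identification
history, and an optional type-specimen flag; a species hypothesis (SH) is a
set of individuals delimited at an explicit distance threshold; a taxon
hypothesis (TH) is any higher-rank pooling of such sets. The package covers
quality filtering by ambiguity content, distance computation, delimitation,
name assignment, backbone attachment, TH construction, identifier
registration across releases, and checklist/FASTA export. It does *not*
cover marker extraction (ITSx), chimera screening, or multiple alignment;
inputs are assumed to be clean, comparable marker sequences or a
precomputed distance matrix.

## Distances

`pairwise_distance` performs a global alignment (Needleman–Wunsch as
implemented by Biopython's `PairwiseAligner`) with match +1, mismatch −1,
linear gap −1. Identity is the fraction of exactly matching columns over
all columns after discarding terminal-gap columns; internal gap columns
count as mismatches, and ambiguity codes (N, R, Y, …) never match — not
even against themselves — so the ambiguity filter upstream stays
meaningful. The distance is `100 × (1 − identity)`, rounded to 4 decimals.

Percent-identity tools differ in exactly these conventions (coverage
requirements, gap and end treatment), and no single published definition is
canonical; the convention above is the simplest deterministic, global,
alignment-based reading, and it is documented rather than configurable.
Two numerical choices stabilize it: the two input sequences are put in
lexicographic order before aligning, so the first-reported optimal
traceback — the canonical alignment — is the same regardless of argument
order; and thresholds compare with an absolute tolerance of 1e-9 so that
boundary distances (exactly 1.5 at threshold 1.5) are inclusive regardless
of floating-point representation.

All delimitation operations accept a distance matrix directly
(`skbio.DistanceMatrix`: symmetric, zero-diagonal, id-labelled), because
the worked examples that define correct behavior are stated as distances,
not sequences.

## Delimitation

* **Ambiguity filter**: sequences with more than six ambiguous nucleotides
  (any non-ACGT IUPAC symbol, case-insensitive) are excluded. Six is the
  established cutoff for ITS reference-data cleaning; it is the
  `max_ambiguous` default and adjustable.
* **Pre-clustering** (optional, for sequence-scale inputs): a greedy
  centroid pass at 20% distance (80% similarity) — pids visited by
  decreasing length then pid, each joining the first centroid within
  threshold or opening a new one — yields compound clusters inside which
  fine delimitation runs independently. This is a scaling device; because
  linkage never crosses compound boundaries, a pair of individuals within
  3% of each other but assigned to different compounds would be separated.
  That approximation is inherited from the greedy pass and is the reason
  pre-clustering is off by default for matrix inputs.
* **Single linkage**: two individuals share an SH iff connected by a path
  whose every edge is ≤ the threshold (computed as connected components of
  the thresholded adjacency via `scipy.sparse.csgraph`). Single linkage is
  the semantics of blastclust-style clustering and is what makes the
  chaining behavior in the worked examples possible. It also guarantees
  *refinement monotonicity*: partitions at a lower threshold refine
  partitions at any higher threshold, which the OTU-ladder nesting relies
  on. The default grid is {0.5, 1.0, 1.5, 2.0, 2.5, 3.0}%.
* **Statistics**: intraspecific variation is the maximum pairwise distance
  within an SH (0 for singletons); the reference individual is the medoid
  (minimum eccentricity, ties broken by longest sequence then smallest
  pid). The medoid rule is a package choice — upstream practice does not
  publish a selection rule — and is deterministic by construction.

## Naming

The cascade, in order: a single type specimen fixes the name; several types
with distinct names resolve by earliest publication year (a deliberately
simple, pluggable proxy for nomenclatural priority — the codes' actual
rules need human judgement); otherwise a single uncontradicted species
binomial among the members' *effective identifications* is adopted. The
effective identification of an individual is its latest-dated one (ties:
expert determination beats sequence annotation beats automated; residual
ties keep the last listed) — re-identification supersedes the old name.
"Genus sp." determinations do not contradict a binomial of the same genus.
Conflicting binomials fall through to the optional consensus branch (modal
species name at or above a configured fraction, 0.8 in BIN-style use; a
modal tie means no consensus) and then to the lowest rank at which all
effective identifications agree — the shared genus token without a
backbone, or any rank via backbone lineages with one. SHs that fail every
branch stay unnamed and are communicable by PID only.

Consensus is off by default: reference-dataset naming prefers escalating
to a higher rank over majority-voting away a minority determination.

## Backbone, THs, identifiers

The backbone is a single-rooted tree of (name, rank) nodes with strictly
decreasing rank resolution toward the root; rank gaps (family → species)
are legal. Named SHs attach to the node carrying their (name, rank) as
unranked children. Homonyms are disambiguated by the members' higher-rank
identifications and otherwise left unplaced — never guessed. Backbone THs
are emitted for every occupied node above species rank, each pooling every
individual of every SH attached in its subtree; species-level datasets are
the SHs themselves. OTU-ladder THs are single-linkage partitions at
strictly increasing thresholds with nesting references; binding a level to
a rank is an annotation recorded in an audit list, last binding wins.

Dataset identity is (SHA-256 of newline-joined sorted member pids,
delimitation descriptor). Same members at a new threshold → new accession;
unchanged pair → same serial in every release, new release suffix
(`.01RE`-style, configurable). Serials are never reused; releases form an
append-only lineage; classification links are annotations, not identity
(one TH keeps one PID across many classifications). `diff_releases`
classifies dataset fates between releases (unchanged / split / merged /
new / retired) by strict member-set coverage. DOI-like URIs are locally
constructed under a configurable resolver prefix; actual DOI minting is
out of scope.

## Synthetic data

The canonical fixtures are **capped line metrics**: individuals at real
coordinates with `d(i,j) = min(|x_i − x_j|, cap)`. This is the simplest
geometry realizing every constraint the worked examples print, and it is a
true metric (triangle inequality asserted exhaustively at instantiation).

* Four-individual fixture: coordinates 0 / 1.6 / 3.0 / 4.7, cap 2.6 —
  adjacent distances 1.6, 1.4, 1.7, everything else 2.6; delimits to
  4 / 3 / 1 SHs at thresholds 1.0 / 1.5 / 2.0 with variations 0 / 1.4 / 2.6.
* Thirty-two-individual fixture: group a (12 individuals) spans [0, 2.6]
  with adjacent gaps ≤ 0.25, group b (12) spans [3.7, 4.9], group c (8)
  spans [−3.6, −1.7], cap 5.2. Closest approaches: a–b 1.1, a–c 1.7.
  Delimits to 3 / 2 / 1 SHs with variations (2.6) / (4.9, 1.9) / (5.2).
  The captions constrain but do not fully determine the matrix; these
  coordinates are one documented choice, and every printed constraint is
  verified by an independent BFS oracle in the tests.

`realize_sequences` converts a small matrix into equal-length DNA whose
alignment distances reproduce it *exactly*: each alignment column gets a
pattern (a partition of the individuals into ≤4 blocks, one base per
block), a column contributes a mismatch to exactly the pairs its pattern
separates, and the integer column counts per pattern are solved exactly by
an integer linear program (`scipy.optimize.milp`) over all patterns. The
remaining columns share a seeded random background and column order is
shuffled. The output is verified through the alignment pipeline and
returned only on exact agreement; an unrealizable matrix (or one whose
mismatch counts `d × L / 100` are not integral) fails loudly. The pattern
space grows like the Bell numbers, so realization is capped at 8
individuals — fixture-scale by design.

`simulate_community` plants `k` groups of `n_per` individuals on a line
with within-group spans ≤ `intra_max` and between-group gaps ≥
`inter_min`; any threshold strictly between the two recovers the planted
partition exactly, which is the basis of the parameter-recovery tests.
All randomness flows through one seeded `numpy` generator.

What the generator does *not* emulate: real ITS evolution (indels, rate
heterogeneity, intragenomic variation), chimeras, length variation, or
non-metric distance noise. Passing tests therefore demonstrate the
correctness of the delimitation/naming/registry machinery under controlled
geometry, not robustness to sequencing artifacts.

## Problem sizes and determinism

Tests run fixtures of 4–32 individuals, 200 random matrices up to n = 30
for the linkage-vs-BFS oracle, communities up to k = 5 groups, and
1000-bp sequence realizations; the whole suite completes in a few seconds.
Every stochastic component is seeded (hypothesis profiles included), and
the registry accepts an injectable clock so that identical pipelines
produce byte-identical persisted tables.

## Known limitations

* The identity convention is one defensible reading, not a reimplementation
  of any specific clustering tool's internals; absolute distances from
  other tools may differ near coverage/gap edge cases.
* Pre-clustering can split near-threshold pairs across compound clusters
  (documented approximation; off by default for matrices).
* Name matching is exact after whitespace normalization — no synonymy,
  orthographic variants, or author strings.
* Type priority by publication year is a proxy; real nomenclatural
  priority has exceptions (conservation, sanctioning) that need curation.
* One backbone per attachment run; multiple classifications are supported
  via `classification_id` annotations, not simultaneous multi-backbone
  reconciliation.
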