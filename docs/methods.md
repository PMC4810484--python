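# Methods

This note documents the models, numerical choices and limitations behind
steromine's stages, in the order the pipeline runs them.

## Sequence alignment and E-values

Local alignment is exact affine-gap Smith–Waterman over BLOSUM62 (taken from
biopython) with the BLAST default penalties: gap open 11, extend 1, so a
length-k gap costs 11 + k.  There is no heuristic seeding; the DP optimum
defines correctness (a shared-word count prefilter exists only inside the
greedy clusterer, where it can only skip comparisons that provably cannot
reach the identity threshold).  The ambiguity letter X scores 0 against
everything and never counts as an identity.

Two identity conventions coexist deliberately:

* **alignment-length identity** (identical pairs / aligned columns, gaps in
  the denominator) for every BLAST-like filter and for identity matrices;
* **short-sequence identity** (identical pairs / length of the shorter
  sequence) for greedy-clustering decisions, matching the convention of the
  reference clustering tool.

E-values use the Karlin–Altschul form E = K·m·n·exp(−λS).  λ and K are
fitted by `calibrate_karlin_altschul`: Smith–Waterman scores of seeded
random background-composition pairs, with a linear fit of log survival
against score over the upper tail.  The shipped constants
(λ = 0.2777, K = 0.0963; 20,000 pairs of length 120, seed 2026) parameterize
*this implementation's* score scale.  They are close to, but not identical
with, published gapped-BLOSUM62 constants, so thresholds such as 10⁻³⁰ and
10⁻²⁵ are interpreted on the package's own calibrated scale.  All thresholds
are config entries and echoed into every run report.

## Sequence evolution model

Divergence is simulated with a reversible amino-acid Markov process whose
exchangeabilities invert the BLOSUM62 half-bit log-odds
(q_ab ∝ p_a·p_b·2^(s_ab/2), Robinson–Robinson background), normalized to one
expected substitution per site per unit time.  This keeps simulated
divergence commensurate with the scoring matrix used downstream.  Indels are
Poisson events (default 0.02 per site per unit time) with geometric lengths
(mean 3); insertions draw from the background.

To hit a target percent identity the generator solves for the branch length
whose expected diagonal transition probability matches the target (with a
first-order correction for identity lost to gap columns), then verifies by
global re-alignment and redraws up to 20 times, adjusting the time
multiplicatively.  Across 100 draws per target the mean realized identity
sits within 0.03 of targets from 0.3 to 0.9 (asserted in the suite).  The
per-site transition matrix is computed from a cached symmetric
eigendecomposition, so tree-scale simulation stays cheap.

## Synthetic communities

The generator emulates the study population rather than any real genome
set; no divergence statistics were available for the original genomes, so
the following are calibration choices, fixed once:

* **Panel**: 8 core enzyme groups (KstD, KshA, HsaA, HsaC, HsaD, HsaE,
  HsaF, HsaG; KshA and HsaC mandatory) in three pathway templates, each
  template copy diverged to ~0.62 identity from an unobserved group
  ancestor — giving ~0.40–0.45 between-template identity: above the 25%
  orthology filter, around the 30% binning filter (so a group bins into one
  or occasionally a few components, each still anchored by seed proteins),
  and below the 50% subclustering threshold, so subclustering splits groups
  by template (typically 3 subclusters per group, within the expected 1–5).  Each template adds 5
  template-specific accessory genes (3 flagged side-chain), which is what
  makes 70% panel coverage discriminate pathways: the right template covers
  at ~1.0, a wrong one at ~8/13 ≈ 0.62.
* **Genomes**: genes are non-overlapping intervals on circular replicons
  with geometric intergenic gaps (mean 120 units, gene span 3·length+3);
  decoys are background-composition proteins of length 100–260 (500 per
  genome under study conditions) plus 5 near-decoys evolved to 10–20%
  identity, which exercise the E-value/identity filters near their decision
  boundary.  At most 5 near-decoys per genome also bounds, by construction,
  the worst-case number of enzyme groups a non-degrader could ever hit below
  the 6-group rule.
* **Species history**: an ultrametric depth-1 tree (random by default; a
  deterministic balanced variant is used where analyses need guaranteed
  internal-branch lengths).  Pathway genes evolve along this tree with a
  per-pathway rate scale chosen so leaf-to-reference identity lands mid
  target range (default 0.5–0.7); the 16S-like marker (600 residues in the
  protein alphabet — no nucleotide model is simulated) evolves slowly
  (0.12 substitutions per unit depth).  Horizontal transfer replaces the
  recipient's pathway genes with near-copies (97% identity) of the donor's
  leaf sequences; marker genes draw from streams that HGT configuration
  cannot touch, making marker invariance structural.
* **Randomness** is organized as named `SeedSequence` streams (panel, tree,
  degrader designation, evolution, marker, HGT, per-genome), so changing one
  aspect of a configuration perturbs only the outputs it should.

What passing tests on these communities do **not** show: performance on real
proteomes with domain architecture variation, paralog expansions, fragmented
assemblies, or contamination; the decoys are compositionally random, so real
remote homologs are harder negatives than anything simulated here.

## Profile HMMs

Architecture is Plan7-like with local alignment in both model and sequence:
entry B→M_k with probability 2(M−k+1)/(M(M+1)), exit M_k→E with probability
1/(M−k+1) (remaining mass scales the learned M→{M,I,D} transitions), insert
emissions equal the background, and residues outside the aligned span are
emitted by the null, so flanks carry no transition cost.  Match states are
alignment columns with gap fraction < 0.5; emissions get
background-proportional pseudocounts with total weight 20/(rows+20) —
subclusters can be small, so smoothing is deliberately strong; transitions
are counted from per-row state paths with Laplace (+1) smoothing (deletions
immediately following an insert run are folded into the I→M move; there is
no I→D/D→I transition).  Scores are all-path (forward) log₂-odds, computed
in scaled linear space; a Viterbi variant exists for diagnostics and the
forward ≥ Viterbi property is asserted.  The forward recursion is verified
against exhaustive path enumeration to 1e-10 relative error.

Per-model E-values come from a Gumbel fit (scipy maximum likelihood) to
forward scores of ≥1000 random sequences with lengths uniform in 100–400;
E(s, N) = N·sf(s) for a database of N sequences.  The 10⁻²⁵ screening
threshold sits ~100 bits above the null mode, far below any true hit
(family members at 40–70% identity score hundreds of bits) and far above
anything reachable by the random or near-decoy proteins, which is why the
false-positive budget test (≤ 1 hit in 500 decoys) holds with slack.  The
fit extrapolates the tail well beyond the sampled range; this is acceptable
here because decisions are made deep in the regime where true and null
scores are separated by a large gap, not near the fitted boundary.

## Orthology and classification

Reciprocal best hits: the forward search is thresholded by mode (expansion
E ≤ 10⁻³⁰; confirmation E ≤ 10⁻²⁵; identity ≥ 25% in both), the back search
runs unthresholded against the complete reference proteome (panel plus
background proteins) and must return the originating reference — this is
what rejects out-paralogs.  Ties anywhere resolve by higher raw score, then
lexicographic id, for determinism.  Several references may map to one
target; such collisions are reported, not suppressed.

The degrader rule is read inclusively: ≥ 6 of 8 groups present *and* both
mandatory groups among them (the mandatory pair counts toward the six).
"Large majority" for pathway assignment is quantified as coverage ≥ 0.7 and
the side-chain bands as ≥ 80% present / ≤ 20% absent; all three are
explicit configuration.

## Gene clusters

Clustering is single-linkage chaining by **gene count**: two hit genes join
a cluster when at most `max_gap_genes` (default 10) non-hit genes lie
between them.  A base-pair criterion was rejected because it would inherit
the simulator's intergenic-length choices; the gene-count rule is robust to
them and the threshold is reported in output headers.  Circular replicons
chain across the origin, making the partition rotation-invariant (asserted
by an exhaustive oracle test).  Strand is recorded but ignored for
clustering, since reference clusters contain genes on both strands.

## MLSA phylogeny

One taxon per detected gene cluster (a genome with two clusters appears
twice).  The four markers (KshA-, HsaA-, HsaC-, HsaD-like) are each aligned
across taxa with the package's progressive aligner (3-mer-distance UPGMA
guide tree, profile–profile NW with expected BLOSUM62 column scores),
trimmed at gap fraction 0.5, and concatenated in fixed order.  Distances are
Poisson-corrected, d = −ln(1−p), with pairwise deletion of gapped columns;
p ≥ 1 raises a saturation error except inside bootstrap replicates, where p
is truncated at 0.95 so a resampled draw cannot abort a replicate.

Trees are neighbor-joining (scikit-bio's implementation behind the module
surface; negative branch-length estimates clamped to zero).  NJ on
Poisson-corrected distances replaces a maximum-likelihood tree search: the
congruence questions asked here are purely topological, NJ is consistent on
additive matrices (verified exhaustively for all binary topologies with ≤ 6
leaves), and a full ML engine is out of scope.  This is the package's one
deliberate methodological substitution and is surfaced prominently.
Bootstrap resamples supermatrix columns with replacement; support is the
percentage of replicates containing each original bipartition, written onto
internal node labels.  The library default is 2,500 replicates; the test
suite and the acceptance script run 100, which is ample for the
presence/absence congruence calls they make.  Congruence is the
Robinson–Foulds symmetric difference of non-trivial bipartitions after
pruning both trees to their shared leaves.

## Pipeline and determinism

Stages run in the order of the original screen (HMM screen first, RBH
confirmation only for candidates).  Every threshold is echoed verbatim in
the JSON run report together with seed, version and per-stage record
counts; dropped records (unresolved hit ids, marker-incomplete taxa) are
enumerated, never silently discarded.  All randomness derives from the
config seed through named streams, reports contain no timestamps, and
mappings are serialized sorted — re-running with the same seed writes
byte-identical artifacts, which the suite asserts.

Problem sizes used by the shipped analyses: the study-condition community is
20 genomes × (500 decoys + 5 near-decoys, degraders adding 13 pathway
genes), screened with ~24 profile HMMs; the congruence contrast uses two
10-genome single-pathway communities on a balanced species tree at
bootstrap 100.

## Known limitations

* E-value scales (alignment and HMM) are internally calibrated, not
  bit-compatible with BLAST/HMMER; comparisons with external tools must be
  made at the level of decisions, not scores.
* One best local alignment per pair — no sub-optimal HSPs, no multi-domain
  envelopes; proteins with repeated domains would be under-served.
* The progressive aligner has no iterative refinement; for the small,
  closely related subclusters it aligns here that is sufficient, and the
  supermatrix stage trims ambiguous columns anyway.
* No nucleotide models anywhere: the "16S-like" marker is a slowly evolving
  protein-alphabet sequence playing the 16S role in tree comparisons.
* Whether the original identity filters were computed over query coverage
  or alignment length is not documented anywhere authoritative; the
  alignment-length convention used here is a declared choice, as is the
  gene-count cluster gap and the 0.7 coverage quantification of "large
  majority".
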