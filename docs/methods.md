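# Methods

`sdm-phylo` infers phylogenies for sets of homologous protein domains
directly from their Cα coordinates. This note records the models and
procedures the package implements, the parameters that matter, what the
synthetic-data generator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Structural dissimilarity

For a pair of domains the pipeline first finds the set of
*topologically equivalent* residues: residue pairs whose Cα atoms lie
within a cutoff (default 3.0 Å) of each other after optimal rigid
superposition. Over the `n` equivalent pairs, with `RMSD` the
root-mean-square Cα deviation after superposition, two fractions are
formed:

```
PFTE = n / length of the smaller domain        (coverage)
SRMS = 1 − RMSD / 3.0, clamped to [0, 1]       (superposition quality)
```

and combined with self-consistent weights into the structural
dissimilarity metric:

```
w1 = ((1 − PFTE) + (1 − SRMS)) / 2
w2 = (PFTE + SRMS) / 2                          (w1 + w2 = 1 identically)
SDM = −100 · log10(w1·PFTE + w2·SRMS)
```

The weighting favors the dominant signal: for close pairs (both
fractions near 1) the metric is driven by the fractions themselves; for
distant pairs the weight shifts to the (1 − ·) complements. Writing the
logarithm argument out, `g = PFTE − PFTE²/2 + SRMS²/2`, shows `g` is
monotone non-decreasing in both fractions, so SDM is monotone
non-increasing in both, equals 0 exactly when PFTE = SRMS = 1, and is
positive otherwise.

Numerical choices: the logarithm is base 10; `g` is clamped below at
`EPS = 1e-4`, capping SDM at 400 for totally dissimilar pairs so
distance-based tree methods always receive finite entries. SRMS is
clamped to [0, 1] to guard imported alignments whose RMSD may exceed
3 Å; the in-house aligner cannot produce one. Lengths count resolved Cα
atoms only. Superposition RMSD below 1e-10 Å is snapped to exactly 0 so
a domain aligned to itself scores SDM = 0 exactly rather than ~1e-13.

## Pairwise structural alignment

The equivalence set is produced by an iterative superposition aligner:

1. **Seeding.** Every gapless 8-residue fragment of structure *a*
   (starts on a stride-4 grid) is superposed by the Kabsch algorithm
   onto every gapless 8-residue fragment of structure *b* (starts at
   every position). Candidates are grouped by register offset
   (start_a − start_b, buckets of width 8) and scored by the number of
   *a* residues whose nearest transformed *b* residue falls within the
   cutoff; the best two candidates per bucket are retained, with
   branch-and-bound pruning and lexicographically-lowest tie breaking
   for determinism.

   The asymmetric grids matter: if both grids were strided, only
   register offsets that are multiples of the stride would be
   reachable, and an indel near a terminus could leave the true
   register without any gapless seed. On folds with internal
   translational pseudo-symmetry (β-barrels: sliding the chain by one
   strand rise maps most residues near their neighbors) the search then
   converges to a misregistered fixed point with plausible-looking
   RMSD. The runner-up seed per bucket is kept for the same reason:
   nearly identical seeds can flow to different fixed points.

2. **Iteration.** From each of the top 8 seed transforms: apply the
   transform, build the score matrix `S(i,j) = max(0, cutoff − d(i,j))`,
   run global sequence-order-preserving dynamic programming (linear gap
   penalty 0.5 per gap position; ties prefer the match move), keep the
   aligned pairs within the cutoff, and re-fit the transform by Kabsch
   superposition on that set. Iteration stops when the equivalence set
   repeats (converged) or after 50 iterations; an oscillating set
   yields the iterate with most equivalences (ties: lower RMSD).

3. **Selection and contract.** Among the per-seed results the
   alignment with most equivalences (ties: lower RMSD) is returned,
   after a final refit-and-filter loop guaranteeing that every reported
   pair is within the cutoff under the reported transform and that the
   RMSD is computed over exactly the reported pairs. If no seed brings
   at least 8 residues within the cutoff the pair is reported as
   maximally dissimilar (`n_equivalent = 0`, hence PFTE = 0, SDM = 400).

The aligner is deliberately minimal — rigid-body only, no Z-scores, no
secondary structure — because the downstream metric consumes only
`(n_equivalent, RMSD)` under the 3 Å rule. Externally computed
equivalences (e.g. from DALI-family tools) can be imported from a
two-column TSV; the transform and RMSD are then recomputed by Kabsch
superposition over the imported pairs, which are not cutoff-filtered.

The alignment is near-symmetric rather than exactly symmetric in its
arguments (the DP is asymmetric); on synthetic families the two
directions agree to within 2% of the smaller length in `n_equivalent`
and 0.05 Å in RMSD, which is the documented contract.

## Tree inference

All builders consume a symmetric, zero-diagonal dissimilarity matrix.

**UPGMA** is standard average linkage; merge heights are half the merge
dissimilarity, ties break on the lowest pair of original label indices.

**Clock-constrained least squares** (the Fitch–Margoliash criterion
under a molecular clock) minimizes

```
Σ_{i<j}  (d_ij − t_ij)² / d_ij^power        (power = 2 by default)
```

over ultrametric trees, where `t_ij` is the tree path length between
leaves i and j; pairs with `d_ij = 0` receive weight 1. On an
ultrametric tree `t_ij = 2·h(mrca(i,j))`, so for a fixed topology the
objective is separable per internal node and the constrained optimum
(heights non-negative, non-decreasing toward the root) is a weighted
isotonic regression on the tree order. Because each node has a single
parent, pool-adjacent-violators block merging solves it exactly; the
non-negativity bound is applied by clamping, which preserves
feasibility and optimality. The fitted score is evaluated in closed
form from per-node sufficient statistics (Σw, Σwd, Σwd²), making
topology scores exact and bit-reproducible.

The topology search starts from UPGMA and hill-climbs with
steepest-ascent nearest-neighbor interchanges, re-fitting heights
exactly for every candidate. When NNI stalls, one subtree-prune-regraft
pass widens the neighborhood; the search ends when neither move type
improves the score. Pure NNI proved insufficient — it stalled in a
local optimum on roughly 2% of random 5-taxon matrices when checked
against exhaustive enumeration of all rooted topologies — while
NNI+SPR agreed with enumeration on 100/100 random 4- and 5-taxon
instances. The returned tree always passes an ultrametricity assertion
(root-to-leaf spread ≤ 1e-6).

**Neighbor joining** is the canonical Saitou–Nei agglomeration with the
Q-criterion; ties break on the lowest original-label-index pair.
Negative branch-length estimates are clamped to zero with the deficit
transferred to the sister branch, preserving the joined pair's summed
length; final three-point branch lengths are clamped at zero. On
exactly additive matrices NJ reproduces all pairwise path lengths to
machine precision, which the tests assert.

**Utilities.** Newick serialization writes branch lengths at 6
significant digits and quotes labels containing metacharacters; parsing
goes through dendropy. Robinson–Foulds distance is the symmetric
difference of non-trivial unrooted bipartitions. Cluster extraction
cuts a rooted tree either at a height or into k blocks; for the k-cut,
branches are removed longest-internal-first (then pendant) until
exactly k leaf blocks exist — cutting a fixed k−1 branches can strand a
leafless component at the root. Singleton blocks are reported as
outliers.

## Sequence side

Percent identity is computed over aligned non-gap positions, either
over the residue pairs of a structural alignment or from a global
Needleman–Wunsch alignment (match +1, mismatch −1, linear gap −2, via
Biopython's PairwiseAligner; among co-optimal alignments its canonical
traceback is reported — scores are tie-independent). Identity
distances are simply `100 − %id` with no substitution-model correction,
and feed a neighbor-joining tree that can be compared against the
structure tree by Robinson–Foulds distance. Identity histograms use
half-open decade bins, the last bin closed at 100.

## Synthetic families

The generator provides ground-truthed inputs for every stage. A
template Cα trace mimicking an eight-stranded antiparallel β-barrel is
built per seed: eight strand segments on a cylinder (radius 6.5–9 Å,
height, cross-section aspect, per-strand angular jitter and twist, and
loop bulges all drawn per seed), corner-smoothed and then sampled at
exactly 3.8 Å consecutive-Cα spacing; parameters are redrawn
(deterministically, up to 25 attempts) until the trace is
self-avoiding. Templates from different seeds differ by > 2 Å RMSD
after superposition. Sequences are uniform over the 20 amino acids.

Leaves are evolved along a known guide tree. Per branch of length ℓ:

* coordinates receive i.i.d. Gaussian noise with standard deviation
  `noise_sigma · √ℓ` per coordinate (Brownian scaling, so squared
  displacement is additive along paths: two leaves separated by path
  length L have expected superposition RMSD ≈ `noise_sigma·√(3L)`,
  which the tests verify by Monte-Carlo);
* `Poisson(indel_rate · ℓ)` single-residue deletions at uniform
  positions (deletions only, keeping residue indices monotone;
  a lineage shrinking below 20 residues raises a generation error);
* `Poisson(substitution_rate · ℓ)` uniform single-site substitutions.

Defaults: template length 160 residues (lipocalin-sized), noise_sigma
0.3 Å, indel_rate 0.5 and substitution_rate 30 per unit branch length,
and a balanced 8-leaf ultrametric guide tree of height 1;
`random_guide_tree` supplies coalescent-style ultrametric trees for
arbitrary leaf counts (the 39-domain runs use it). Every random choice
derives from the spec seed (per-branch generators are seeded as
`[seed, branch_index]`), so identical specs give byte-identical
families.

What the generator does *not* emulate: real folding physics, side
chains, insertions (available behind no flag — deletions only),
correlated/segmental motions (helix shifts, loop remodeling),
ligand-induced conformational change, or realistic amino-acid
composition and substitution matrices. Passing tests therefore show
that the pipeline recovers the divergence structure its own model
implies — noise accumulating along a tree — not that it resolves any
particular real protein family; on real data, alignment quality (not
tree fitting) is the limiting stage.

## Problem sizes used in the checks

The routine checks run a 39-domain family (741 pairwise alignments,
~160-residue domains) for the full-size pipeline, 50 independent 8-leaf
families for topology recovery (clock tree vs. guide tree,
Robinson–Foulds = 0 expected in ≥ 90% of seeds) and for the
SDM-vs-path-length rank correlation (> 0.8), 20 random 4-/5-taxon
matrices against exhaustive topology enumeration, and a 0.05°-refined
Euler-grid rotation search against the closed-form superposition on
20 four-point instances.

## Known limitations

* The aligner is rigid-body; hinge or domain-swapped pairs will score
  as more dissimilar than a flexible aligner would report.
* SDM saturates at the cap (400) for pairs sharing no alignable core;
  a matrix dominated by capped entries carries little tree signal.
* The clock search is a deterministic local search (UPGMA start,
  NNI + SPR); for matrices far from ultrametric it can in principle
  return a local optimum, although none was observed at n ≤ 5 against
  enumeration.
* The k-block tree cut is an explicit operationalization of "clusters
  seen in the dendrogram"; it is not guaranteed to match cluster
  boundaries a human would draw by eye.
* Sequence trees use uncorrected percent-identity distances; at low
  identity these compress and the sequence tree is correspondingly
  unreliable (which is the motivation for structure-based trees).
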