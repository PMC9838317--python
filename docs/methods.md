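# Methods

## Setting

Input: K unrooted gene trees G_1..G_K over subsets of N species (one
Newick per line; multifurcations allowed; multi-copy families either carry
duplicate leaf labels or an explicit leaf→species mapping file).  Output:
an unrooted binary species tree over all species that appear in at least
one usable gene tree, optionally with bootstrap supports.  Everything is
topological: branch lengths are parsed and discarded.

The *internode distance* between leaves i and j is the number of internal
nodes on the path connecting them (equivalently, edge-count distance minus
one; a cherry pair has distance 1).  The *coverage pattern* L(G_k) is the
species set of gene k.  Inducing a tree on a taxon subset removes the
other leaves and suppresses the resulting degree-1/degree-2 nodes.

## Criterion

The per-gene distance matrix D_k holds gene k's internode distances; for
multi-copy families the species-pair entry is the minimum over all
leaf-copy pairs mapping to the two species (MiniNJ rule), which reduces to
the plain internode distance for single-copy families.

The optimized criterion is the global induced length

    L_p(S, G) = sum_k sum_{ {i,j} subset L(G_k) } 2^(-M_k(i,j)) D_k(i,j)

with M_k the internode matrix of S induced on L(G_k).  Two conventions to
note:

* **Unordered pairs.**  The symmetric double-sum convention would double
  every term; the minimizer is unchanged.  All values printed by this
  package use the unordered-pair convention.
* **Pattern grouping.**  M_k depends on gene k only through its coverage
  pattern, so families sharing a pattern are pre-summed (one matrix and
  one induced geometry per distinct pattern).  A gene-by-gene evaluation
  oracle in the test suite confirms the grouped sum to 1e-9.

The averaged-matrix criterion L(S, D_G) (the quantity minimized by plain
distance summaries, and by our starting-tree refinement) is also provided.
Species pairs co-occurring in no gene have an undefined average and
contribute 0 there — the only finite choice, and consistent with L_p where
such pairs never arise.  With complete data, L_p = K · L identically.

Weights 2^(−M) are computed in double precision; M is a small integer so
they are exact binary fractions.  Scores are compared with absolute
tolerance 1e-9 throughout.

## Search

Hill climbing over SPR moves:

1. **Starting tree.**  Default: neighbor joining (scikit-bio) on the
   averaged internode matrix, followed by nearest-neighbor-interchange
   hill climbing on the balanced-minimum-evolution length — which for a
   distance matrix D equals L(S, D), since Pauplin's pair weight
   2^(1−p_ij) is 2^(−internode distance).  Pairs missing from the
   averaged matrix are imputed by graph shortest paths through observed
   entries (scipy); this imputation affects only the starting tree, never
   the criterion.  If the species co-occurrence graph is disconnected no
   distance tree exists and the user is directed to random starts.
   Alternatively r ≥ 1 random starting trees (uniform over topologies via
   sequential leaf attachment) are searched independently and the best
   final score wins.
2. **Move evaluation.**  All SPR neighbors are enumerated in a canonical
   edge order, deduplicated by resulting bipartition set.  A move's score
   delta is computed by rescoring only the pattern groups whose induced
   geometry can change.  The exact test: a pattern's induced (suppressed)
   topology changes only if the pruned edge separates the pattern, i.e.
   the moved subtree contains some but not all of the pattern's taxa.  A
   move that only threads a pattern-free subtree through a pattern's
   spanning paths inserts/removes degree-2 points that suppression
   discards, leaving distances untouched.  Deltas are verified against
   full rescoring in the tests.
3. **Batch application.**  All improving moves (delta < −1e-9) are sorted
   best-first and applied greedily subject to pairwise-disjoint
   *touched-edge sets* (pruned edge, its two sibling edges at the
   attachment node, the regraft edge, and the path between them).  Since
   disjoint moves can still interact through shared geometry, the full
   score is recomputed after the batch; if it failed to improve, only the
   single best move is applied.  The score trace is therefore strictly
   decreasing and termination is guaranteed.
4. **Ties.**  Moves with |delta| ≤ 1e-9 are never applied, which prevents
   cycling on terraces (sets of trees with equal score under the observed
   coverage patterns).

The search is deterministic given the seed: randomness enters only through
random starting trees.

## Bootstrap

Multi-locus (gene-level) bootstrap: each of m replicates draws K families
with replacement from a pool (default: the input families; a separate pool
may be supplied), runs the full analysis — the replicate's own
distance-based start, then SPR search — and the Felsenstein support of
each branch of the best tree is the fraction of replicate trees containing
that bipartition.  Replicates never start from the best tree, to avoid
biasing supports toward it.  A replicate covering fewer species counts
toward a branch only if the branch's restriction to the replicate's taxa
is still one of the replicate tree's nontrivial splits; uninformative
replicates count against the branch (conservative).  Replicate RNG streams
are derived from (master seed, replicate index), so replicates are
individually reproducible.  A `fast` mode scores replicates with their
distance start only.

## Synthetic data

The generator reproduces the statistical structure of taxon-deletion
benchmarks at the topology level:

* **Species tree**: uniform random binary topology (sequential leaf
  attachment to a uniformly chosen edge).
* **Gene trees**: copies of the species tree, each perturbed by a chosen
  number of random NNI moves.  Zero moves = no discordance; the move count
  is a direct knob on the mean RF distance between gene trees and species
  tree, which is the quantity that matters to a topology-only criterion.
  Externally simulated gene trees (e.g. from a coalescent simulator) can
  be supplied instead wherever a family list is accepted.
* **Deletion**: species a receives deletion probability ds(a) ~ B*(μs, ν)
  and gene k receives df(k) ~ B*(μf, ν), where B*(μ, ν) is the Beta
  distribution with mean μ = α/(α+β) and sample size ν = α+β (ν defaults
  to 5).  Cell (a, k) is deleted iff an independent Bernoulli(ds(a)) OR
  Bernoulli(df(k)) fires — two deletion stages whose union gives the mean
  missing fraction 1 − (1−μs)(1−μf); both means at 0.6 remove 84% of all
  gene sequences on average.  After deletion, genes with fewer than 4
  species are dropped and species covered by no surviving gene are pruned
  from the reference tree.  The recorded missing fraction counts deleted
  cells over the full grid, before the gene filter.

What the generator does **not** emulate: coalescent branch lengths and
population-size-driven discordance structure, sequence evolution, and
gene-tree estimation error (which can be approximated by extra NNI noise).
Passing tests therefore demonstrate correctness of the criterion, the
search and the deletion model's arithmetic — not accuracy under realistic
gene-tree estimation error, which depends on an inference pipeline outside
this package's scope.

All randomness flows from one master seed through named substreams (tree,
discordance, profile, deletion), so a (parameters, seed) pair pins the
dataset byte-for-byte.

## Problem sizes in the test suite

The suite exercises the search at desk scale, chosen to keep the full run
in minutes: brute-force optimality and consistency checks enumerate all
topologies at 5–7 taxa (15 / 105 / 945 trees) on 20–30 seeded instances;
recovery experiments use 15 species × 200 genes over 20 replicates at
deletion means 0.3 and 0.6; deletion-model arithmetic uses the benchmark
grid of 50 species × 200 genes over 50 seeds.  On the oracle instances the
search attains the exhaustive optimum in ≥ 90% of cases — the hill climb
carries no optimality guarantee, and the attainment rate is the honest
statement of its small-scale behavior.

## Known limitations

* The SPR neighborhood is enumerated in full each iteration (O(n²) moves,
  each scored over affected patterns); datasets with many hundreds of
  species will be slow in pure Python, and no distributed parallelism is
  provided.
* Scoring tie-breaks make the returned member of a terrace deterministic
  but arbitrary; terraces themselves are not enumerated or reported.
* Rooted-tree semantics, branch-length estimation, and orthology-aware
  decomposition of multi-copy families are out of scope; multi-copy
  support is limited to the MiniNJ distance rule.
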