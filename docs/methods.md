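# Methods

## Scope and model

`phylodist` computes per-taxon evolutionary distinctiveness on an
edge-weighted phylogenetic tree `T = (V, E, λ)` with taxon set `X`
(`n = |X| ≥ 2`, lengths `λ(e) ≥ 0` in the input's time units).  Three
indices are implemented, all linear combinations of branch lengths whose
coefficients depend only on the splits of `T` (hence polytomy-safe):

* **Fair Proportion** — rooted: `FP(x) = Σ_{e∈path(r,x)} λ(e)/|S_e(x)|`,
  where `S_e(x)` is the leaf set below `e`.  Conservation
  `Σ_x FP(x) = Σ_e λ(e)` holds by construction (each edge's length is
  split among exactly its descendants).
* **Shapley value** — unrooted: the Shapley value of the coalitional game
  `Y ↦ PD_T(Y)`; equivalently `ψ_x = Σ_e |S̄_e(x)|/(n|S_e(x)|)·λ(e)`.
* **HED** — unrooted, with independent extinction probabilities `p(y)`:
  `ψ_x = Σ_e (Π_{y∈S_e(x)−{x}} p(y))·(1 − Π_{y∈S̄_e(x)} p(y))·λ(e)`,
  the expected marginal PD `x` adds to the surviving taxa.

FP *requires* a rooted tree and refuses unrooted input (FP depends on root
placement; guessing a root would hide errors).  Shapley and HED are
unrooted-tree indices: rooted input has a degree-2 root suppressed first
(merging the two stem edges), which is also why their scores are invariant
under re-rooting.  A branch length attached to the Newick root, when
present, is stored but excluded from every score and from the reported
total length: no split of `X` is associated with it.

## Linear-time evaluation

Each edge `{v,w}` becomes two arcs; for the arc `a` pointing away from a
taxon `z` on edge `e`, the Shapley coefficient is
`κ(a) = |S̄_e(z)|/(n|S_e(z)|)` and the HED coefficient is
`κ′(a) = (Π_{y∈S_e(z)} p(y))·(1 − Π_{y∈S̄_e(z)} p(y))`, where `S_e(z)` is
the split block containing `z`.  A taxon's score is the sum of
`coef(a)·λ(a)` over the arcs directed away from it (for HED the sum equals
`p(x)·ψ_x`, so it is divided by `p(x)` afterwards).

The implementation:

1. orients the tree from a fixed start vertex and computes per-edge leaf
   counts (one bottom-up sweep);
2. computes per-edge probability products on both sides (one bottom-up and
   one top-down sweep; sibling products are combined via prefix/suffix
   partials, never by division, which would be unavailable with zero
   factors);
3. walks the leaves in the depth-first circuit order of the input Newick
   (a planar walk), evaluates the first leaf's arc sum directly, and
   updates it along the path between consecutive leaves.  Every edge lies
   on at most two consecutive-leaf paths (the Euler tour uses each edge
   exactly twice), so step 3 does at most `2|E|` coefficient updates — the
   `TraversalStats` counter exposes this and the tests assert it.

Ties in the leaf ordering do not exist: the ordering is exactly the Newick
left-to-right leaf order (preserved through unrooting by appending the
merged root edge last in the adjacency lists), which makes all outputs
deterministic across runs.

### Zero-probability taxa

For `p(x) = 0` the division by `p(x)` is impossible, and the product over
`S_e(x)` vanishes on every arc whose near side contains `x`.  A second
coefficient family handles this: with `A*` the positive-`p` subset of a
block, `κ̃′(a) = (Π_{y∈S_e(z)*} p(y))·(1 − Π_{y∈S̄_e(z)} p(y))` if the
near block contains at most one zero-probability taxon, and 0 otherwise;
the far-side factor uses the plain product (so it is 1 whenever the far
side contains any zero-probability taxon).  The arc sum of `κ̃′` over
`A_x` equals the HED edge formula for every `x` with `p(x) = 0` — the test
suite verifies this against literal subset enumeration on hundreds of small
trees with 0, 1, and all-zero probability patterns, which pins down the
reading of the case condition.  Both families ride the same incremental
traversal, so the `2|E|` work bound is unchanged.

Probabilities that are positive but below 1e-300 are clamped to exactly 0
(with a logged warning) before coefficients are built: dividing by such a
value would amplify rounding error by ~300 orders of magnitude, and the
zero-probability formula is exact only for a true zero, so the clamp is
what makes the two statements consistent.

### Numerical choices

* Split-side probability products are carried as (positive-factor part,
  zero-factor count); the positive part is a plain double product up to 64
  taxa and a sum of logs beyond (a product over thousands of factors
  underflows; `exp` of the log sum degrades gracefully to 0.0).
* Zero-length edges are legal and contribute 0 to every score; negative
  lengths are rejected at parse time.
* Internal comparisons in tests use relative tolerance 1e-9 with an
  absolute floor of 1e-12 near zero — double-precision accumulation over
  the incremental updates stays orders of magnitude below that at the tree
  sizes tested (observed ≲1e-13 at n = 1000).
* The quadratic cross-check (`shapley_quadratic`/`hed_quadratic`) iterates
  all edges per taxon with its own per-edge leaf sets and plain-product
  bookkeeping, sharing none of the incremental-update code.  Its one
  division (removing the focal taxon's factor from the near-side product)
  is safe because zero factors are counted, not multiplied in.

## Brute-force oracles

`phylodist.oracles` evaluates the definitions literally: Shapley as the
factorial-weighted sum over all subsets containing `x` (weights kept in
exact integer arithmetic, one division at the end) and as the average
marginal PD over all `n!` arrival orders; HED as the survival-weighted sum
over all subsets of `X − {x}`.  PD is re-derived independently there by
unioning leaf-to-leaf edge paths, so an error in the split-based PD or
score code cannot cancel in the comparison.  Enumeration is capped at
n = 12 (and n = 7 for the permutation form); the oracles are test
machinery, never invoked on user data.

## Extinction probabilities

IUCN categories CR/EN/VU/NT/LC are mapped through a named value set:
`isaac` (0.4/0.2/0.1/0.05/0.025 — risk doubling per rank) or `iucn100`
(0.999/0.667/0.1/0.01/0.0001).  Data-deficient taxa are imputed by the
count-weighted mean of the mapped taxa (default), pinned to a category
(`as_category:NT`), or fixed.  Analyses run under different DD assumptions
can be combined with `combine_runs`, implemented as the unweighted
per-taxon mean of the score tables — the combination rule is genuinely
open, so both raw runs are kept available for any other downstream rule.
EX/EW codes are rejected with instructions to prune those tips: scoring an
extinct taxon as `p = 1` would silently distort every other taxon's HED.

Taxon matching between trees and probability tables is exact and
case-sensitive (after trimming whitespace and Newick unquoting); the
historical alternative — fuzzy matching — is precisely how large-tree
scoring pipelines have gone wrong, so mismatches fail loudly with the
offending names.

## Synthetic data

`yule_tree` draws a pure-birth tree conditioned on the tip count: each of
`k` lineages splits after an Exp(rate·k) wait, and once `n` lineages exist
one further Exp(rate·n) wait sets the common tip time, so trees are exactly
ultrametric with strictly positive lengths.  This emulates the shape and
depth profile of dated species trees used in distinctiveness studies; it
does **not** emulate polytomies, zero branches, extinction (no death
process), or taxon-sampling artefacts of real supertrees, so passing tests
certify algorithmic correctness, not robustness to dirty empirical trees —
polytomies and zero lengths are covered separately by hand-built fixtures.
The default birth rate is 1; all indices are scale-equivariant, so the unit
is irrelevant to every property tested.  `basal_clade_fixture` builds the
adversarial configuration where Shapley and FP disagree most — a small
clade on a long stem attached at the root of a large balanced radiation —
and the suite asserts every basal tip gets Shapley > FP there.

`random_probabilities` draws p ~ U[0,1] or category-sampled values, with
`n_zeros` taxa forced to exactly 0 to exercise the zero-probability path.
All generators are pure functions of seed and parameters.

## Batch mode

`score_batch` streams a multi-tree Newick file (one tree per line), scores
each tree, and accumulates per-taxon means and SDs with Welford's update,
so memory does not grow with the number of trees.  SDs are sample SDs
(ddof = 1), reported as 0 for a single tree.  Taxon-set mismatches across
trees are hard errors naming the offending tree and the symmetric
difference; `intersect=True` (CLI `--intersect`) instead prunes all trees
to the common taxa, merging pruned-through edges by summing lengths.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use: 200 Yule trees at
n = 2…9 against the exhaustive oracles (the full subset lattice is cached
per tree, so this is fast); conservation at n = 10/100/1000; limit and
correlation checks at n = 120–500; and the work-bound/timing check at
n = 10⁴ vs 10⁵, asserting the per-leaf time grows by at most 3× across
that decade (a quadratic implementation grows ~10×).  These sizes were
chosen so the whole validation runs in seconds on one core while still
separating linear from quadratic behaviour by a wide margin.

## Known limitations

* Single-tree scores carry no uncertainty; only across-tree moments are
  reported in batch mode.
* No NEXUS/PhyloXML input and no tree manipulation beyond unrooting,
  re-rooting, and pruning; alternative distinctiveness indices
  (equal-splits etc.) and split-network generalisations are out of scope.
* FP deliberately has no automatic (e.g. midpoint) rooting.
* HED with probabilities extremely close to (but above) 1e-300 is treated
  as the zero case; exact scores in that regime are not representable in
  double precision anyway.
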