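# Methods

## Lineage model and conventions

A cell lineage is a rooted strictly binary tree: L terminal cells (leaves)
with type labels, L − 1 internal progenitor cells, the zygote as root. Depth
counts cell divisions from the zygote (root at 0). Branch lengths carry no
meaning and are ignored on input; developmental time is not modeled.
Polytomies and unrooted trees are rejected.

Division programs are canonicalized bottom-up: the fate of a terminal cell
is its type name; the fate of an internal cell is its program, the
*unordered* pair of its daughters' fates. Unordered canonicalization is a
deliberate choice — anatomical left/right order of sublineages carries no
information in this fate-based definition — and every statistic here is
invariant to swapping the children of any node. Lineage complexity is the
number of distinct programs; simplicity S = 1/complexity.

## Robustness

f = ∏ᵢ (nᵢ/Nᵢ)^aᵢ over included (non-apoptotic) types. Apoptotic terminal
cells (`death` in the packaged censuses) stay in the tree and in program
definitions; they are excluded only from the product, so removing one costs
nothing while removing an internal ancestor of live cells does.

**f_n** is computed exactly: one pass accumulates per-node subtree type
counts, giving the f after each of the N_all − 1 single removals (every
non-root cell, apoptotic terminals included) in O(N_all · T); f_n is their
mean. It is fully deterministic.

**f_p** uses failure probability p = 1/N_internal unless overridden. Drawing
b ~ Binomial(N_program, p) failed programs uniformly without replacement is
mathematically identical to failing each program independently with
probability p; the exact oracle therefore enumerates all 2^N_program subsets
(capped at 18 programs) with weight p^k (1−p)^(P−k). The Monte Carlo
estimator (default 10 · N_all replicates) vectorizes replicates against a
leaf × program incidence matrix and agrees with the oracle at the expected
1/√replicates rate. With p = 1/N_internal the expected number of internal
cells with failed programs is ∑ usage·p = 1 exactly, which makes f_p
comparable between a lineage and its randomizations.

Rate heterogeneity (sensitivity variant): per draw, each non-root cell gets
an exponential necrosis rate with mean 1/(N_all − 1) and f_n is the
rate-weighted mean of single-removal f values; each program gets an
exponential failure probability with mean p truncated at 1 (probabilities
must be valid; the tail treatment is our choice) and one Bernoulli
realization is scored. Individual-level spread of f is available from
`stochastic_f_distribution`, where every non-root cell (or program) fails
independently per draw.

## Null models

All eight randomizers conserve the terminal census exactly. Defaults used in
published-scale analyses are 10,000 samples (5,000 per depth for the
fixed-depth family, 50 per gradient step); the test suite and acceptance
script scale these down (200–1,000 samples, 300–2,000 f_p replicates) to
keep runs in minutes — problem sizes are stated with every reported number.

* **Free coalescence** — repeatedly merge two uniformly chosen remaining
  cells until one root remains.
* **Fixed maximum depth D** — coalescence in which a merge is permitted only
  if the resulting subtree-height multiset {hᵢ} still satisfies the Kraft
  budget ∑ 2^hᵢ ≤ 2^D (each subtree must fit a slot at depth ≤ D − hᵢ in the
  remaining upper tree). When random pair sampling finds no permitted merge,
  the two shallowest subtrees are merged — a move that provably preserves
  the budget — so construction never dead-ends; outcomes whose realized
  maximum depth falls short of D are rejected and redrawn. D may range from
  the theoretical minimum ⌈log₂ L⌉ upward; far above the coalescent mode the
  rejection rate grows.
* **Bootstrap depths** — terminal depths resampled with replacement from the
  real multiset; a resample is accepted iff its maximum equals the real
  maximum and it closes to a single root (Kraft sum exactly 1; rejection is
  vectorized and capped at 10,000 attempts). Kraft equality provably forces
  an even cell count at every level of the deepest-first pairing, so no
  parity fix-up is ever needed.
* **Exact depth multiset** — terminal identities shuffled over the real
  depth slots, topology rebuilt by random deepest-first pairing.
* **Relabeling** — identical topology with terminal cells permuted freely,
  within their depths, or within depths while keeping every twin pair
  (same-type terminal siblings) together. The twins variant assigns twin
  pairs to randomly chosen sibling-leaf position pairs of the right depth;
  incidental new same-type sibling pairs can arise, so the conserved
  quantity is "every original twin pair is still a twin", not an exact
  count.
* **Clonality gradient g** — per depth, a fraction g of each type's cells is
  sorted by a per-lineage random type order, the rest are inserted at random
  positions, and cells are assigned to that depth's leaf positions left to
  right. C rises with g. The gradient separates clonality levels best on
  depth-concentrated (balanced) topologies, which the tests use.

Empirical P is r/n — the fraction of null samples at least as extreme as the
observation, ties counting as extreme; the (r+1)/(n+1) variant is not used
so that P = 0 is reportable as "no random lineage was more robust".
Z = (observed − null mean)/null SD, flagged undefined at zero null variance.

## Feature statistics

Clonality: C = (1/T) ∑ᵢ mean_M(d) / mean_{Mᵢ}(d), with d the lineal (edge)
distance, M all terminal pairs and Mᵢ the within-type pairs. The numerator
depends on topology alone (edge decomposition ∑ s_e (L − s_e)), the
within-type mean shrinks as types cluster, so larger C = more clonal. The
exact placement of sums vs. means in this index is a design choice of this
package; a ratio-of-sums form is available via `form="ratio_of_sums"` and
recorded in the result. Types with fewer than two members contribute no pair
and are skipped; T counts contributing types.

Rare-early: Spearman ρ (average ranks for ties, as everywhere here) between
terminal depth and own-type size over included types. Physical–lineal:
Spearman ρ between Euclidean nucleus distance and lineal distance over all
same-type pairs with coordinates; cells lacking coordinates are excluded
with a warning, not an error. The hill climb examines, per round, a fixed
number of lineages one same-depth same-type swap away and keeps the best
strictly improving candidate, so ρ_p-l never decreases and census and
per-cell depths are invariant. Twin spatial Z compares the mean twin
distance with replicate means of randomly drawn distinct same-type pairs
matching the twin type composition (100 replicates by default).

## Expression reclassification

Agglomerative hierarchical clustering on pairwise Euclidean distances, cut
to exactly k groups. The linkage criterion is not fixed by the procedure's
description; complete linkage is the default here, with single/average/ward
selectable and recorded in the partition metadata. Cells are sorted
lexicographically before clustering so distance ties resolve
deterministically. Partition agreement is mutual information in bits;
MI(p, p) equals the partition entropy.

## Macroevolution

The terminal-type sequence is one uniform shuffle of the target census,
drawn per replicate and shareable across selection intensities for paired
comparisons. Each of m − 1 rounds examines 100 uniform candidate
bifurcations of current terminals (one daughter inherits the parental type,
the other takes the next sequence type), ranks them by fitness with ties
broken by generation order (stable sort, deterministic under seed), and
draws the winner uniformly from the top k; k = 100 is neutral evolution.
Perturbation rates are recomputed as the lineage grows (one expected
necrosis per lineage; program failure 1/N_internal). During tournaments f_p
uses the exact oracle up to 12 programs and reduced Monte Carlo beyond —
full 10·N_all sampling inside a 100-candidate tournament would dominate the
runtime without changing rankings materially. For fully bilaterally
symmetric target organisms, bifurcations act on one half-lineage and fitness
is evaluated on the mirrored whole.

A scale note: selection for simplicity favors self-similar, slightly
shallower trees and therefore carries a small positive side effect on f_n in
this growth model; the meaningful comparison — implemented in the tests — is
that simplicity-only selection fails to reach the robustness that direct
selection for f_n produces, while exceeding it in simplicity.

## Synthetic data: what it emulates and what it does not

The packaged census files carry only the published per-type terminal counts
(embryonic C. elegans 671 with 113 apoptotic; the 937-cell post-embryonic
expansion; P. marina 638; H. roretzi 110; a neuron-subtype split of the
embryonic census). No real tree topology, coordinates or expression values
are shipped; `synth_lineage` arranges the requested census on a random
(optionally depth-constrained) topology with two planted organizational
features: rare-early strength s keeps the depth-sorted slot order for each
cell with probability s (s = 1 places rare types maximally shallow), and
twin enrichment converts mixed-type sibling pairs into twins via same-depth
swaps. Expression matrices are unit-variance Gaussians around axis-aligned
cluster centers `separation` SDs apart; coordinates are unit Gaussians
around uniform type centers plus a recursive tree embedding weighted by
`clustering_strength` (the planted physical–lineal link; shrinking
within-type spread alone would rescale distances without creating rank
correlation) and a twin-adjacency contraction toward pair midpoints.

Passing tests on these generators therefore demonstrate the machinery's
correctness and the direction of every published trend at reduced scale
(32–671 terminals, 200–1,000 null samples); they do not certify the real
lineages' absolute P values, Z-scores or percentage reductions, which
require the published trees and coordinates as inputs. When those are
supplied as Newick + TSV, the same entry points compute the full-scale
statistics.

## Degenerate inputs and numerical choices

Statistics that need variation (Spearman correlations, Z-scores) return a
flagged degenerate result at zero variance rather than raising; structural
impossibilities (no type with two members for C, no twin with coordinates,
single-cell lineages for f_n) raise typed errors. Exponents aᵢ < 1,
probabilities outside [0, 1] and non-positive sample counts are rejected at
construction. All randomness flows through numpy Generators; one global seed
fans out to named per-stage substreams (SeedSequence) so pipeline stages can
be re-run independently yet reproducibly.
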