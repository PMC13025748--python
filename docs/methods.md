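# Methods

## Corpus model and normalization

The unit of analysis is a recipe: an unordered set of normalized ingredient
names with a cuisine label and one of four canonical courses (appetizer,
soup, main dish, dessert). Raw tables are long-format (one row per
recipe–ingredient occurrence); duplicate rows collapse into the set, so a
recipe contributes at most once to any co-occurrence count regardless of
textual style.

Raw names pass through a three-tier rule engine before analysis:

* **retention** keeps composite items whose technological identity would be
  lost by decomposition (a fermented dairy preparation such as churut is
  not "milk + herbs"; a roux marks a thickening technology);
* **aggregation** merges functional equivalents under one canonical name
  (macaroni and noodles → dry pasta);
* **deconstruction** expands umbrella terms into their components (soup
  vegetables → carrot, parsnip, celeriac).

Precedence is retention > deconstruction > aggregation, so a declared
cultural signature always wins. Matching is exact on case-folded,
whitespace-trimmed strings — the corpora this targets are curated, and
fuzzy matching would hide curation errors rather than fix them. The
stoplist (default: salt, water) is applied *after* the rules, so no
deconstruction can reintroduce an excluded name. Salt and water are
excluded because they act as universal super-hubs that collapse path
structure while carrying no discriminating flavour information. Recipes
emptied by the stoplist are dropped (they contribute no edges); an
ingredient missing from the 14-class taxonomy or an unharmonized course
label is a hard error, never a silent bin.

## Networks

For any cuisine × course subset, the graph has the subset's item vocabulary
as nodes (ingredients, or the categories present) and integer edge weights
counting recipes containing both endpoints. Category networks use
presence/absence of the *category* per recipe — three meats and one
vegetable in one dish yield a single meat–vegetable increment and no
self-loop. Isolated nodes stay in the node set by default (the vocabulary,
not the edge endpoints, defines *V*); this inflates the density denominator
and can be disabled with `include_isolated=False`, so both conventions are
reproducible.

## Metrics

* **Density** D = 2m/n(n−1); undefined (error) for n < 2.
* **Weighted degree** and its percentage share of total strength (shares
  sum to 100 by construction).
* **Betweenness** is computed on the binarized graph: the path-count
  definition σ_jk(i)/σ_jk contains no weight term. A `use_weights` option
  (distance = 1/w_ij) exists as a sensitivity check, not a default.
* **Eigenvector centrality** uses the weighted adjacency via power
  iteration (tolerance 1e-10, 1000 iterations max), computed on the largest
  connected component with off-component nodes at 0, reported at unit
  Euclidean norm; max-normalization is available behind a flag since both
  conventions circulate.
* **Clustering** is the unweighted local coefficient averaged over all n
  nodes, counting degree-<2 nodes as 0; a weighted geometric-mean variant
  is behind a flag.
* **Communities** come from weighted Louvain. Louvain is order-dependent,
  so we run 20 restarts with seed-derived sub-seeds and keep the
  max-modularity partition (ties: first occurrence); fixed seed ⇒
  bit-reproducible output. Community labels are contiguous integers ordered
  by smallest member.
* Degenerate networks (n < 2 or m = 0) yield explicit `None`/note markers
  in reports, never silent zeros.

## Between-cuisine similarity

The binary Jaccard index over canonical edge sets (sorted name pairs),
weights ignored. This deliberately targets the topological skeleton: it is
invariant to corpus size differences that inflate weights, and an item
present in only one network contributes only through its edges. No
weight-aware variant is offered; removing frequency bias is the point of
the binary choice.

## Split-sample comparability

For each cuisine pair, per iteration: draw two *disjoint* equal-size
subsets from each cuisine (a split-sample; sampling without replacement),
record each cuisine's within-similarity, draw one fresh subset per cuisine
for the between-similarity, and score the iteration a success if
min(within_A, within_B) > between. The default is 500 iterations; sample
size 10 for course-level cells and 33 (the smallest cuisine corpus) for
pooled analyses. Thresholds: p ≥ 0.80 reliably comparable, 0.60–0.80
conditional, < 0.60 not reliably supported.

Two readings of the procedure are defensible — paired draws per iteration
versus pooling all within- and between-distributions; the paired reading is
the default and the pooled one remains a documented alternative. Iterations
with an undefined Jaccard (empty edge union) count as failures of the
exceedance event and are logged. A course cell is reported missing when a
cuisine has fewer than 10 recipes, and also when a disjoint 2×size split is
impossible (size 10 needs 20 recipes) — the published exclusion rule and
the split-sample arithmetic disagree in the 10–19 recipe range, and we err
on the side of not reporting an estimate the sampling scheme cannot
support. Randomness is keyed by (seed, role, cuisine label), which makes
every cell invariant under swapping the pair order.

## Robustness

**Subsampling stability.** Rebuild each cuisine's network from 80% of its
recipes without replacement, recompute the between-cuisine Jaccard per
replicate (defaults: 1200 replicates at category level, 800 at ingredient
level), and report the 2.5th–97.5th percentile interval. Degenerate
replicates are skipped and logged; a >5% skip rate triggers a warning.

**Ingredient-swap null model.** A bipartite degree-preserving randomization
of the recipe × ingredient incidence matrix: repeatedly pick two random
occurrences in different recipes and exchange their ingredients, rejecting
swaps that would duplicate an ingredient within a recipe. Every realization
preserves the recipe-size multiset and the global ingredient frequency
vector exactly — the minimal procedure satisfying both conservation laws —
while destroying structured co-occurrence. The chain burns in for 10× the
occurrence count before the first snapshot and continues with 2× between
snapshots (60 realizations per cuisine by default). Null Jaccards combine
the two cuisines' chains by paired index. The p-value is upper-tail with
add-one correction, p = (1 + #{null ≥ observed})/(1 + n_null), floor
1/61 ≈ 0.0164 at n_null = 60; ties count toward the null, so saturated
networks (where shuffling cannot change a near-complete graph) correctly
report p ≈ 1 rather than spurious significance. One- versus two-tailed and
the add-one convention are not uniquely pinned down by published practice;
this choice reproduces both the ≈0.02 floor and the p ≈ 1 regime and is
the package's documented convention.

## Synthetic corpus generator

The generator emulates the statistical skeleton of a multi-ethnic cookbook
corpus: 5 cuisines × 4 courses with configurable cell counts (the bundled
`transylvanian_preset` uses the published 20-cell structure summing to 1409
recipes), per-recipe sizes from a discrete triangular distribution on 3–15
(mode 6), and a shared regional pool versus cuisine-private pools with a
draw-level overlap probability. The preset uses a 120-ingredient shared
core, 50 private ingredients per cuisine and overlap 0.6, giving a pooled
vocabulary of a few hundred names — the order observed in curated historical
corpora. A synthetic taxonomy assigns pool members round-robin over the 14
categories unless a plan is supplied, guaranteeing every category is
realizable. Each cuisine consumes its own named random stream, so one
cuisine's parameters never perturb another's recipes, and a fixed seed
yields a byte-identical corpus.

Two planted structures exist because the base generator draws ingredients
independently (frequency signal only):

* **Forbidden category pairs** reject-and-resample recipes (bounded at 1000
  retries) whose category set would contain both members of a pair,
  emulating the kosher meat–dairy exclusion.
* **Blocks** (`n_blocks`, `block_fidelity`) confine a recipe's draws to one
  ingredient block with the given probability, planting community structure
  — the co-occurrence signal the swap-null is designed to detect.

What the generator does *not* emulate: realistic (Zipf-like) ingredient
frequency skew, course-specific vocabularies, or any flavour chemistry.
Passing tests on synthetic corpora therefore demonstrate that the machinery
recovers planted structure under controlled conditions, not that any
particular real-world claim holds.

### Calibration conditions used by the checks

Two measured facts shaped the test conditions, both worth knowing when
interpreting results on real data:

* A *single* forbidden pair removes one edge from a near-complete weighted
  14-node graph; the resulting modularity gain is within Louvain's noise
  floor (and the dairy-singleton partition is actually negative), so the
  fragmentation check plants a bipartite meat-side {meat, offal} ×
  dairy-side {dairy, composite} exclusion at 40 recipes per cuisine —
  comparable to the smallest real cuisine corpora, and closer to how a
  dietary law separates groups of categories than a lone edge deletion.
  Under these conditions constrained twins show strictly higher
  category-level modularity in ≥ 90% of paired seeds.
* For a corpus with no planted structure the observed between-cuisine
  Jaccard is exchangeable with its swap-null replicates at the ingredient
  level (p is uniform by construction), so "no structure" is only reliably
  flagged in the tie-dominated regime. The calibration check therefore
  mirrors the two regimes seen in practice: structured corpora (5 blocks,
  fidelity 0.95, 100-ingredient shared pool, 60 recipes per cuisine) reach
  the ingredient-level p floor of 1/61, while unstructured corpora are
  evaluated at the saturated category level, where p ≈ 1.

## Problem sizes in the shipped checks

The test-suite and acceptance-script runs use deliberately compact
conditions — corpora of 20–120 recipes per cuisine, 60-iteration
comparability estimates, 60 null realizations, and reduced subsampling
replicate counts — chosen so the full battery of resampling checks runs in
a few minutes on one core while every planted effect retains a comfortable
detection margin. Full-scale defaults (500 comparability iterations,
1200/800 subsampling replicates) remain the library defaults for real
analyses.

## Known limitations

* Presence/absence coding: no quantities, so centrality ranks structural
  importance, not organoleptic intensity.
* The swap chain is a standard fixed-margin MCMC without exact-uniformity
  guarantees over the ensemble; rejection rates are logged but the sampler
  is not a proof-grade curveball implementation.
* Exact reproduction of published eigenvector values depends on an
  unstated normalization; both unit-norm and max-norm are implemented.
* The normalization rule engine applies externally supplied rules; it does
  not attempt to reconstruct any particular corpus's full curation history
  from the handful of published examples.
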