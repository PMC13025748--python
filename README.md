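# culinet

Co-occurrence network analysis of multi-cuisine recipe corpora.

Historical cookbooks are structured records of a food culture: which
ingredients a community used, and — more tellingly — which ingredients it
allowed to meet in a single dish. `culinet` turns a long-format recipe table
(one row per recipe–ingredient occurrence, labelled by cuisine and course)
into weighted, undirected co-occurrence networks and quantifies how cuisines
relate, resist, and converge. It was built around a harmonized corpus of
1409 recipes from five Transylvanian ethnic traditions (Hungarian, Romanian,
Armenian, Jewish, Transylvanian Saxon), but every stage works on any corpus
with the same schema.

## The model

For a recipe set *R* over ingredients *V*, the network is *G = (V, E, W)*
with edge weights

```
w_ij = Σ_{r∈R} I(i ∈ r ∧ j ∈ r)
```

— the number of recipes containing both *i* and *j*, with per-recipe
presence/absence semantics. Analysis runs at two granularities: raw
ingredients, and a 14-class functional taxonomy (meat, vegetable, grain,
dairy, fat, spice, flavoring agent, fruit, egg, mushroom, alcohol,
composite, offal, ancillaries). On each network the package computes:

* weighted degree `wd_i = Σ_j w_ij` and its share of total strength;
* betweenness `bc_i = Σ σ_jk(i)/σ_jk` (gatekeeper ingredients);
* eigenvector centrality `Ax = λx` on the weighted adjacency;
* density `D = 2m/n(n−1)`, average clustering `C`, and weighted Louvain
  modularity `M`;
* between-cuisine similarity as the binary Jaccard index of edge sets,
  `J(A,B) = |A∩B| / |A∪B|`.

Because historical corpora are uneven, every comparison is qualified by a
split-sample comparability probability (does within-cuisine sampling
variability stay below the between-cuisine difference?), an 80%-subsampling
stability interval, and an ingredient-swap null model that preserves recipe
sizes and ingredient frequencies while destroying structured co-occurrence
(add-one empirical p-values, floor 1/61 at 60 realizations).

A seedable synthetic-corpus generator (shared regional core, cuisine-private
pools, tunable overlap, planted blocks, forbidden category pairs emulating
the kosher meat–dairy exclusion) makes the whole pipeline testable without
any external data.

## Worked example

```python
import culinet as cn

corpus = cn.generate_corpus(cn.transylvanian_preset(seed=1))
study = cn.CuisineNetworkStudy(corpus, level="category")
result = study.fit(seed=1)
print(result.summary())
```

```
Cuisine co-occurrence network study
============================================================
recipes: 1409   level: category   course: pooled
cuisines: Hungarian, Romanian, Armenian, Jewish, Saxon

Network metrics
------------------------------------------------------------
            n   m  density  avg_clustering  modularity
cuisine
Hungarian  14  91   1.0000          1.0000      0.0000
Romanian   14  91   1.0000          1.0000      0.0000
Armenian   14  91   1.0000          1.0000      0.0000
Jewish     14  90   0.9890          0.9890      0.0135
Saxon      14  91   1.0000          1.0000      0.0000

Between-cuisine edge Jaccard (category, pooled)
------------------------------------------------------------
           Hungarian  Romanian  Armenian  Jewish  Saxon
Hungarian     1.0000    1.0000    1.0000  0.9890 1.0000
Romanian      1.0000    1.0000    1.0000  0.9890 1.0000
Armenian      1.0000    1.0000    1.0000  0.9890 1.0000
Jewish        0.9890    0.9890    0.9890  1.0000 0.9890
Saxon         1.0000    1.0000    1.0000  0.9890 1.0000
```

The four unconstrained cuisines saturate the 14-category graph (density 1,
modularity 0); the Jewish cuisine, generated with the meat–dairy exclusion,
is missing exactly that edge (m = 90, density 0.989), which lowers its
Jaccard to every other cuisine to 90/91 ≈ 0.989 and gives it the only
non-zero modularity. On real corpora the same machinery exposes the
published pattern: near-complete Hungarian/Romanian/Armenian category
graphs versus markedly sparser Saxon and Jewish ones.

The shell interface mirrors the library:

```
culinet simulate --seed 1 --out corpus.csv
culinet all --config config.yaml --seed 1 --out results/
```

`culinet all` writes the normalized corpus, per-cuisine GraphML/edge-list
networks, metric reports (CSV/JSON), Jaccard and comparability matrices,
the robustness table, rendered figures, and a manifest sufficient to re-run
bit-identically.

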