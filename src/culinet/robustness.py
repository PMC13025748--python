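"""Stability and null-model checks for between-cuisine similarity.

Two complementary checks qualify every between-cuisine Jaccard value:

* **Subsampling stability** -- rebuild each cuisine's network from 80% of
  its recipes (without replacement), many times (1200 replicates at
  category level, 800 at ingredient level by default), and report the
  2.5th-97.5th percentile interval of the replicate Jaccards.
* **Ingredient-swap null model** -- randomize each cuisine by repeatedly
  swapping ingredient occurrences between two random recipes, rejecting
  swaps that would duplicate an ingredient within a recipe.  This is a
  bipartite degree-preserving randomization of the recipe x ingredient
  incidence matrix: every realization keeps each recipe's size and each
  ingredient's total frequency exactly, while destroying structured
  co-occurrence.  The observed full-corpus Jaccard is compared against 60
  paired null realizations per cuisine with an add-one upper-tail p-value,
  p = (1 + #{null >= observed}) / (1 + n_null), whose floor at n_null = 60
  is 1/61 ~ 0.0164.

The swap chain burns in for 10x the occurrence count before the first
snapshot and continues with 2x between snapshots, so successive
realizations are decorrelated draws from one chain.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import CategoryTaxonomy, Corpus, Recipe
from .errors import InsufficientDataError, UndefinedSimilarityError
from .networks import build_category_network, build_ingredient_network
from .similarity import edge_jaccard

logger = logging.getLogger(__name__)

#: default subsampling replicate counts by network level
DEFAULT_REPLICATES = {"category": 1200, "ingredient": 800}
BURN_IN_FACTOR = 10
THIN_FACTOR = 2


@dataclass
class RobustnessConfig:
    subsample_fraction: float = 0.80
    #: None resolves to the per-level default (1200 category / 800 ingredient)
    n_replicates: int | None = None
    n_null: int = 60
    level: str = "category"
    seed: int = 0

    def resolved_replicates(self, level: str) -> int:
        if self.n_replicates is not None:
            return self.n_replicates
        return DEFAULT_REPLICATES[level]


@dataclass(frozen=True)
class RobustnessCell:
    pair: tuple[str, str]
    level: str
    interval_low: float
    interval_high: float
    observed: float
    null_mean: float
    p_value: float
    n_replicates: int
    n_skipped: int


def _builder(level: str):
    return build_category_network if level == "category" else build_ingredient_network


def _stream(seed: int, *tokens: str) -> np.random.Generator:
    entropy = [seed] + [zlib.crc32(t.encode()) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def subsample_interval(
    recipes_a: Sequence[Recipe],
    recipes_b: Sequence[Recipe],
    config: RobustnessConfig,
    rng: np.random.Generator,
    level: str | None = None,
) -> tuple[float, float, np.ndarray]:
    """2.5th-97.5th percentile interval of subsampled between-cuisine Jaccard."""
    level = level or config.level
    if len(recipes_a) < 5 or len(recipes_b) < 5:
        raise InsufficientDataError(
            "subsampling needs >= 5 recipes per cuisine "
            f"(have {len(recipes_a)}, {len(recipes_b)})"
        )
    n_rep = config.resolved_replicates(level)
    ka = math.ceil(config.subsample_fraction * len(recipes_a))
    kb = math.ceil(config.subsample_fraction * len(recipes_b))
    build = _builder(level)
    values = []
    skipped = 0
    for _ in range(n_rep):
        sub_a = [recipes_a[i] for i in rng.choice(len(recipes_a), ka, replace=False)]
        sub_b = [recipes_b[i] for i in rng.choice(len(recipes_b), kb, replace=False)]
        try:
            values.append(edge_jaccard(build(sub_a), build(sub_b)).jaccard)
        except UndefinedSimilarityError:
            skipped += 1
    if skipped > 0.05 * n_rep:
        logger.warning(
            "subsample_interval: %d/%d replicates degenerate", skipped, n_rep
        )
    arr = np.asarray(values)
    low, high = np.percentile(arr, [2.5, 97.5])
    return float(low), float(high), arr


class _SwapChain:
    """Mutable recipe x ingredient incidence under occurrence swaps."""

    def __init__(self, recipes: Sequence[Recipe], rng: np.random.Generator):
        self.template = list(recipes)
        self.rng = rng
        self.sets: list[set[str]] = [set(r.ingredients) for r in recipes]
        self.occ: list[list] = [
            [ri, ing] for ri, s in enumerate(self.sets) for ing in sorted(s)
        ]

    @property
    def n_occurrences(self) -> int:
        return len(self.occ)

    def attempt_swaps(self, n_attempts: int) -> int:
        """Attempt pairwise occurrence swaps; returns accepted count."""
        if self.n_occurrences < 2:
            return 0
        accepted = 0
        pairs = self.rng.integers(0, self.n_occurrences, size=(n_attempts, 2))
        for i, j in pairs:
            oi, oj = self.occ[i], self.occ[j]
            ri, ing_i = oi
            rj, ing_j = oj
            if ri == rj or ing_i == ing_j:
                continue
            if ing_j in self.sets[ri] or ing_i in self.sets[rj]:
                continue  # would duplicate an ingredient within a recipe
            self.sets[ri].remove(ing_i)
            self.sets[ri].add(ing_j)
            self.sets[rj].remove(ing_j)
            self.sets[rj].add(ing_i)
            oi[1], oj[1] = ing_j, ing_i
            accepted += 1
        return accepted

    def snapshot(self, taxonomy: CategoryTaxonomy | None) -> list[Recipe]:
        out = []
        for template, items in zip(self.template, self.sets):
            categories = (
                taxonomy.categories_of(items) if taxonomy is not None else frozenset()
            )
            out.append(
                Recipe(
                    recipe_id=template.recipe_id,
                    cuisine=template.cuisine,
                    course=template.course,
                    ingredients=frozenset(items),
                    categories=categories,
                )
            )
        return out


def swap_null_corpus(
    recipes: Sequence[Recipe],
    rng: np.random.Generator,
    taxonomy: CategoryTaxonomy | None = None,
    n_attempts: int | None = None,
) -> list[Recipe]:
    """One swap-null realization of a recipe list.

    Preserves the recipe-size multiset and the global ingredient frequency
    vector exactly.  An unswappable input (fewer than 2 recipes, or a
    vocabulary too small to exchange) is returned unchanged with a warning.
    """
    if len(recipes) < 2:
        raise InsufficientDataError("swap null needs at least 2 recipes")
    chain = _SwapChain(recipes, rng)
    n_attempts = (
        BURN_IN_FACTOR * chain.n_occurrences if n_attempts is None else n_attempts
    )
    accepted = chain.attempt_swaps(n_attempts)
    if accepted == 0:
        logger.warning(
            "swap_null_corpus: no swap accepted in %d attempts; "
            "returning input unchanged",
            n_attempts,
        )
    return chain.snapshot(taxonomy)


def swap_null_realizations(
    recipes: Sequence[Recipe],
    n_realizations: int,
    rng: np.random.Generator,
    taxonomy: CategoryTaxonomy | None = None,
) -> list[list[Recipe]]:
    """A chain of swap-null realizations (burn-in 10x, thinning 2x occurrences)."""
    if len(recipes) < 2:
        raise InsufficientDataError("swap null needs at least 2 recipes")
    chain = _SwapChain(recipes, rng)
    chain.attempt_swaps(BURN_IN_FACTOR * chain.n_occurrences)
    out = [chain.snapshot(taxonomy)]
    for _ in range(n_realizations - 1):
        chain.attempt_swaps(THIN_FACTOR * chain.n_occurrences)
        out.append(chain.snapshot(taxonomy))
    return out


def null_p_value(observed: float, null_values: Sequence[float]) -> tuple[float, float]:
    """Null mean and add-one upper-tail empirical p-value.

    p = (1 + #{null >= observed}) / (1 + n): the probability of seeing at
    least as much shared structure by chance, bounded below by 1/(n+1).
    """
    if len(null_values) == 0:
        raise ValueError("null_values must be non-empty")
    arr = np.asarray(null_values, dtype=float)
    p = (1.0 + int(np.sum(arr >= observed))) / (1.0 + arr.size)
    return float(arr.mean()), float(p)


def robustness_table(
    corpus: Corpus,
    config: RobustnessConfig,
    levels: Sequence[str] = ("category", "ingredient"),
) -> pd.DataFrame:
    """Full robustness table: all cuisine pairs x levels.

    Null realizations are generated once per cuisine (one chain each) and
    combined pairwise by index (i-th of A with i-th of B), yielding
    ``n_null`` null Jaccards per pair; the observed statistic is the
    full-corpus between-cuisine Jaccard.
    """
    cuisines = corpus.cuisines
    by_cuisine = {c: corpus.subset(c) for c in cuisines}
    nulls = {
        c: swap_null_realizations(
            by_cuisine[c],
            config.n_null,
            _stream(config.seed, "null", c),
            taxonomy=corpus.taxonomy,
        )
        for c in cuisines
    }
    rows = []
    for level in levels:
        build = _builder(level)
        full_nets = {c: build(by_cuisine[c]) for c in cuisines}
        null_nets = {c: [build(r) for r in nulls[c]] for c in cuisines}
        for i, a in enumerate(cuisines):
            for b in cuisines[i + 1 :]:
                observed = edge_jaccard(full_nets[a], full_nets[b]).jaccard
                null_vals = []
                for na, nb in zip(null_nets[a], null_nets[b]):
                    try:
                        null_vals.append(edge_jaccard(na, nb).jaccard)
                    except UndefinedSimilarityError:
                        null_vals.append(0.0)
                null_mean, p = null_p_value(observed, null_vals)
                rng = _stream(config.seed, "subsample", level, a, b)
                low, high, values = subsample_interval(
                    by_cuisine[a], by_cuisine[b], config, rng, level=level
                )
                rows.append(
                    {
                        "cuisine_a": a,
                        "cuisine_b": b,
                        "level": level,
                        "interval_low": low,
                        "interval_high": high,
                        "observed": observed,
                        "null_mean": null_mean,
                        "p_value": p,
                        "n_replicates": values.size,
                        "n_null": len(null_vals),
                    }
                )
    return pd.DataFrame(rows)
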