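"""Synthetic multi-cuisine recipe corpora with controlled structure.

The generator emulates the statistical skeleton of a historical multi-ethnic
cookbook corpus: a shared regional ingredient core, cuisine-specific private
pools, a tunable probability (``overlap``) that any single draw comes from
the shared core, per-recipe ingredient counts of roughly 3-15, a 5 x 4
cuisine-by-course cell structure, and optional forbidden category pairs per
cuisine (emulating the kosher meat-dairy exclusion, which forbids the two
categories from co-occurring in a single dish).

Two optional knobs plant higher-order structure:

* ``n_blocks``/``block_fidelity`` confine a recipe's draws to one of several
  ingredient blocks with the given probability, planting community structure
  in the co-occurrence graph.  With fidelity 0 the generator draws
  ingredients independently, i.e. the corpus carries frequency information
  but no structured co-occurrence -- exactly the regime the ingredient-swap
  null model is meant to reproduce.

Reproducibility contract: the same :class:`SimulationConfig` (including
seed) yields a byte-identical corpus; each cuisine consumes its own named
random stream, so changing one cuisine's parameters leaves the others'
recipes untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .corpus import CATEGORIES, COURSES, CategoryTaxonomy, Corpus, Recipe, clean_name
from .errors import GenerationError, ValidationError

_MAX_RETRIES = 1000


@dataclass
class SimulationConfig:
    cuisines: tuple[str, ...] = ("A", "B")
    #: either one count for every (cuisine, course) cell or an explicit map
    recipes_per_cell: int | Mapping[tuple[str, str], int] = 25
    shared_pool_size: int = 60
    private_pool_size: int = 40
    overlap: float = 0.5
    #: (min, max, mode) of the discrete triangular recipe-size distribution
    recipe_size: tuple[int, int, int] = (3, 15, 6)
    forbidden_pairs: Mapping[str, frozenset[frozenset[str]]] = field(
        default_factory=dict
    )
    n_blocks: int = 1
    block_fidelity: float = 0.0
    taxonomy: CategoryTaxonomy | None = None
    courses: tuple[str, ...] = COURSES
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap <= 1.0:
            raise ValidationError("overlap must be in [0, 1]")
        lo, hi, mode = self.recipe_size
        if lo < 2 or hi < lo or not lo <= mode <= hi:
            raise ValidationError("recipe_size must satisfy 2 <= min <= mode <= max")
        if self.shared_pool_size + self.private_pool_size < hi:
            raise ValidationError("pools smaller than the largest recipe size")
        if self.n_blocks < 1:
            raise ValidationError("n_blocks must be >= 1")
        if not 0.0 <= self.block_fidelity <= 1.0:
            raise ValidationError("block_fidelity must be in [0, 1]")
        self.forbidden_pairs = {
            c: frozenset(frozenset(map(clean_name, p)) for p in pairs)
            for c, pairs in self.forbidden_pairs.items()
        }

    def cell_count(self, cuisine: str, course: str) -> int:
        if isinstance(self.recipes_per_cell, Mapping):
            return int(self.recipes_per_cell.get((cuisine, course), 0))
        return int(self.recipes_per_cell)


def shared_pool(config: SimulationConfig) -> list[str]:
    return [f"shared-{i:03d}" for i in range(config.shared_pool_size)]


def private_pool(config: SimulationConfig, cuisine: str) -> list[str]:
    tag = clean_name(cuisine).replace(" ", "_")
    return [f"{tag}-{i:03d}" for i in range(config.private_pool_size)]


def synthetic_taxonomy(config: SimulationConfig) -> CategoryTaxonomy:
    """Round-robin assignment of pool members over the 14 categories.

    Guarantees every category is realizable as long as pools hold >= 14
    ingredients in total.  A user-supplied taxonomy in the config wins.
    """
    if config.taxonomy is not None:
        return config.taxonomy
    names = list(shared_pool(config))
    for cuisine in config.cuisines:
        names.extend(private_pool(config, cuisine))
    mapping = {name: CATEGORIES[i % len(CATEGORIES)] for i, name in enumerate(names)}
    return CategoryTaxonomy(mapping=mapping)


def _size_pmf(lo: int, hi: int, mode: int) -> np.ndarray:
    ks = np.arange(lo, hi + 1, dtype=float)
    up = (ks - lo + 1) / (mode - lo + 1)
    down = (hi - ks + 1) / (hi - mode + 1)
    w = np.minimum(up, down)
    return w / w.sum()


def _violates(categories: frozenset[str], pairs: frozenset[frozenset[str]]) -> bool:
    return any(pair <= categories for pair in pairs)


def _draw_recipe(
    rng: np.random.Generator,
    size: int,
    shared: list[str],
    private: list[str],
    blocks_shared: list[list[str]],
    blocks_private: list[list[str]],
    config: SimulationConfig,
) -> set[str]:
    block = int(rng.integers(config.n_blocks)) if config.n_blocks > 1 else 0
    chosen: set[str] = set()
    for _ in range(size):
        use_shared = rng.random() < config.overlap
        pool = shared if use_shared else private
        if config.n_blocks > 1 and rng.random() < config.block_fidelity:
            pool = blocks_shared[block] if use_shared else blocks_private[block]
        candidates = [x for x in pool if x not in chosen]
        if not candidates:
            # block or pool exhausted: widen to the full vocabulary
            candidates = [x for x in shared + private if x not in chosen]
            if not candidates:
                break
        chosen.add(candidates[int(rng.integers(len(candidates)))])
    return chosen


def generate_corpus(config: SimulationConfig) -> Corpus:
    """Generate a corpus matching the config's cell counts exactly.

    Recipes violating a cuisine's forbidden category pairs are rejected and
    redrawn (bounded retries); an infeasible constraint set raises
    :class:`GenerationError`.
    """
    taxonomy = synthetic_taxonomy(config)
    shared = shared_pool(config)
    blocks_shared = [shared[b :: config.n_blocks] for b in range(config.n_blocks)]
    pmf = _size_pmf(*config.recipe_size)
    sizes = np.arange(config.recipe_size[0], config.recipe_size[1] + 1)

    recipes: list[Recipe] = []
    for ci, cuisine in enumerate(config.cuisines):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(ci,))
        )
        private = private_pool(config, cuisine)
        blocks_private = [
            private[b :: config.n_blocks] for b in range(config.n_blocks)
        ]
        pairs = config.forbidden_pairs.get(cuisine, frozenset())
        for course in config.courses:
            for k in range(config.cell_count(cuisine, course)):
                for attempt in range(_MAX_RETRIES):
                    size = int(rng.choice(sizes, p=pmf))
                    ingredients = _draw_recipe(
                        rng, size, shared, private, blocks_shared, blocks_private, config
                    )
                    if len(ingredients) < 2:
                        continue
                    categories = taxonomy.categories_of(ingredients)
                    if not _violates(categories, pairs):
                        break
                else:
                    raise GenerationError(
                        f"could not satisfy forbidden pairs for {cuisine!r} "
                        f"after {_MAX_RETRIES} retries"
                    )
                recipes.append(
                    Recipe(
                        recipe_id=f"{clean_name(cuisine).replace(' ', '_')}-"
                        f"{clean_name(course).replace(' ', '_')}-{k:04d}",
                        cuisine=cuisine,
                        course=course,
                        ingredients=frozenset(ingredients),
                        categories=categories,
                    )
                )
    return Corpus(recipes=recipes, taxonomy=taxonomy)


def planted_structure_report(corpus: Corpus, config: SimulationConfig) -> dict:
    """Compare realized corpus statistics with the planted configuration.

    Returns realized shared-pool occurrence fraction, recipe-size summary,
    cell-count mismatches and forbidden-pair violations (must be 0 for any
    valid generator run).
    """
    occurrences = 0
    shared_occ = 0
    sizes = []
    violations = 0
    for r in corpus.recipes:
        sizes.append(len(r.ingredients))
        occurrences += len(r.ingredients)
        shared_occ += sum(1 for i in r.ingredients if i.startswith("shared-"))
        pairs = config.forbidden_pairs.get(r.cuisine, frozenset())
        if _violates(r.categories, pairs):
            violations += 1
    counts = corpus.counts
    mismatches = 0
    for cuisine in config.cuisines:
        for course in config.courses:
            if counts.get((cuisine, course), 0) != config.cell_count(cuisine, course):
                mismatches += 1
    sizes_arr = np.asarray(sizes)
    return {
        "n_recipes": len(corpus.recipes),
        "n_occurrences": occurrences,
        "realized_overlap": shared_occ / occurrences if occurrences else float("nan"),
        "size_min": int(sizes_arr.min()),
        "size_max": int(sizes_arr.max()),
        "size_mean": float(sizes_arr.mean()),
        "cell_count_mismatches": mismatches,
        "forbidden_violations": violations,
    }
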