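"""Split-sample comparability assessment for uneven corpora.

Historical recipe corpora are uneven across cuisines, so before comparing
two cuisines we ask whether sampling variability is smaller than the
cross-cuisine difference.  For each cuisine pair, per iteration:

* draw two *disjoint* random subsets of equal size from cuisine A, build
  their networks, record their edge Jaccard (within-A stability), and the
  same for cuisine B;
* draw one subset from each cuisine and record the between-cuisine Jaccard;
* score the iteration a success if min(within_A, within_B) > between.

``p_feasible`` is the success fraction over the iterations (default 500).
Pairs with p >= 0.80 are *reliably* comparable, 0.60-0.80 *conditionally*,
below 0.60 *not reliably supported*.  Course-level cells use balanced
samples of 10 recipes per cuisine; pooled analyses use 33 (the smallest
cuisine corpus in the reference study).  Cuisines too small to split-sample
are reported as insufficient-data, never as zero.

Randomness is keyed by (seed, role, cuisine label), which makes every cell
reproducible bit-for-bit and invariant under swapping the pair order.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import COURSES, Corpus, Recipe
from .errors import InsufficientDataError, UndefinedSimilarityError
from .networks import build_category_network, build_ingredient_network
from .similarity import edge_jaccard

logger = logging.getLogger(__name__)

RELIABLE = "reliable"
CONDITIONAL = "conditional"
UNSUPPORTED = "unsupported"
INSUFFICIENT = "insufficient-data"

#: minimum recipes per cuisine for a course-level cell to be reported
MIN_RECIPES = 10


@dataclass
class ComparabilityConfig:
    n_iterations: int = 500
    #: None resolves to 10 for course-level scopes and 33 for pooled
    sample_size: int | None = None
    level: str = "ingredient"
    seed: int = 0
    #: within- and between-draws paired per iteration (pooled reading off)
    paired: bool = True

    def resolved_size(self, scope: str) -> int:
        if self.sample_size is not None:
            return self.sample_size
        return 33 if scope == "pooled" else 10


@dataclass(frozen=True)
class ComparabilityCell:
    pair: tuple[str, str]
    p_feasible: float
    verdict: str


def _stream(seed: int, role: str, label: str) -> np.random.Generator:
    entropy = [seed, zlib.crc32(role.encode()), zlib.crc32(label.encode())]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _builder(level: str):
    return build_category_network if level == "category" else build_ingredient_network


def _sample(recipes: Sequence[Recipe], size: int, rng: np.random.Generator):
    idx = rng.choice(len(recipes), size=size, replace=False)
    return [recipes[i] for i in idx]


def split_sample_similarity(
    recipes: Sequence[Recipe],
    size: int,
    level: str,
    rng: np.random.Generator,
) -> float:
    """Edge Jaccard between two disjoint equal-size subsets of one cuisine.

    Returns NaN when the Jaccard is undefined (empty edge union).
    """
    if 2 * size > len(recipes):
        raise InsufficientDataError(
            f"need >= {2 * size} recipes for a disjoint split of {size}+{size}, "
            f"have {len(recipes)}"
        )
    idx = rng.permutation(len(recipes))
    first = [recipes[i] for i in idx[:size]]
    second = [recipes[i] for i in idx[size : 2 * size]]
    build = _builder(level)
    try:
        return edge_jaccard(build(first), build(second)).jaccard
    except UndefinedSimilarityError:
        return float("nan")


def between_similarity(
    recipes_a: Sequence[Recipe],
    recipes_b: Sequence[Recipe],
    size: int,
    level: str,
    rng_a: np.random.Generator,
    rng_b: np.random.Generator | None = None,
) -> float:
    """Edge Jaccard between one random subset from each cuisine."""
    if size > len(recipes_a) or size > len(recipes_b):
        raise InsufficientDataError(
            f"subset size {size} exceeds a cuisine corpus "
            f"({len(recipes_a)}, {len(recipes_b)})"
        )
    rng_b = rng_a if rng_b is None else rng_b
    build = _builder(level)
    sub_a = _sample(recipes_a, size, rng_a)
    sub_b = _sample(recipes_b, size, rng_b)
    try:
        return edge_jaccard(build(sub_a), build(sub_b)).jaccard
    except UndefinedSimilarityError:
        return float("nan")


def comparability_probability(
    recipes_a: Sequence[Recipe],
    recipes_b: Sequence[Recipe],
    config: ComparabilityConfig,
    scope: str = "per-course",
) -> ComparabilityCell:
    """Probability that within-cuisine stability exceeds between-cuisine similarity."""
    label_a = recipes_a[0].cuisine if recipes_a else "A"
    label_b = recipes_b[0].cuisine if recipes_b else "B"
    pair = (label_a, label_b)
    size = config.resolved_size(scope)
    feasible = (
        len(recipes_a) >= MIN_RECIPES
        and len(recipes_b) >= MIN_RECIPES
        and 2 * size <= len(recipes_a)
        and 2 * size <= len(recipes_b)
    )
    if not feasible:
        return ComparabilityCell(pair=pair, p_feasible=float("nan"), verdict=INSUFFICIENT)

    within = {
        label_a: _stream(config.seed, "within", label_a),
        label_b: _stream(config.seed, "within", label_b),
    }
    between = {
        label_a: _stream(config.seed, "between", label_a),
        label_b: _stream(config.seed, "between", label_b),
    }
    successes = 0
    undefined = 0
    for _ in range(config.n_iterations):
        wa = split_sample_similarity(recipes_a, size, config.level, within[label_a])
        wb = split_sample_similarity(recipes_b, size, config.level, within[label_b])
        bt = between_similarity(
            recipes_a, recipes_b, size, config.level, between[label_a], between[label_b]
        )
        if np.isnan(wa) or np.isnan(wb) or np.isnan(bt):
            undefined += 1  # counts as a failure of the exceedance event
            continue
        if min(wa, wb) > bt:
            successes += 1
    if undefined:
        logger.info(
            "pair %s: %d/%d iterations had an undefined Jaccard",
            pair,
            undefined,
            config.n_iterations,
        )
    p = successes / config.n_iterations
    verdict = RELIABLE if p >= 0.80 else CONDITIONAL if p >= 0.60 else UNSUPPORTED
    return ComparabilityCell(pair=pair, p_feasible=p, verdict=verdict)


@dataclass
class ComparabilityMatrix:
    p: pd.DataFrame
    verdicts: pd.DataFrame
    scope: str
    level: str

    def to_csv(self, path) -> None:
        self.p.to_csv(path)


def comparability_matrix(
    corpus: Corpus,
    config: ComparabilityConfig,
    scope: str = "pooled",
) -> dict[str, ComparabilityMatrix]:
    """Pairwise comparability matrices, pooled or one per course.

    Returns a mapping scope-label -> matrix ("pooled", or one entry per
    course).  Cells whose cuisines fail the sampling preconditions are NaN
    with verdict ``insufficient-data``.
    """
    cuisines = corpus.cuisines
    scopes = [("pooled", "all")] if scope == "pooled" else [(c, c) for c in COURSES]
    out: dict[str, ComparabilityMatrix] = {}
    for scope_label, course in scopes:
        p = pd.DataFrame(np.nan, index=cuisines, columns=cuisines, dtype=float)
        verdicts = pd.DataFrame("", index=cuisines, columns=cuisines, dtype=object)
        for i, a in enumerate(cuisines):
            for b in cuisines[i + 1 :]:
                cell = comparability_probability(
                    corpus.subset(a, course),
                    corpus.subset(b, course),
                    config,
                    scope="pooled" if scope_label == "pooled" else "per-course",
                )
                p.loc[a, b] = p.loc[b, a] = cell.p_feasible
                verdicts.loc[a, b] = verdicts.loc[b, a] = cell.verdict
        out[scope_label] = ComparabilityMatrix(
            p=p, verdicts=verdicts, scope=scope_label, level=config.level
        )
    return out
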