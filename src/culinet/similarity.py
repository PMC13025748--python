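"""Binary Jaccard comparison of co-occurrence networks.

Two networks are compared through their edge *sets* only: J = |A ∩ B| /
|A ∪ B| over canonical (sorted name pair) edges, ignoring weights.  The
binary index targets the topological skeleton of a cuisine and removes
frequency biases caused by unequal corpus sizes; an item present in one
network but absent from the other contributes only through its edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import Corpus
from .errors import UndefinedSimilarityError
from .networks import CooccurrenceNetwork, subset_network

POOLED = "pooled"


@dataclass(frozen=True)
class SimilarityResult:
    pair: tuple[str, str]
    level: str
    course: str
    jaccard: float
    intersection_size: int
    union_size: int


def edge_jaccard(
    net_a: CooccurrenceNetwork, net_b: CooccurrenceNetwork
) -> SimilarityResult:
    """Binary Jaccard index of two networks' edge sets."""
    if net_a.level != net_b.level:
        raise ValueError(
            f"cannot compare networks at different levels "
            f"({net_a.level!r} vs {net_b.level!r})"
        )
    ea, eb = net_a.edge_set(), net_b.edge_set()
    union = len(ea | eb)
    if union == 0:
        raise UndefinedSimilarityError("both edge sets are empty")
    inter = len(ea & eb)
    course_a, course_b = net_a.subset_label[1], net_b.subset_label[1]
    return SimilarityResult(
        pair=(net_a.subset_label[0], net_b.subset_label[0]),
        level=net_a.level,
        course=course_a if course_a == course_b else POOLED,
        jaccard=inter / union,
        intersection_size=inter,
        union_size=union,
    )


@dataclass
class SimilarityMatrix:
    """Symmetric cuisine-by-cuisine Jaccard matrix plus the pair results."""

    matrix: pd.DataFrame
    pairs: list[SimilarityResult]
    level: str
    course: str

    def to_csv(self, path: str | Path) -> None:
        self.matrix.to_csv(path)

    def pairs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    r.pair[0],
                    r.pair[1],
                    r.level,
                    r.course,
                    r.jaccard,
                    r.intersection_size,
                    r.union_size,
                )
                for r in self.pairs
            ],
            columns=[
                "cuisine_a",
                "cuisine_b",
                "level",
                "course",
                "jaccard",
                "intersection",
                "union",
            ],
        )


def similarity_matrix(
    corpus: Corpus,
    level: str = "category",
    course: str = POOLED,
    include_isolated: bool = True,
) -> SimilarityMatrix:
    """Pairwise between-cuisine edge Jaccard at one level, one course scope.

    Empty cuisine subsets yield missing (NaN) cells, never fabricated zeros;
    the diagonal is 1 by definition.
    """
    cuisines = corpus.cuisines
    if len(cuisines) < 2:
        raise ValueError("similarity matrix needs at least two cuisines")
    nets: dict[str, CooccurrenceNetwork | None] = {}
    for c in cuisines:
        recipes = corpus.subset(c, "all" if course == POOLED else course)
        if recipes:
            builder_course = "all" if course == POOLED else course
            nets[c] = subset_network(
                corpus, c, builder_course, level=level, include_isolated=include_isolated
            )
        else:
            nets[c] = None
    mat = pd.DataFrame(np.nan, index=cuisines, columns=cuisines, dtype=float)
    results: list[SimilarityResult] = []
    for i, a in enumerate(cuisines):
        if nets[a] is not None:
            mat.loc[a, a] = 1.0
        for b in cuisines[i + 1 :]:
            if nets[a] is None or nets[b] is None:
                continue
            res = edge_jaccard(nets[a], nets[b])
            res = SimilarityResult(
                pair=(a, b),
                level=level,
                course=course,
                jaccard=res.jaccard,
                intersection_size=res.intersection_size,
                union_size=res.union_size,
            )
            results.append(res)
            mat.loc[a, b] = res.jaccard
            mat.loc[b, a] = res.jaccard
    return SimilarityMatrix(matrix=mat, pairs=results, level=level, course=course)
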