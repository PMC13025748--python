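"""Model/Results facade over the analysis pipeline.

:class:`CuisineNetworkStudy` is constructed from a corpus (loaded,
synthetic, or assembled from a dataframe) and frozen analysis choices
(level, course scope, isolated-node convention).  Its :meth:`fit` runs the
deterministic stages (networks, metrics, similarity) and, when configured,
the resampling stages (comparability, robustness), returning a
:class:`StudyResults` that carries every table plus a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .comparability import ComparabilityConfig, ComparabilityMatrix, comparability_matrix
from .corpus import (
    CategoryTaxonomy,
    Corpus,
    NormalizationRuleSet,
    RawRecipeRecord,
    build_recipes,
    corpus_summary,
)
from .metrics import MetricsReport, metrics_report
from .networks import CooccurrenceNetwork, subset_network
from .robustness import RobustnessConfig, robustness_table
from .similarity import SimilarityMatrix, similarity_matrix
from .simulate import SimulationConfig, generate_corpus


class CuisineNetworkStudy:
    """Co-occurrence network study of a multi-cuisine recipe corpus.

    Parameters
    ----------
    corpus
        Normalized recipe corpus.
    level
        "category" or "ingredient"; the granularity of every fitted network.
    course
        Canonical course to restrict to, or "pooled" for all recipes.
    include_isolated
        Whether items that never co-occur stay in the node set (affects the
        density denominator).
    """

    def __init__(
        self,
        corpus: Corpus,
        level: str = "category",
        course: str = "pooled",
        include_isolated: bool = True,
    ):
        if not corpus.recipes:
            raise ValueError("empty corpus")
        self.corpus = corpus
        self.level = level
        self.course = course
        self.include_isolated = include_isolated

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        rules: NormalizationRuleSet | None = None,
        taxonomy: CategoryTaxonomy | None = None,
        course_map: Mapping[str, str] | None = None,
        schema: Mapping[str, str] | None = None,
        **kwargs,
    ) -> "CuisineNetworkStudy":
        """Build from a long-format table (one row per recipe-ingredient)."""
        from .corpus import DEFAULT_SCHEMA

        schema = {**DEFAULT_SCHEMA, **(schema or {})}
        records = [
            RawRecipeRecord(
                recipe_id=str(r[schema["recipe_id"]]),
                cuisine=str(r[schema["cuisine"]]),
                course=str(r[schema["course"]]),
                ingredient_raw=str(r[schema["ingredient"]]),
            )
            for r in df.to_dict("records")
        ]
        rules = rules or NormalizationRuleSet.identity()
        if taxonomy is None:
            raise ValueError("a CategoryTaxonomy is required")
        corpus = build_recipes(records, rules, taxonomy, course_map)
        return cls(corpus, **kwargs)

    @classmethod
    def from_simulation(
        cls, config: SimulationConfig, **kwargs
    ) -> "CuisineNetworkStudy":
        return cls(generate_corpus(config), **kwargs)

    def fit(
        self,
        seed: int = 0,
        comparability: ComparabilityConfig | None = None,
        robustness: RobustnessConfig | None = None,
    ) -> "StudyResults":
        """Run the analysis stages and collect them into a results object."""
        course = "all" if self.course == "pooled" else self.course
        networks: dict[str, CooccurrenceNetwork] = {}
        metrics: dict[str, MetricsReport] = {}
        for cuisine in self.corpus.cuisines:
            if not self.corpus.subset(cuisine, course):
                continue
            net = subset_network(
                self.corpus,
                cuisine,
                course,
                level=self.level,
                include_isolated=self.include_isolated,
            )
            networks[cuisine] = net
            metrics[cuisine] = metrics_report(net, seed=seed)
        sim = similarity_matrix(
            self.corpus,
            level=self.level,
            course=self.course,
            include_isolated=self.include_isolated,
        )
        comp = None
        if comparability is not None:
            scope = "pooled" if self.course == "pooled" else "per-course"
            comp = comparability_matrix(self.corpus, comparability, scope=scope)
        rob = None
        if robustness is not None:
            rob = robustness_table(self.corpus, robustness, levels=(self.level,))
        return StudyResults(
            study=self,
            networks=networks,
            metrics=metrics,
            similarity=sim,
            comparability=comp,
            robustness=rob,
            seed=seed,
        )


@dataclass
class StudyResults:
    """Fitted networks, metric reports, and comparison tables."""

    study: CuisineNetworkStudy
    networks: dict[str, CooccurrenceNetwork]
    metrics: dict[str, MetricsReport]
    similarity: SimilarityMatrix
    comparability: dict[str, ComparabilityMatrix] | None = None
    robustness: pd.DataFrame | None = None
    seed: int = 0
    _summary_cache: str | None = field(default=None, repr=False)

    @property
    def density(self) -> pd.Series:
        return pd.Series(
            {c: r.density for c, r in self.metrics.items()}, name="density"
        )

    @property
    def modularity(self) -> pd.Series:
        return pd.Series(
            {c: r.modularity for c, r in self.metrics.items()}, name="modularity"
        )

    @property
    def avg_clustering(self) -> pd.Series:
        return pd.Series(
            {c: r.avg_clustering for c, r in self.metrics.items()},
            name="avg_clustering",
        )

    def weighted_degree_shares(self) -> pd.DataFrame:
        """Node x cuisine table of weighted-degree shares (%)."""
        cols = {
            c: rep.nodes_frame()["weighted_degree_share"]
            for c, rep in self.metrics.items()
        }
        return pd.DataFrame(cols)

    def network_metrics_frame(self) -> pd.DataFrame:
        rows = [r.to_dict() for r in self.metrics.values()]
        return pd.DataFrame(rows).set_index("cuisine")

    def corpus_summary(self) -> pd.DataFrame:
        return corpus_summary(self.study.corpus)

    def summary(self) -> str:
        """Plain-text study summary in the style of a fit report."""
        if self._summary_cache is not None:
            return self._summary_cache
        lines = []
        level, course = self.study.level, self.study.course
        n = len(self.study.corpus)
        lines.append("Cuisine co-occurrence network study")
        lines.append("=" * 60)
        lines.append(f"recipes: {n}   level: {level}   course: {course}")
        lines.append(f"cuisines: {', '.join(self.networks)}")
        lines.append("")
        lines.append("Network metrics")
        lines.append("-" * 60)
        frame = self.network_metrics_frame()[
            ["n", "m", "density", "avg_clustering", "modularity"]
        ]
        lines.append(frame.to_string(float_format=lambda v: f"{v:.4f}"))
        lines.append("")
        lines.append(f"Between-cuisine edge Jaccard ({level}, {course})")
        lines.append("-" * 60)
        lines.append(self.similarity.matrix.to_string(float_format=lambda v: f"{v:.4f}"))
        if self.comparability:
            for scope, mat in self.comparability.items():
                lines.append("")
                lines.append(f"Split-sample comparability p ({scope})")
                lines.append("-" * 60)
                lines.append(mat.p.to_string(float_format=lambda v: f"{v:.3f}"))
        if self.robustness is not None:
            lines.append("")
            lines.append("Robustness (subsample interval, swap-null p)")
            lines.append("-" * 60)
            cols = [
                "cuisine_a",
                "cuisine_b",
                "level",
                "interval_low",
                "interval_high",
                "observed",
                "null_mean",
                "p_value",
            ]
            lines.append(
                self.robustness[cols].to_string(
                    index=False, float_format=lambda v: f"{v:.4f}"
                )
            )
        self._summary_cache = "\n".join(lines)
        return self._summary_cache
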