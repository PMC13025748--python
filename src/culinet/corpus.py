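"""Recipe corpus loading, normalization and summarization.

A corpus arrives as a long-format table with one row per recipe-ingredient
occurrence (recipe id, cuisine, course, raw ingredient name).  Three curated
inputs turn raw rows into analysis-ready :class:`Recipe` objects:

* a :class:`NormalizationRuleSet` implementing the three-tier granularity
  strategy -- *retention* keeps culturally meaningful composites intact
  (e.g. ``churut``, ``roux``), *aggregation* merges functional equivalents
  (``macaroni``/``noodles`` -> ``dry pasta``), and *deconstruction* expands
  umbrella terms into components (``soup vegetables`` -> carrot, parsnip,
  celeriac).  A stoplist (default: salt and water) removes culinary
  super-hubs that would otherwise collapse the network topology.
* a :class:`CategoryTaxonomy` mapping every normalized ingredient to one of
  14 functional categories (meat, vegetable, grain, dairy, fat, spice,
  flavoring agent, fruit, egg, mushroom, alcohol, composite, offal,
  ancillaries).
* a course harmonization map collapsing local course subtypes onto the four
  canonical courses: appetizer, soup, main dish, dessert.

Within a recipe every ingredient is treated as present/absent: duplicate
rows collapse into a set, so textual style cannot inflate edge weights
downstream.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import (
    EmptyCorpusError,
    SchemaError,
    UnknownCourseError,
    UnmappedIngredientError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: The 14 functional ingredient categories used at the coarse analysis level.
CATEGORIES: tuple[str, ...] = (
    "meat",
    "vegetable",
    "grain",
    "dairy",
    "fat",
    "spice",
    "flavoring agent",
    "fruit",
    "egg",
    "mushroom",
    "alcohol",
    "composite",
    "offal",
    "ancillaries",
)

#: Canonical course labels after harmonization.
COURSES: tuple[str, ...] = ("appetizer", "soup", "main dish", "dessert")

DEFAULT_STOPLIST: frozenset[str] = frozenset({"salt", "water"})

#: Default column names for long-format input tables.
DEFAULT_SCHEMA: dict[str, str] = {
    "recipe_id": "recipe_id",
    "cuisine": "cuisine",
    "course": "course",
    "ingredient": "ingredient",
}


def clean_name(name: str) -> str:
    """Case-fold and whitespace-normalize an ingredient or label name."""
    return " ".join(str(name).strip().lower().split())


@dataclass(frozen=True)
class RawRecipeRecord:
    """One recipe-ingredient occurrence row from the input table."""

    recipe_id: str
    cuisine: str
    course: str
    ingredient_raw: str


@dataclass
class NormalizationRuleSet:
    """Ordered retention / deconstruction / aggregation rules plus stoplist.

    Precedence when a name matches several tiers is retention >
    deconstruction > aggregation: a declared cultural signature always wins
    over mechanical rewriting.  Matching is exact on case-folded,
    whitespace-trimmed strings.  The stoplist is applied *after* the rules so
    that a deconstruction can never reintroduce an excluded name.
    """

    retained: frozenset[str] = frozenset()
    aggregations: dict[str, str] = field(default_factory=dict)
    deconstructions: dict[str, tuple[str, ...]] = field(default_factory=dict)
    stoplist: frozenset[str] = DEFAULT_STOPLIST

    def __post_init__(self) -> None:
        self.retained = frozenset(clean_name(n) for n in self.retained)
        self.aggregations = {
            clean_name(k): clean_name(v) for k, v in self.aggregations.items()
        }
        self.deconstructions = {
            clean_name(k): tuple(clean_name(c) for c in comps)
            for k, comps in self.deconstructions.items()
        }
        self.stoplist = frozenset(clean_name(n) for n in self.stoplist)
        for name, comps in self.deconstructions.items():
            if not comps:
                raise ValidationError(
                    f"deconstruction of {name!r} has an empty component list"
                )
        tiers = [self.retained, set(self.deconstructions), set(self.aggregations)]
        seen: set[str] = set()
        for tier in tiers:
            dup = seen & tier
            if dup:
                raise ValidationError(
                    "names match more than one rule tier: " + ", ".join(sorted(dup))
                )
            seen |= tier

    def normalize(self, name: str) -> list[str]:
        """Map one raw name to zero or more normalized names."""
        cleaned = clean_name(name)
        if not cleaned:
            raise ValidationError("empty ingredient name")
        if cleaned in self.retained:
            out = [cleaned]
        elif cleaned in self.deconstructions:
            out = list(self.deconstructions[cleaned])
        elif cleaned in self.aggregations:
            out = [self.aggregations[cleaned]]
        else:
            out = [cleaned]
        return [n for n in out if n not in self.stoplist]

    @classmethod
    def identity(cls, stoplist: Iterable[str] = DEFAULT_STOPLIST) -> "NormalizationRuleSet":
        """Rules that only clean names and apply the stoplist."""
        return cls(stoplist=frozenset(stoplist))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NormalizationRuleSet":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            retained=frozenset(data.get("retained", ())),
            aggregations=dict(data.get("aggregations", {})),
            deconstructions={
                k: tuple(v) for k, v in (data.get("deconstructions", {})).items()
            },
            stoplist=frozenset(data.get("stoplist", DEFAULT_STOPLIST)),
        )

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "retained": sorted(self.retained),
            "aggregations": dict(sorted(self.aggregations.items())),
            "deconstructions": {
                k: list(v) for k, v in sorted(self.deconstructions.items())
            },
            "stoplist": sorted(self.stoplist),
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def normalize_ingredient(name: str, rules: NormalizationRuleSet) -> list[str]:
    """Apply the three-tier normalization to one raw name.

    Returns the (possibly empty) list of normalized names; stoplist members
    are removed after rule application.
    """
    return rules.normalize(name)


@dataclass
class CategoryTaxonomy:
    """Mapping from normalized ingredient names to the 14 categories."""

    mapping: dict[str, str]
    categories: tuple[str, ...] = CATEGORIES

    def __post_init__(self) -> None:
        if len(set(self.categories)) != 14:
            raise ValidationError(
                f"taxonomy must have exactly 14 category labels, got "
                f"{len(set(self.categories))}"
            )
        self.mapping = {clean_name(k): clean_name(v) for k, v in self.mapping.items()}
        bad = {v for v in self.mapping.values() if v not in self.categories}
        if bad:
            raise ValidationError(
                "mapping uses unknown categories: " + ", ".join(sorted(bad))
            )

    def __contains__(self, ingredient: str) -> bool:
        return clean_name(ingredient) in self.mapping

    def category_of(self, ingredient: str) -> str:
        return self.mapping[clean_name(ingredient)]

    def categories_of(self, ingredients: Iterable[str]) -> frozenset[str]:
        missing = [i for i in ingredients if i not in self.mapping]
        if missing:
            raise UnmappedIngredientError(missing)
        return frozenset(self.mapping[i] for i in ingredients)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CategoryTaxonomy":
        """Read a two-column table (ingredient, category)."""
        df = pd.read_csv(path, dtype=str)
        if df.shape[1] < 2:
            raise SchemaError("taxonomy CSV needs (ingredient, category) columns")
        ing, cat = df.columns[:2]
        return cls(mapping=dict(zip(df[ing], df[cat])))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.mapping.items()), columns=["ingredient", "category"]
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class Recipe:
    """One dish: cuisine, canonical course, and its normalized ingredient set."""

    recipe_id: str
    cuisine: str
    course: str
    ingredients: frozenset[str]
    categories: frozenset[str] = frozenset()


@dataclass
class Corpus:
    """A list of recipes plus the taxonomy used to build them."""

    recipes: list[Recipe]
    taxonomy: CategoryTaxonomy | None = None

    def __len__(self) -> int:
        return len(self.recipes)

    @property
    def vocabulary(self) -> set[str]:
        vocab: set[str] = set()
        for r in self.recipes:
            vocab |= r.ingredients
        return vocab

    @property
    def cuisines(self) -> list[str]:
        """Cuisine labels in order of first appearance."""
        seen: dict[str, None] = {}
        for r in self.recipes:
            seen.setdefault(r.cuisine, None)
        return list(seen)

    @property
    def counts(self) -> dict[tuple[str, str], int]:
        return dict(Counter((r.cuisine, r.course) for r in self.recipes))

    def subset(self, cuisine: str = "all", course: str = "all") -> list[Recipe]:
        return [
            r
            for r in self.recipes
            if (cuisine == "all" or r.cuisine == cuisine)
            and (course == "all" or r.course == course)
        ]

    def to_frame(self) -> pd.DataFrame:
        """Long-format normalized table with a category column."""
        rows = []
        for r in self.recipes:
            for ing in sorted(r.ingredients):
                cat = (
                    self.taxonomy.category_of(ing)
                    if self.taxonomy is not None and ing in self.taxonomy
                    else ""
                )
                rows.append((r.recipe_id, r.cuisine, r.course, ing, cat))
        return pd.DataFrame(
            rows, columns=["recipe_id", "cuisine", "course", "ingredient", "category"]
        )


def load_corpus(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> list[RawRecipeRecord]:
    """Read a long-format recipe table into raw records.

    ``schema`` maps the logical names (recipe_id, cuisine, course,
    ingredient) to the file's actual column names.  Rows with an empty
    ingredient or recipe id are rejected and reported by row index.
    """
    path = Path(path)
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyCorpusError(f"{path} is empty") from None
    missing = [c for c in schema.values() if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path} is missing required columns: {', '.join(missing)} "
            f"(present: {', '.join(df.columns)})"
        )
    if df.empty:
        raise EmptyCorpusError(f"{path} has a header but no rows")
    records: list[RawRecipeRecord] = []
    rejected: list[int] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        rid = str(row[schema["recipe_id"]]).strip()
        ing = str(row[schema["ingredient"]]).strip()
        if not rid or not ing:
            rejected.append(idx)
            continue
        records.append(
            RawRecipeRecord(
                recipe_id=rid,
                cuisine=str(row[schema["cuisine"]]).strip(),
                course=str(row[schema["course"]]).strip(),
                ingredient_raw=ing,
            )
        )
    if rejected:
        logger.warning(
            "rejected %d rows with empty recipe_id/ingredient at indices %s",
            len(rejected),
            rejected[:20],
        )
    if not records:
        raise EmptyCorpusError(f"{path} contains no usable rows")
    return records


def identity_course_map() -> dict[str, str]:
    return {c: c for c in COURSES}


def build_recipes(
    records: Sequence[RawRecipeRecord],
    rules: NormalizationRuleSet,
    taxonomy: CategoryTaxonomy,
    course_map: Mapping[str, str] | None = None,
) -> Corpus:
    """Assemble normalized :class:`Recipe` objects from raw records.

    Ingredient sets are deduplicated; recipes emptied by the stoplist are
    dropped (they contribute no co-occurrence edges) and logged.  Unknown
    course labels and taxonomy gaps are hard errors, never silently binned.
    """
    course_map = {clean_name(k): v for k, v in (course_map or identity_course_map()).items()}
    grouped: dict[str, list[RawRecipeRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.recipe_id not in grouped:
            order.append(rec.recipe_id)
        grouped.setdefault(rec.recipe_id, []).append(rec)

    recipes: list[Recipe] = []
    dropped: list[str] = []
    unmapped: set[str] = set()
    for rid in order:
        rows = grouped[rid]
        cuisines = {r.cuisine for r in rows}
        raw_courses = {clean_name(r.course) for r in rows}
        if len(cuisines) > 1 or len(raw_courses) > 1:
            raise ValidationError(
                f"recipe {rid!r} has inconsistent cuisine/course labels"
            )
        raw_course = raw_courses.pop()
        if raw_course not in course_map:
            raise UnknownCourseError(
                f"recipe {rid!r}: course {raw_course!r} not in harmonization map"
            )
        course = course_map[raw_course]
        if course not in COURSES:
            raise UnknownCourseError(
                f"course map sends {raw_course!r} to non-canonical {course!r}"
            )
        ingredients: set[str] = set()
        for r in rows:
            ingredients.update(rules.normalize(r.ingredient_raw))
        if not ingredients:
            dropped.append(rid)
            continue
        missing = [i for i in ingredients if i not in taxonomy]
        if missing:
            unmapped.update(missing)
            continue
        recipes.append(
            Recipe(
                recipe_id=rid,
                cuisine=rows[0].cuisine,
                course=course,
                ingredients=frozenset(ingredients),
                categories=taxonomy.categories_of(ingredients),
            )
        )
    if unmapped:
        raise UnmappedIngredientError(unmapped)
    if dropped:
        logger.info(
            "dropped %d recipes emptied by the stoplist: %s",
            len(dropped),
            dropped[:20],
        )
    if not recipes:
        raise EmptyCorpusError("no recipes survived normalization")
    return Corpus(recipes=recipes, taxonomy=taxonomy)


def corpus_summary(corpus: Corpus) -> pd.DataFrame:
    """Cuisine x course recipe-count table with row/column totals."""
    if not corpus.recipes:
        raise EmptyCorpusError("cannot summarize an empty corpus")
    counts = corpus.counts
    cuisines = corpus.cuisines
    data = {
        course: [counts.get((c, course), 0) for c in cuisines] for course in COURSES
    }
    df = pd.DataFrame(data, index=cuisines)
    df["total"] = df.sum(axis=1)
    df.loc["total"] = df.sum(axis=0)
    return df
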