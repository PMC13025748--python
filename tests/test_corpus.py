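"""Corpus loading, three-tier normalization, and summary invariants."""

import pandas as pd
import pytest

from culinet.corpus import (
    COURSES,
    CategoryTaxonomy,
    NormalizationRuleSet,
    RawRecipeRecord,
    build_recipes,
    corpus_summary,
    load_corpus,
    normalize_ingredient,
)
from culinet.errors import (
    EmptyCorpusError,
    SchemaError,
    UnknownCourseError,
    UnmappedIngredientError,
    ValidationError,
)


@pytest.fixture
def rules():
    return NormalizationRuleSet(
        retained=frozenset({"churut", "roux"}),
        aggregations={"macaroni": "dry pasta", "noodles": "dry pasta"},
        deconstructions={"soup vegetables": ("carrot", "parsnip", "celeriac")},
    )


class TestNormalization:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("soup vegetables", ["carrot", "parsnip", "celeriac"]),
            ("macaroni", ["dry pasta"]),
            ("noodles", ["dry pasta"]),
            ("churut", ["churut"]),
            ("salt", []),
            ("water", []),
            ("  Onion  ", ["onion"]),
        ],
    )
    def test_three_tier_examples(self, rules, raw, expected):
        assert normalize_ingredient(raw, rules) == expected

    def test_empty_name_rejected(self, rules):
        with pytest.raises(ValidationError):
            normalize_ingredient("   ", rules)

    def test_idempotent_on_normalized_names(self, rules):
        raws = ["soup vegetables", "macaroni", "churut", "beef", "Onion"]
        normalized = [n for raw in raws for n in rules.normalize(raw)]
        for name in normalized:
            assert rules.normalize(name) == [name]

    def test_overlapping_tiers_rejected(self):
        with pytest.raises(ValidationError):
            NormalizationRuleSet(
                retained=frozenset({"churut"}),
                aggregations={"churut": "dairy drink"},
            )

    def test_stoplist_applied_after_deconstruction(self):
        rules = NormalizationRuleSet(
            deconstructions={"brine": ("water", "salt", "vinegar")}
        )
        assert rules.normalize("brine") == ["vinegar"]

    def test_yaml_roundtrip(self, rules, tmp_path):
        path = tmp_path / "rules.yaml"
        rules.to_yaml(path)
        loaded = NormalizationRuleSet.from_yaml(path)
        assert loaded == rules


class TestLoadCorpus:
    def _write(self, tmp_path, rows, columns=None):
        columns = columns or ["recipe_id", "cuisine", "course", "ingredient"]
        path = tmp_path / "corpus.csv"
        pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
        return path

    def test_one_recipe_three_ingredients(self, tmp_path):
        path = self._write(
            tmp_path,
            [
                ("r1", "Hungarian", "soup", "beef"),
                ("r1", "Hungarian", "soup", "onion"),
                ("r1", "Hungarian", "soup", "carrot"),
            ],
        )
        records = load_corpus(path)
        assert len(records) == 3
        assert {r.recipe_id for r in records} == {"r1"}

    def test_missing_column_is_schema_error(self, tmp_path):
        path = self._write(
            tmp_path,
            [("r1", "Hungarian", "beef")],
            columns=["recipe_id", "cuisine", "ingredient"],
        )
        with pytest.raises(SchemaError):
            load_corpus(path)

    def test_empty_file_is_empty_corpus_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(EmptyCorpusError):
            load_corpus(path)

    def test_empty_ingredient_rows_rejected(self, tmp_path):
        path = self._write(
            tmp_path,
            [
                ("r1", "Hungarian", "soup", "beef"),
                ("r1", "Hungarian", "soup", ""),
            ],
        )
        records = load_corpus(path)
        assert len(records) == 1

    def test_custom_schema(self, tmp_path):
        path = self._write(
            tmp_path,
            [("r1", "Hungarian", "soup", "beef")],
            columns=["id", "nation", "dish_type", "item"],
        )
        records = load_corpus(
            path,
            schema={
                "recipe_id": "id",
                "cuisine": "nation",
                "course": "dish_type",
                "ingredient": "item",
            },
        )
        assert records[0].ingredient_raw == "beef"


class TestBuildRecipes:
    def _records(self, spec):
        return [
            RawRecipeRecord(rid, "Hungarian", course, ing)
            for rid, course, ings in spec
            for ing in ings
        ]

    def test_stoplist_only_recipe_dropped(self, pantry_taxonomy):
        records = self._records(
            [("r1", "soup", ["salt", "water"]), ("r2", "soup", ["beef", "onion"])]
        )
        corpus = build_recipes(
            records, NormalizationRuleSet.identity(), pantry_taxonomy
        )
        assert [r.recipe_id for r in corpus.recipes] == ["r2"]

    def test_stoplist_removed_categories_populated(self, pantry_taxonomy):
        records = self._records([("r1", "main dish", ["beef", "salt", "onion"])])
        corpus = build_recipes(
            records, NormalizationRuleSet.identity(), pantry_taxonomy
        )
        (recipe,) = corpus.recipes
        assert recipe.ingredients == {"beef", "onion"}
        assert recipe.categories == {"meat", "vegetable"}

    def test_duplicate_rows_collapse(self, pantry_taxonomy):
        records = self._records([("r1", "soup", ["beef", "beef", "onion"])])
        corpus = build_recipes(
            records, NormalizationRuleSet.identity(), pantry_taxonomy
        )
        assert corpus.recipes[0].ingredients == {"beef", "onion"}

    def test_unmapped_ingredient_lists_offenders(self, pantry_taxonomy):
        records = self._records([("r1", "soup", ["beef", "dragonfruit"])])
        with pytest.raises(UnmappedIngredientError) as exc:
            build_recipes(records, NormalizationRuleSet.identity(), pantry_taxonomy)
        assert "dragonfruit" in str(exc.value)

    def test_unknown_course_is_error(self, pantry_taxonomy):
        records = self._records([("r1", "brunch", ["beef"])])
        with pytest.raises(UnknownCourseError):
            build_recipes(records, NormalizationRuleSet.identity(), pantry_taxonomy)

    def test_course_harmonization(self, pantry_taxonomy):
        records = self._records([("r1", "torte", ["sugar", "egg"])])
        corpus = build_recipes(
            records,
            NormalizationRuleSet.identity(),
            pantry_taxonomy,
            course_map={"torte": "dessert"},
        )
        assert corpus.recipes[0].course == "dessert"

    def test_no_stoplist_member_survives(self, pantry_taxonomy):
        records = self._records(
            [("r1", "soup", ["beef", "salt"]), ("r2", "soup", ["onion", "water"])]
        )
        corpus = build_recipes(
            records, NormalizationRuleSet.identity(), pantry_taxonomy
        )
        for r in corpus.recipes:
            assert not (r.ingredients & {"salt", "water"})


class TestSummary:
    def test_counts_conserved(self, pantry_taxonomy):
        records = [
            RawRecipeRecord(f"r{i}", "Hungarian", course, ing)
            for i, course in enumerate(COURSES * 5)
            for ing in ("beef", "onion")
        ]
        corpus = build_recipes(
            records, NormalizationRuleSet.identity(), pantry_taxonomy
        )
        table = corpus_summary(corpus)
        assert table.loc["Hungarian", list(COURSES)].tolist() == [5, 5, 5, 5]
        assert table.loc["total", "total"] == len(corpus.recipes) == 20


class TestTaxonomy:
    def test_exactly_14_categories_required(self):
        with pytest.raises(ValidationError):
            CategoryTaxonomy(mapping={}, categories=("meat", "dairy"))

    def test_unknown_category_rejected(self):
        with pytest.raises(ValidationError):
            CategoryTaxonomy(mapping={"beef": "protein"})

    def test_csv_roundtrip(self, pantry_taxonomy, tmp_path):
        path = tmp_path / "taxonomy.csv"
        pantry_taxonomy.to_csv(path)
        loaded = CategoryTaxonomy.from_csv(path)
        assert loaded.mapping == pantry_taxonomy.mapping
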