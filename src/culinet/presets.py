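"""Bundled corpus presets.

The Transylvanian preset mirrors the cuisine-by-course cell structure of the
harmonized historical cookbook corpus the package was built around: five
ethnic cuisines (Hungarian, Romanian, Armenian, Jewish, Transylvanian
Saxon), four courses, 1409 recipes in total, with the published per-cell
recipe counts and a kosher-style meat-dairy exclusion for the Jewish
cuisine.  The generated ingredients are synthetic; only the corpus shape
(cell counts, recipe sizes, shared-core structure) is realistic.
"""

from __future__ import annotations

from .simulate import SimulationConfig

CUISINES: tuple[str, ...] = (
    "Hungarian",
    "Romanian",
    "Armenian",
    "Jewish",
    "Saxon",
)

#: Published recipe counts per (cuisine, course) cell of the harmonized
#: historical corpus; the grand total is 1409.
CELL_COUNTS: dict[tuple[str, str], int] = {
    ("Hungarian", "appetizer"): 33,
    ("Hungarian", "soup"): 119,
    ("Hungarian", "main dish"): 338,
    ("Hungarian", "dessert"): 416,
    ("Romanian", "appetizer"): 18,
    ("Romanian", "soup"): 19,
    ("Romanian", "main dish"): 93,
    ("Romanian", "dessert"): 92,
    ("Armenian", "appetizer"): 43,
    ("Armenian", "soup"): 34,
    ("Armenian", "main dish"): 68,
    ("Armenian", "dessert"): 60,
    ("Jewish", "appetizer"): 11,
    ("Jewish", "soup"): 2,
    ("Jewish", "main dish"): 24,
    ("Jewish", "dessert"): 6,
    ("Saxon", "appetizer"): 2,
    ("Saxon", "soup"): 16,
    ("Saxon", "main dish"): 10,
    ("Saxon", "dessert"): 5,
}


def transylvanian_preset(seed: int = 0) -> SimulationConfig:
    """Synthetic corpus with the historical corpus' cell structure.

    Pool sizes and overlap are chosen so the pooled ingredient vocabulary is
    a few hundred names (the order observed in curated cookbook corpora)
    with a substantial shared regional core; the Jewish cuisine carries the
    meat-dairy exclusion.
    """
    return SimulationConfig(
        cuisines=CUISINES,
        recipes_per_cell=CELL_COUNTS,
        shared_pool_size=120,
        private_pool_size=50,
        overlap=0.6,
        recipe_size=(3, 15, 6),
        forbidden_pairs={"Jewish": frozenset({frozenset({"meat", "dairy"})})},
        seed=seed,
    )
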