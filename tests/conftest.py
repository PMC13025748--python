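import math
from itertools import combinations

import pytest

from culinet.corpus import CATEGORIES, CategoryTaxonomy, Recipe


def mk_recipe(rid, ingredients, cuisine="X", course="main dish", categories=()):
    return Recipe(
        recipe_id=str(rid),
        cuisine=cuisine,
        course=course,
        ingredients=frozenset(ingredients),
        categories=frozenset(categories),
    )


@pytest.fixture
def pantry_taxonomy():
    """Small hand-written taxonomy covering the unit-test ingredients."""
    mapping = {
        "beef": "meat",
        "chicken": "meat",
        "goose": "meat",
        "milk": "dairy",
        "sour cream": "dairy",
        "churut": "composite",
        "roux": "composite",
        "onion": "vegetable",
        "carrot": "vegetable",
        "parsnip": "vegetable",
        "celeriac": "vegetable",
        "flour": "grain",
        "dry pasta": "grain",
        "lard": "fat",
        "oil": "fat",
        "paprika": "spice",
        "pepper": "spice",
        "vinegar": "flavoring agent",
        "sugar": "flavoring agent",
        "apple": "fruit",
        "plum": "fruit",
        "egg": "egg",
        "mushroom": "mushroom",
        "rum": "alcohol",
        "liver": "offal",
        "baking soda": "ancillaries",
    }
    return CategoryTaxonomy(mapping=mapping)


def random_recipes(rng, n_recipes=8, vocab=15, size_range=(2, 5), cuisine="X"):
    vocabulary = [f"i{k:02d}" for k in range(vocab)]
    out = []
    for r in range(n_recipes):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        items = rng.choice(vocabulary, size=size, replace=False)
        out.append(mk_recipe(f"r{r}", items, cuisine=cuisine))
    return out


def brute_force_betweenness(graph):
    """Exhaustive shortest-path enumeration; normalized like the package."""
    nodes = sorted(graph)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        best = [math.inf]
        paths = []

        def dfs(cur, visited, path):
            if len(path) - 1 > best[0]:
                return
            if cur == t:
                length = len(path) - 1
                if length < best[0]:
                    best[0] = length
                    paths.clear()
                if length == best[0]:
                    paths.append(list(path))
                return
            for nb in graph[cur]:
                if nb not in visited:
                    visited.add(nb)
                    path.append(nb)
                    dfs(nb, visited, path)
                    path.pop()
                    visited.remove(nb)

        dfs(s, {s}, [s])
        if not paths:
            continue
        sigma = len(paths)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            score[v] += through / sigma
    norm = (n - 1) * (n - 2) / 2
    return {v: sc / norm for v, sc in score.items()}


def brute_force_avg_clustering(graph):
    """Triangle counting per node, averaged over all nodes."""
    total = 0.0
    for v in graph:
        nbrs = list(graph[v])
        k = len(nbrs)
        if k < 2:
            continue
        e = sum(1 for a, b in combinations(nbrs, 2) if graph.has_edge(a, b))
        total += 2.0 * e / (k * (k - 1))
    return total / graph.number_of_nodes()


def random_connected_graph(rng, max_nodes=8):
    """Random connected graph: a random spanning tree plus random extra edges."""
    import networkx as nx

    n = int(rng.integers(3, max_nodes + 1))
    nodes = [f"n{i}" for i in range(n)]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    order = list(rng.permutation(n))
    for i in range(1, n):
        j = int(rng.integers(0, i))
        g.add_edge(nodes[order[i]], nodes[order[j]], weight=int(rng.integers(1, 5)))
    for u, v in combinations(nodes, 2):
        if not g.has_edge(u, v) and rng.random() < 0.3:
            g.add_edge(u, v, weight=int(rng.integers(1, 5)))
    return g
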