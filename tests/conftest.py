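"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results by brute force — recursive
deep equality, path-wise tree copying, all-pairs partitioning, per-term
lookup — without touching the hashing/grouping code paths they check.
"""

from __future__ import annotations

import random
import unicodedata
from typing import Dict, List, Sequence, Tuple

import pytest

from mzmeta.model import SourceFloat

# ---------------------------------------------------------------------------
# Deep-equality oracle (independent of canonical_serialize)
# ---------------------------------------------------------------------------


def leaf_token(value) -> tuple:
    """Type-aware token for a leaf: decimals by source text, strings NFC."""
    if value is None:
        return ("null",)
    if isinstance(value, bool):
        return ("bool", value)
    if isinstance(value, SourceFloat):
        return ("float", unicodedata.normalize("NFC", value.text))
    if isinstance(value, float):
        return ("float", repr(value))
    if isinstance(value, int):
        return ("int", value)
    return ("str", unicodedata.normalize("NFC", value))


def deep_equal(a, b) -> bool:
    """Recursive content equality of two parameter trees."""
    a_is_tree, b_is_tree = isinstance(a, dict), isinstance(b, dict)
    if a_is_tree != b_is_tree:
        return False
    if not a_is_tree:
        return leaf_token(a) == leaf_token(b)
    norm_a = {unicodedata.normalize("NFC", k): v for k, v in a.items()}
    norm_b = {unicodedata.normalize("NFC", k): v for k, v in b.items()}
    if set(norm_a) != set(norm_b):
        return False
    return all(deep_equal(norm_a[k], norm_b[k]) for k in norm_a)


def brute_force_partition(named_trees: Sequence[Tuple[str, dict]]
                          ) -> List[List[str]]:
    """O(N²) all-pairs partition by deep equality.

    Returns groups ordered by first member in lexicographic name order,
    members sorted — the same convention the grouping engine uses.
    """
    ordered = sorted(named_trees, key=lambda item: item[0])
    groups: List[Tuple[dict, List[str]]] = []
    for name, tree in ordered:
        for representative, members in groups:
            if deep_equal(tree, representative):
                members.append(name)
                break
        else:
            groups.append((tree, [name]))
    return [sorted(members) for _, members in groups]


# ---------------------------------------------------------------------------
# Random tree generation (seeded, hypothesis-free for the big corpora)
# ---------------------------------------------------------------------------

_WORDS = ("Tune", "Method", "Spray voltage", "Resolution", "AGC", "µl",
          "Scan range", "Ion source", "positive", "Ångström", "m/z")


def random_leaf(rng: random.Random):
    kind = rng.randrange(5)
    if kind == 0:
        return rng.choice(_WORDS) + str(rng.randrange(100))
    if kind == 1:
        return rng.randrange(-1000, 100000)
    if kind == 2:
        return SourceFloat(f"{rng.randrange(0, 500)}.{rng.randrange(100):02d}")
    if kind == 3:
        return rng.random() < 0.5
    return None


def random_tree(rng: random.Random, depth: int = 3, breadth: int = 4) -> dict:
    tree = {}
    for i in range(rng.randrange(1, breadth + 1)):
        key = f"{rng.choice(_WORDS)} {i}"
        if depth > 0 and rng.random() < 0.35:
            tree[key] = random_tree(rng, depth - 1, breadth)
        else:
            tree[key] = random_leaf(rng)
    return tree


def shuffled_copy(tree: dict, rng: random.Random) -> dict:
    keys = list(tree)
    rng.shuffle(keys)
    return {
        k: shuffled_copy(tree[k], rng) if isinstance(tree[k], dict) else tree[k]
        for k in keys
    }


def leaf_paths(tree: dict, prefix=()) -> list:
    paths = []
    for key, value in tree.items():
        if isinstance(value, dict):
            paths.extend(leaf_paths(value, (*prefix, key)))
        else:
            paths.append((*prefix, key))
    return paths


def perturb_one_leaf(tree: dict, rng: random.Random) -> dict:
    """Copy with exactly one leaf changed to a differently-rendered value."""
    from mzmeta.model import copy_tree, render_scalar

    result = copy_tree(tree)
    paths = leaf_paths(result)
    if not paths:
        result["added leaf"] = 1
        return result
    path = rng.choice(paths)
    node = result
    for key in path[:-1]:
        node = node[key]
    old = node[path[-1]]
    while True:
        new = random_leaf(rng)
        if render_scalar(new) != render_scalar(old):
            node[path[-1]] = new
            return result


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240301)
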