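"""Shared fixtures and independent oracles."""

from __future__ import annotations

import itertools
import random

import dendropy
import numpy as np
import pytest
from hypothesis import settings

import paleomt as pm

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def genome_16k() -> str:
    rng = np.random.default_rng(20170)
    return "".join(rng.choice(list("ACGT"), size=16000))


@pytest.fixture(scope="session")
def genome_4k() -> str:
    rng = np.random.default_rng(20171)
    return "".join(rng.choice(list("ACGT"), size=4000))


# ---------------------------------------------------------------------------
# Brute-force small-parsimony oracle
# ---------------------------------------------------------------------------


def brute_force_parsimony_score(tree: dendropy.Tree, column: dict[str, str | None]) -> int:
    """Exhaustive minimum number of state changes for one column.

    Enumerates every assignment of A/C/G/T to the internal nodes and counts
    mismatched edges.  A missing leaf (None) contributes no cost for any
    parent state (it can always copy its parent), so only internal nodes
    need enumeration — this stays exact.
    """
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    leaves = [n for n in tree.leaf_node_iter()]
    best = None
    for combo in itertools.product("ACGT", repeat=len(internal)):
        assign = {id(n): s for n, s in zip(internal, combo)}
        cost = 0
        for node in internal:
            if node.parent_node is not None:
                cost += assign[id(node)] != assign[id(node.parent_node)]
        for leaf in leaves:
            obs = column.get(leaf.taxon.label)
            if obs is not None:
                cost += obs != assign[id(leaf.parent_node)]
        if best is None or cost < best:
            best = cost
    return int(best)


def random_tree(rnd: random.Random, n_leaves: int, allow_polytomy: bool = True) -> dendropy.Tree:
    """Random rooted tree over labelled leaves, optionally multifurcating."""
    nodes = [f"L{i}" for i in range(n_leaves)]
    while len(nodes) > 1:
        if allow_polytomy and len(nodes) > 2 and rnd.random() < 0.3:
            k = rnd.randint(3, min(4, len(nodes)))
        else:
            k = 2
        picked = rnd.sample(range(len(nodes)), k)
        children = [nodes[i] for i in picked]
        for i in sorted(picked, reverse=True):
            nodes.pop(i)
        nodes.append("(" + ",".join(children) + ")")
    tree = dendropy.Tree.get(
        data=nodes[0] + ";", schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    return tree


def random_column(rnd: random.Random, labels: list[str], p_missing: float = 0.15) -> dict:
    return {
        l: (None if rnd.random() < p_missing else rnd.choice("ACGT")) for l in labels
    }


@pytest.fixture
def small_clade_config() -> pm.SimulationConfig:
    """Scaled-down clade simulation for fast unit tests."""
    return pm.SimulationConfig(
        seed=1,
        genome_length=2000,
        clade_sizes={"I": 4, "II": 3, "III": 3},
        stem_mutations={"I": 12, "II": 10, "III": 8},
        homoplasy_injections={("I", "II"): 3, ("II", "III"): 4, ("I", "III"): 2},
        within_clade_mutations=2,
        outgroup_mutations=40,
    )
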