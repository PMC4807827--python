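"""Shared fixtures and independent oracles.

The brute-force subtree oracle unions tip-to-MRCA paths edge by edge on the
dendropy node structure — deliberately different mechanics from the
edge/tip-incidence kernel it cross-checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from divnull import OccurrenceTable, PhyloTree, TraitTable


def make_random_tree(rng: np.random.Generator, n_tips: int) -> PhyloTree:
    """Random binary topology with uniform branch lengths (not ultrametric)."""
    parts = [f"t{i}:{rng.uniform(0.1, 2.0):.6f}" for i in range(n_tips)]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a},{b}):{rng.uniform(0.0, 2.0):.6f}")
    newick = parts[0]
    newick = newick[: newick.rfind(":")] + ";"  # drop the root edge length
    return PhyloTree.from_newick(newick)


def brute_subtree_sum(tree: PhyloTree, tips, include_root: bool = False) -> float:
    """Union of tip-to-MRCA (or tip-to-root) paths, summed edge by edge."""
    taxa = {leaf.taxon.label: leaf for leaf in tree.tree.leaf_node_iter()}
    nodes = [taxa[t] for t in tips]

    def path_to_root(node):
        chain = []
        while node.parent_node is not None:
            chain.append(node)
            node = node.parent_node
        return chain

    paths = [path_to_root(n) for n in nodes]
    if include_root:
        edges = {id(n): n for p in paths for n in p}
        return sum(n.edge.length or 0.0 for n in edges.values())
    ancestor_sets = [set(id(n) for n in p) for p in paths]
    common = set.intersection(*ancestor_sets) if ancestor_sets else set()
    # MRCA-rooted subtree: drop edges every tip's path shares (above the MRCA)
    edges = {id(n): n for p in paths for n in p if id(n) not in common}
    return sum(n.edge.length or 0.0 for n in edges.values())


def make_random_traits(rng: np.random.Generator, n_species: int) -> TraitTable:
    species = [f"t{i}" for i in range(n_species)]
    frame = pd.DataFrame(
        {
            "mass": rng.uniform(0, 10, n_species),
            "depth": rng.normal(size=n_species),
            "guild": rng.choice(["graz", "filt", "pred"], n_species),
        },
        index=species,
    )
    # guard the >=2-level invariant for tiny n
    if frame["guild"].nunique() < 2:
        frame.loc[species[0], "guild"] = "graz"
        frame.loc[species[1], "guild"] = "filt"
    return TraitTable(
        frame,
        {"mass": "continuous", "depth": "continuous", "guild": "categorical"},
    )


def make_random_occurrences(
    rng: np.random.Generator, n_sites: int = 4, n_species: int = 8
) -> OccurrenceTable:
    species = [f"t{i}" for i in range(n_species)]
    assemblages = {}
    for s in range(n_sites):
        wet = rng.choice(n_species, size=rng.integers(2, n_species), replace=False)
        n_dry = int(rng.integers(1, len(wet) + 1))
        dry = rng.choice(wet, size=n_dry, replace=False)
        assemblages[(f"s{s}", "wet")] = [species[i] for i in wet]
        assemblages[(f"s{s}", "dry")] = [species[i] for i in dry]
    return OccurrenceTable.from_assemblages(assemblages, species=species)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


@pytest.fixture
def tiny_tree() -> PhyloTree:
    return PhyloTree.from_newick("((A:1,B:1):2,C:3);")


@pytest.fixture
def three_species_traits() -> TraitTable:
    frame = pd.DataFrame(
        {"guild": ["a", "a", "b"], "size": [0.0, 5.0, 10.0]},
        index=["s1", "s2", "s3"],
    )
    return TraitTable(frame, {"guild": "categorical", "size": "continuous"})
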