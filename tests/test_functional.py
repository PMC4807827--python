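"""Gower distance, UPGMA dendrograms and dendrogram-based FD."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

import divnull as dn
from divnull.errors import InputError

from conftest import brute_subtree_sum, make_random_traits


def gower_loop_oracle(traits: dn.TraitTable) -> np.ndarray:
    """Per-pair, per-trait python loop straight from the definition."""
    species = list(traits.species)
    n = len(species)
    ranges = {}
    for trait, kind in traits.types.items():
        if kind == "continuous":
            col = traits.values[trait].astype(float)
            ranges[trait] = col.max() - col.min()
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            terms = []
            for trait, kind in traits.types.items():
                xi = traits.values[trait].iloc[i]
                xj = traits.values[trait].iloc[j]
                if pd.isna(xi) or pd.isna(xj):
                    continue
                if kind == "continuous":
                    terms.append(abs(float(xi) - float(xj)) / ranges[trait])
                else:
                    terms.append(0.0 if xi == xj else 1.0)
            out[i, j] = sum(terms) / len(terms)
    return out


class TestGower:
    def test_hand_example(self, three_species_traits):
        d = dn.gower_distance(three_species_traits)
        assert d.value("s1", "s2") == pytest.approx(0.25)
        assert d.value("s1", "s3") == pytest.approx(1.0)
        assert d.value("s2", "s3") == pytest.approx(0.75)

    def test_identical_and_opposite_species(self):
        frame = pd.DataFrame(
            {"a": ["x", "x", "y"], "b": [0.0, 0.0, 1.0]}, index=["p", "q", "r"]
        )
        traits = dn.TraitTable(frame, {"a": "categorical", "b": "continuous"})
        d = dn.gower_distance(traits)
        assert d.value("p", "q") == 0.0  # identical in every trait
        assert d.value("p", "r") == 1.0  # categorical mismatch + range extremes

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_per_trait_loop_oracle(self, seed):
        traits = make_random_traits(np.random.default_rng(seed), 7)
        got = dn.gower_distance(traits).matrix
        np.testing.assert_allclose(got, gower_loop_oracle(traits), atol=1e-12)

    def test_invariant_under_relabel_and_affine_rescale(self, rng):
        traits = make_random_traits(rng, 6)
        base = dn.gower_distance(traits).matrix
        values = traits.values.copy()
        values["mass"] = values["mass"] * 3.5 - 12.0  # affine rescale
        values["guild"] = values["guild"].map(
            {"graz": "Z1", "filt": "Z2", "pred": "Z3"}
        )
        again = dn.gower_distance(dn.TraitTable(values, traits.types)).matrix
        np.testing.assert_allclose(again, base, atol=1e-12)

    def test_missing_values_reweighted(self):
        frame = pd.DataFrame(
            {"a": [0.0, 1.0, 0.5], "b": ["x", np.nan, "y"]}, index=["p", "q", "r"]
        )
        traits = dn.TraitTable(frame, {"a": "continuous", "b": "categorical"})
        d = dn.gower_distance(traits)
        # p-q: only trait a observed jointly -> |0-1|/1 = 1, not (1+?)/2
        assert d.value("p", "q") == pytest.approx(1.0)
        assert d.value("p", "r") == pytest.approx((0.5 + 1.0) / 2)

    def test_no_shared_trait_pair_rejected(self):
        frame = pd.DataFrame(
            {"a": [0.0, np.nan, 1.0], "b": [np.nan, "x", "y"]},
            index=["p", "q", "r"],
        )
        traits = dn.TraitTable(frame, {"a": "continuous", "b": "categorical"})
        with pytest.raises(InputError, match="no observed trait"):
            dn.gower_distance(traits)


class TestUpgma:
    def test_two_species(self):
        d = dn.DistanceTable(["a", "b"], np.array([[0.0, 0.6], [0.6, 0.0]]))
        dend = dn.upgma(d)
        assert dend.height == pytest.approx(0.3)
        assert dend.total_length == pytest.approx(0.6)
        assert dend.cophenetic("a", "b") == pytest.approx(0.6)

    def test_three_species_hand_trace(self):
        # d(1,2)=.2, d(1,3)=d(2,3)=.8 -> merge (1,2) at height .1, root at .4
        m = np.array([[0, 0.2, 0.8], [0.2, 0, 0.8], [0.8, 0.8, 0]])
        dend = dn.upgma(dn.DistanceTable(["x1", "x2", "x3"], m))
        assert dend.height == pytest.approx(0.4)
        # edges: tips x1,x2 -> .1 each; internal -> .3; tip x3 -> .4
        assert dend.total_length == pytest.approx(0.1 + 0.1 + 0.3 + 0.4)
        assert dn.dendrogram_fd(dend, ["x1", "x2"]) == pytest.approx(0.2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_average_linkage(self, seed):
        """Cophenetic distances agree with an independent agglomeration."""
        rng = np.random.default_rng(seed)
        n = 9
        # continuous random distances: ties have probability zero
        condensed = rng.uniform(0.05, 1.0, n * (n - 1) // 2)
        labels = [f"t{i}" for i in range(n)]
        dend = dn.upgma(dn.DistanceTable(labels, squareform(condensed)))
        ours = np.array(
            [
                [dend.cophenetic(a, b) for b in labels] for a in labels
            ]
        )
        theirs = squareform(cophenet(linkage(condensed, method="average")))
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_ultrametric_three_point_condition(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        m = squareform(rng.uniform(0.05, 1.0, n * (n - 1) // 2))
        labels = [f"t{i}" for i in range(n)]
        dend = dn.upgma(dn.DistanceTable(labels, m))
        C = dend.index.patristic_matrix()
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert C[i, j] <= max(C[i, k], C[j, k]) + 1e-9

    def test_deterministic_tie_break(self):
        # all distances equal: the lexicographically smallest pair merges first
        m = np.full((3, 3), 0.5)
        np.fill_diagonal(m, 0.0)
        d1 = dn.upgma(dn.DistanceTable(["b", "a", "c"], m))
        tree = d1.to_tree().to_newick().replace(" ", "")
        assert "(a:0.25,b:0.25)" in tree or "(b:0.25,a:0.25)" in tree

    def test_single_species_rejected(self):
        with pytest.raises(InputError):
            dn.upgma(dn.DistanceTable(["a"], np.zeros((1, 1))))


class TestDendrogramFD:
    def test_singleton_is_zero(self, three_species_traits):
        dend = dn.upgma(dn.gower_distance(three_species_traits))
        assert dn.dendrogram_fd(dend, ["s1"]) == 0.0

    def test_full_pool_is_total_length(self, three_species_traits):
        dend = dn.upgma(dn.gower_distance(three_species_traits))
        fd = dn.dendrogram_fd(dend, ["s1", "s2", "s3"])
        assert fd == pytest.approx(dend.total_length)

    def test_pair_equals_cophenetic(self, rng):
        traits = make_random_traits(rng, 8)
        dend = dn.upgma(dn.gower_distance(traits))
        labels = dend.labels
        for a, b in [(0, 3), (2, 5), (1, 7)]:
            assert dn.dendrogram_fd(dend, [labels[a], labels[b]]) == pytest.approx(
                dend.cophenetic(labels[a], labels[b])
            )

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_path_union_oracle(self, seed):
        rng = np.random.default_rng(seed)
        traits = make_random_traits(rng, 10)
        dend = dn.upgma(dn.gower_distance(traits))
        as_tree = dend.to_tree()
        labels = list(dend.labels)
        for _ in range(20):
            k = int(rng.integers(1, 11))
            subset = list(rng.choice(labels, size=k, replace=False))
            expect = brute_subtree_sum(as_tree, subset)
            assert dn.dendrogram_fd(dend, subset) == pytest.approx(expect, abs=1e-9)

    def test_monotone_under_addition(self, rng):
        traits = make_random_traits(rng, 10)
        dend = dn.upgma(dn.gower_distance(traits))
        labels = list(dend.labels)
        for _ in range(50):
            k = int(rng.integers(1, 10))
            subset = list(rng.choice(labels, size=k, replace=False))
            extra = rng.choice([s for s in labels if s not in subset])
            assert dn.dendrogram_fd(dend, subset + [extra]) >= dn.dendrogram_fd(
                dend, subset
            ) - 1e-12

    def test_empty_and_unknown_assemblage_rejected(self, three_species_traits):
        dend = dn.upgma(dn.gower_distance(three_species_traits))
        with pytest.raises(InputError):
            dn.dendrogram_fd(dend, [])
        with pytest.raises(InputError):
            dn.dendrogram_fd(dend, ["nope"])

    def test_recluster_variant_full_pool(self, three_species_traits):
        dist = dn.gower_distance(three_species_traits)
        dend = dn.upgma(dist)
        assert dn.fd_by_reclustering(dist, ["s1", "s2", "s3"]) == pytest.approx(
            dend.total_length
        )
        assert dn.fd_by_reclustering(dist, ["s2"]) == 0.0
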