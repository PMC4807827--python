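"""Dendrogram-based functional diversity (FD).

The Petchey–Gaston construction: a mixed-type trait table yields a pairwise
Gower dissimilarity matrix; UPGMA clustering of that matrix yields an
ultrametric dendrogram over the full species pool; the FD of an assemblage is
the branch-length sum of the dendrogram subtree connecting its species.

The dendrogram is built ONCE from the full pool and assemblage FD is read off
by pruning, never by re-clustering the assemblage's own submatrix: pruning
makes FD monotone under species addition (re-clustering does not) and keeps
values comparable across sites and seasons. Re-clustering is still available
(:func:`fd_by_reclustering`) for sensitivity analysis.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError
from .io import PhyloTree, TraitTable
from .subtree import BranchLengthIndex


class DistanceTable:
    """Symmetric pairwise dissimilarities in [0, 1] with a zero diagonal."""

    def __init__(self, labels: Sequence[str], matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        n = len(labels)
        if matrix.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(matrix, matrix.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(matrix), 0.0):
            raise ValidationError("distance matrix diagonal not zero")
        if matrix.min() < -1e-12 or matrix.max() > 1 + 1e-9:
            raise ValidationError("dissimilarities must lie in [0, 1]")
        self.labels: tuple = tuple(labels)
        self.matrix = np.clip(matrix, 0.0, 1.0)

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.matrix[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def gower_distance(traits: TraitTable) -> DistanceTable:
    """Gower dissimilarity over mixed traits.

    Per pair, the mean over traits of a per-trait term: 0/1 mismatch for
    categorical traits, range-normalised absolute difference for continuous
    ones. The range is the FULL species pool's range so assemblage values stay
    comparable. Missing values drop out of the mean (pairwise-complete
    reweighting); a pair with no jointly observed trait is an error.
    """
    species = list(traits.species)
    n = len(species)
    if n < 2:
        raise InputError("Gower distance needs at least 2 species")
    num = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for trait in traits.values.columns:
        col = traits.values[trait]
        if traits.types[trait] == "continuous":
            x = col.to_numpy(dtype=float)
            ok = ~np.isnan(x)
            rng = np.nanmax(x) - np.nanmin(x)
            if rng == 0:
                raise InputError(f"continuous trait {trait!r} has zero range")
            diff = np.abs(x[:, None] - x[None, :]) / rng
        else:
            vals = col.to_numpy(dtype=object)
            ok = ~pd.isna(col).to_numpy()
            diff = (vals[:, None] != vals[None, :]).astype(float)
        both = ok[:, None] & ok[None, :]
        num += np.where(both, np.nan_to_num(diff), 0.0)
        cnt += both
    np.fill_diagonal(cnt, np.maximum(np.diag(cnt), 1))
    if (cnt == 0).any():
        i, j = np.argwhere(cnt == 0)[0]
        raise InputError(
            f"species pair ({species[i]}, {species[j]}) shares no observed trait"
        )
    matrix = num / cnt
    np.fill_diagonal(matrix, 0.0)
    return DistanceTable(species, matrix)


class Dendrogram:
    """Ultrametric UPGMA merge tree in Gower-distance units.

    Tips sit at height 0; each internal node at the merge height (half the
    average inter-cluster distance). Edge length = parent height - child
    height. Exposes the same induced-subtree machinery as the phylogeny side.
    """

    def __init__(
        self,
        labels: Sequence[str],
        merges: list[tuple[int, int, float]],
    ):
        self.labels: tuple = tuple(labels)
        self.merges = list(merges)
        n = len(self.labels)
        if len(self.merges) != n - 1:
            raise ValidationError("a binary merge tree over n tips has n-1 merges")
        heights = np.zeros(2 * n - 1)
        members = []
        for i in range(n):
            row = np.zeros(n, dtype=bool)
            row[i] = True
            members.append(row)
        parent_height = np.full(2 * n - 1, np.nan)
        for k, (a, b, h) in enumerate(self.merges):
            node = n + k
            heights[node] = h
            if h < heights[a] - 1e-12 or h < heights[b] - 1e-12:
                raise ValidationError("merge heights must be non-decreasing")
            parent_height[a] = parent_height[b] = h
            members.append(members[a] | members[b])
        self._heights = heights
        # every node except the root contributes an edge
        lengths = []
        rows = []
        for node in range(2 * n - 2):
            lengths.append(parent_height[node] - heights[node])
            rows.append(members[node])
        self.index = BranchLengthIndex(self.labels, np.array(lengths), np.array(rows))

    @property
    def height(self) -> float:
        return float(self._heights[-1])

    @property
    def total_length(self) -> float:
        return self.index.total_length

    def cophenetic(self, a: str, b: str) -> float:
        P = self.index.patristic_matrix()
        i, j = self.labels.index(a), self.labels.index(b)
        return float(P[i, j])

    def to_tree(self) -> PhyloTree:
        """Serialise as a Newick phylogeny (for export or cross-checking)."""
        n = len(self.labels)
        texts = list(self.labels)
        node_h = [0.0] * n
        for a, b, h in self.merges:
            ta = f"{texts[a]}:{h - node_h[a]:.10g}"
            tb = f"{texts[b]}:{h - node_h[b]:.10g}"
            texts.append(f"({ta},{tb})")
            node_h.append(h)
        return PhyloTree.from_newick(texts[-1] + ";")


def upgma(dist: DistanceTable) -> Dendrogram:
    """Unweighted pair-group average clustering with a deterministic tie-break.

    Merge height is half the average inter-cluster distance, so tip-to-tip
    cophenetic distance equals the average distance itself. When several pairs
    tie at the minimum distance, the pair whose lexicographically smallest
    member is smallest (then the smallest partner) merges first, making the
    dendrogram platform-independent.
    """
    n = len(dist.labels)
    if n < 2:
        raise InputError("UPGMA needs at least 2 species")
    D = dist.matrix.astype(float).copy()
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    minlab = {i: dist.labels[i] for i in range(n)}
    col = {i: i for i in range(n)}  # cluster id -> matrix column
    merges: list[tuple[int, int, float]] = []
    next_id = n
    for _ in range(n - 1):
        cols = np.array([col[c] for c in active])
        sub = D[np.ix_(cols, cols)].copy()
        iu = np.triu_indices(len(active), k=1)
        d = sub[iu].min()
        ties = np.flatnonzero(sub[iu] == d)
        best = None
        for t in ties:
            a, b = active[iu[0][t]], active[iu[1][t]]
            lab = tuple(sorted((minlab[a], minlab[b])))
            if best is None or lab < best[0]:
                best = (lab, a, b)
        _, a, b = best
        merges.append((a, b, d / 2.0))
        # UPGMA update: size-weighted average of distances to the two clusters
        ca, cb = col[a], col[b]
        na, nb = sizes[a], sizes[b]
        for c in active:
            if c in (a, b):
                continue
            cc = col[c]
            newd = (na * D[ca, cc] + nb * D[cb, cc]) / (na + nb)
            D[ca, cc] = D[cc, ca] = newd
        active.remove(a)
        active.remove(b)
        sizes[next_id] = na + nb
        minlab[next_id] = min(minlab[a], minlab[b])
        col[next_id] = ca
        active.append(next_id)
        next_id += 1
    return Dendrogram(dist.labels, merges)


def dendrogram_fd(
    dend: Dendrogram, assemblage: Iterable[str], include_root: bool = False
) -> float:
    """FD of an assemblage: induced-subtree branch-length sum on the dendrogram.

    Singleton assemblages have FD 0; the full pool returns the dendrogram's
    total edge length (root-path above the pool MRCA is the root itself).
    """
    return dend.index.subtree_length(assemblage, include_root=include_root)


def fd_by_reclustering(dist: DistanceTable, assemblage: Iterable[str]) -> float:
    """Sensitivity-analysis variant: re-cluster the assemblage's own submatrix.

    Uses the pool-level Gower distances (pool-range normalisation) but builds a
    fresh UPGMA dendrogram for the assemblage and returns its total length.
    Not monotone under species addition; not used by the main pipeline.
    """
    members = list(dict.fromkeys(assemblage))
    if not members:
        raise InputError("empty assemblage")
    if len(members) == 1:
        return 0.0
    idx = [dist.labels.index(m) for m in members]
    sub = DistanceTable(members, dist.matrix[np.ix_(idx, idx)])
    return upgma(sub).total_length
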