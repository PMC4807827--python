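"""Branch-length bookkeeping shared by functional and phylogenetic diversity.

Both diversity measures are the same quantity on different trees: the total
branch length of the subtree induced by an assemblage's tips. The default
convention roots that subtree at the assemblage's most recent common ancestor
(the path from the MRCA up to the tree root is excluded); ``include_root=True``
keeps it.

The index precomputes, for every edge, which tips lie below it. An edge
belongs to the MRCA-rooted induced subtree exactly when its tip count ``c``
satisfies ``0 < c < k`` for an assemblage of ``k`` tips: edges with ``c == k``
lie on (or above) the path from MRCA to root, edges with ``c == 0`` lead only
to excluded tips. This turns each evaluation into one boolean mat-vec, so a
whole null ensemble evaluates as a single matrix product.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy
import numpy as np

from .errors import InputError


class BranchLengthIndex:
    """Edge/tip incidence of a rooted tree, for fast induced-subtree sums."""

    def __init__(self, labels: Sequence[str], lengths: np.ndarray, incidence: np.ndarray):
        self.labels: tuple = tuple(labels)
        self.lengths = np.asarray(lengths, dtype=float)  # (E,)
        self.incidence = np.asarray(incidence, dtype=bool)  # (E, T)
        if self.incidence.shape != (self.lengths.size, len(self.labels)):
            raise ValueError("incidence shape mismatch")
        self._pos = {lab: i for i, lab in enumerate(self.labels)}
        # float copy for matmul speed
        self._inc_f = self.incidence.astype(np.float64)

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "BranchLengthIndex":
        leaves = list(tree.leaf_node_iter())
        labels = [lf.taxon.label for lf in leaves]
        pos = {id(lf): i for i, lf in enumerate(leaves)}
        n = len(labels)
        lengths = []
        rows = []
        below: dict[int, np.ndarray] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                mask = np.zeros(n, dtype=bool)
                mask[pos[id(node)]] = True
            else:
                mask = np.zeros(n, dtype=bool)
                for child in node.child_nodes():
                    mask |= below[id(child)]
            below[id(node)] = mask
            if node is tree.seed_node:
                continue  # the root's own edge is outside the tree proper
            lengths.append(node.edge.length or 0.0)
            rows.append(mask)
        return cls(labels, np.array(lengths), np.array(rows))

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    def indicator(self, tips: Iterable[str]) -> np.ndarray:
        vec = np.zeros(len(self.labels), dtype=bool)
        for t in tips:
            if t not in self._pos:
                raise InputError(f"unknown tip {t!r}")
            vec[self._pos[t]] = True
        return vec

    def subtree_length(self, tips: Iterable[str], include_root: bool = False) -> float:
        """Branch-length sum connecting ``tips`` (0 for singletons/empty-free).

        Raises on an empty assemblage or unknown tips.
        """
        vec = self.indicator(tips)
        k = int(vec.sum())
        if k == 0:
            raise InputError("empty assemblage")
        counts = self._inc_f @ vec.astype(np.float64)
        if include_root:
            mask = counts > 0
        else:
            mask = (counts > 0) & (counts < k)
        return float(self.lengths[mask].sum())

    def subtree_length_many(
        self, indicators: np.ndarray, include_root: bool = False
    ) -> np.ndarray:
        """Vectorised ``subtree_length`` over columns of a (T, R) 0/1 matrix."""
        V = np.asarray(indicators)
        if V.ndim != 2 or V.shape[0] != len(self.labels):
            raise ValueError(
                f"indicator matrix must be (n_tips={len(self.labels)}, R)"
            )
        V = V.astype(np.float64)
        k = V.sum(axis=0)  # (R,)
        counts = self._inc_f @ V  # (E, R)
        if include_root:
            mask = counts > 0.5
        else:
            mask = (counts > 0.5) & (counts < k[None, :] - 0.5)
        return self.lengths @ mask

    def patristic_matrix(self) -> np.ndarray:
        """Pairwise path-length (patristic / cophenetic) distances between tips."""
        L = self.lengths
        depths = L @ self._inc_f  # (T,) root-to-tip path lengths
        shared = (self._inc_f * L[:, None]).T @ self._inc_f
        return depths[:, None] + depths[None, :] - 2.0 * shared
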