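"""Faith-style phylogenetic diversity (PD) on a pruned input phylogeny.

PD of an assemblage is the sum of branch lengths of the phylogeny's subtree
connecting the assemblage's species, measured from their most recent common
ancestor downward (the same convention as the functional-diversity kernel, so
the two statistics are directly comparable); an ``include_root`` flag keeps
the MRCA-to-root path instead. A singleton assemblage has PD 0.
"""

from __future__ import annotations

from typing import Iterable

from .errors import InputError
from .io import PhyloTree
from .subtree import BranchLengthIndex


def prune_tree(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    """Restrict the tree to ``keep``, collapsing pass-through nodes.

    Collapsed degree-2 nodes have their incident edge lengths summed, so
    patristic distances among the kept tips are preserved exactly.
    """
    keep = list(dict.fromkeys(keep))
    known = set(tree.tip_labels)
    unknown = [t for t in keep if t not in known]
    if unknown:
        raise InputError(f"cannot prune to unknown tips: {unknown}")
    if not keep:
        raise InputError("cannot prune to an empty tip set")
    clone = tree.tree.clone(depth=1)
    clone.retain_taxa_with_labels(keep)
    # dendropy's unifurcation suppression sums edge lengths along collapsed
    # paths, which is exactly the distance-preserving behaviour needed.
    clone.suppress_unifurcations()
    return PhyloTree(clone)


def pd_index(tree: PhyloTree) -> BranchLengthIndex:
    """Precompute the edge/tip incidence used for repeated PD evaluations."""
    return BranchLengthIndex.from_dendropy(tree.tree)


def faith_pd(
    tree: PhyloTree | BranchLengthIndex,
    assemblage: Iterable[str],
    include_root: bool = False,
) -> float:
    """Branch-length sum connecting ``assemblage`` on the tree.

    Accepts either a tree or a prebuilt :class:`BranchLengthIndex` (use the
    latter when evaluating many assemblages on one tree).
    """
    index = tree if isinstance(tree, BranchLengthIndex) else pd_index(tree)
    return index.subtree_length(assemblage, include_root=include_root)
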