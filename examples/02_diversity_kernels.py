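"""Functional and phylogenetic diversity of a tiny assemblage.

Three species, two traits (one categorical, one continuous) and a small
phylogeny. FD is the branch-length sum of the Gower/UPGMA dendrogram subtree
connecting an assemblage; PD is the same quantity on the phylogeny.
"""

import pandas as pd

import divnull as dn

traits = dn.TraitTable(
    pd.DataFrame(
        {"guild": ["a", "a", "b"], "body_size": [0.0, 5.0, 10.0]},
        index=["s1", "s2", "s3"],
    ),
    {"guild": "categorical", "body_size": "continuous"},
)

dist = dn.gower_distance(traits)
print("Gower distances:")
print(dist.to_frame().round(3), end="\n\n")

dend = dn.upgma(dist)
print(f"UPGMA dendrogram: {dend.to_tree().to_newick()}")
print(f"FD of the full pool  : {dn.dendrogram_fd(dend, ['s1', 's2', 's3']):.3f}")
print(f"FD of the pair s1,s2 : {dn.dendrogram_fd(dend, ['s1', 's2']):.3f}"
      "  (= their cophenetic distance)")
print(f"FD of a singleton    : {dn.dendrogram_fd(dend, ['s1']):.3f}", end="\n\n")

tree = dn.PhyloTree.from_newick("((s1:1,s2:1):2,s3:3);")
print(f"PD of the full pool  : {dn.faith_pd(tree, ['s1', 's2', 's3']):.3f}"
      "  (= total tree length)")
print(f"PD of the pair s1,s3 : {dn.faith_pd(tree, ['s1', 's3']):.3f}"
      "  (= patristic distance)")
pruned = dn.prune_tree(tree, ["s1", "s3"])
print(f"PD after pruning     : {dn.faith_pd(pruned, ['s1', 's3']):.3f}"
      "  (pruning is PD-neutral)")
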