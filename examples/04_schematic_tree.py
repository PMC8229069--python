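"""Build the ultrametric schematic tree from CON2 profile distances.

Profile distance is the columnwise mean Jaccard distance between IUPAC base
sets; UPGMA turns the distance matrix into an ultrametric dendrogram.
"""

from satprofile import profile_distance_matrix, to_newick, upgma
from satprofile.fixtures import con2_expected_matrix

matrix = con2_expected_matrix()  # the packaged CON2 worked-example matrix
labels, D = profile_distance_matrix(matrix)
tree = upgma(D, labels)

print(to_newick(tree))
group1 = [
    "D. antarctica KEW-0522816",
    "D. antarctica KEW-0661919",
    "D. antarctica KEW-0521613",
    "D. parvula",
]
print()
print("antarctica+parvula monophyletic:", tree.is_monophyletic(group1))
print(f"root height (half the largest merge distance): {tree.root.height:.4f}")
# The four group-1 accessions share one profile (pairwise distance 0) and
# form a clade; the remaining groups attach at increasing heights.
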