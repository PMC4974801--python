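"""Cluster simulated isolates by pairwise distance with UPGMA.

Pairwise per-site differences between haploid genomes feed an
average-linkage (UPGMA) agglomeration; the resulting ultrametric tree is
written as newick.  On clonal data this recovers the clade structure of
the underlying genealogy.
"""

from clonalpop import (
    DemographicModel,
    pairwise_distance_matrix,
    simulate_coalescent,
    upgma,
    write_newick,
)

sample = simulate_coalescent(
    n=8, model=DemographicModel.constant(6.0), L=30000, seed=12
)
dmat = pairwise_distance_matrix(sample.alignment)
tree = upgma(dmat, list(sample.alignment.ids))

print("pairwise p-distances (x 1e4):")
for i, row in enumerate(dmat):
    print(sample.alignment.ids[i], " ".join(f"{1e4 * d:5.2f}" for d in row))
print()
print("UPGMA tree:", write_newick(tree))
print()
print("true genealogy:", write_newick(sample.genealogy))
print("Branch lengths of the UPGMA tree are per-site distances / 2;")
print("the genealogy's are in the simulator's coalescent time units.")
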