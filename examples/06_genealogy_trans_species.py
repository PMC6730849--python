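"""Gene genealogies: trans-species polymorphism at STE3.

Neighbor-joining trees from JC distances; a gene whose alleles stopped
recombining before speciation clusters by mating type across species,
recombining genes cluster by species.
"""

from fusedmat.genealogy import classify_clustering, nj_tree, pairwise_distances
from fusedmat.io import write_newick
from fusedmat.simulate import SimConfig, simulate_dataset

ds = simulate_dataset(SimConfig(seed=1))
labels = {s.strain_id: (s.species, s.allele_class) for s in ds.truth.strains}

for key, name in [("g01", "STE3"), ("g02", "STE20 (core MAT)"),
                  ("b0_0", "background control")]:
    seqs = {s: c for s, c in ds.ortholog_cds[key].items() if c}
    tree = nj_tree(pairwise_distances(seqs, model="JC"))
    pat = classify_clustering(tree, {t: labels[t] for t in seqs})
    print(f"{name}: {pat.kind}")
    print("  " + write_newick(tree))
# Only STE3 shows the mating-type (trans-species) pattern: its a/alpha
# alleles split long before the species did. Core companions and background
# genes still cluster by species.
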