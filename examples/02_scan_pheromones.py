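"""Find pheromone-precursor candidates in an assembly.

Scans for ORFs translating to M-X(15-60)-C-[ILMVST]-[ILMVST]-X-Stop, the
consensus of CaaX-terminated lipopeptide mating pheromones.
"""

from fusedmat.pheromones import scan_genome
from fusedmat.simulate import SimConfig, simulate_dataset

ds = simulate_dataset(SimConfig(seed=1))
strain = ds.truth.strains[0]
hits = scan_genome(ds.assemblies[strain.strain_id])

gene_spans = {(g["contig"], g["start"], g["end"], g["strand"])
              for g in strain.genes}
print(f"{strain.strain_id}: {len(hits)} consensus candidates genome-wide")
for h in hits:
    genic = (h.contig, h.start, h.end, h.strand) in gene_spans
    tag = "annotated gene (the planted MF precursor)" if genic else "chance ORF"
    print(f"  {h.contig}:{h.start}-{h.end} ({h.strand}) spacer={h.spacer_len} "
          f"CaaX={h.caax}  <- {tag}")
# The consensus is deliberately permissive, so chance ORFs appear at this
# genome size; the precursor gene is the candidate that coincides with an
# annotated gene in the core MAT region.
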