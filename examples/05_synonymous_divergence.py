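"""Recombination-suppression test on a three-strain panel.

For each core-MAT gene of a trio (one A1, two A2 strains): which allele
pair is most similar, and is synonymous divergence (NG86 dS) between mating
types higher than within? A one-sided Student's t-test compares the two dS
distributions.
"""

import numpy as np

from fusedmat.divergence import (closest_pair_calls, compare_ds_sets,
                                 ds_between_cds)
from fusedmat.simulate import SimConfig, simulate_dataset

cfg = SimConfig(n_species=2,
                strains_per_species=[["A1", "A2", "A2"], ["A1", "A2"]],
                seed=1)
ds = simulate_dataset(cfg)
labels = {"sp1s1": "A1", "sp1s2": "A2", "sp1s3": "A2"}

between, within, calls = [], [], []
for i in range(23):
    key = f"g{i:02d}"
    alleles = {s: ds.ortholog_cds[key].get(s) for s in labels}
    call = closest_pair_calls(key, alleles, labels)
    if call.status == "called":
        calls.append(call.pair_label)
    if i in (1, 22):
        continue  # STE3 alleles are trans-specific; SXI1/SXI2 are not alleles
    eb = ds_between_cds(alleles["sp1s1"], alleles["sp1s3"])
    ew = ds_between_cds(alleles["sp1s2"], alleles["sp1s3"])
    if eb.dS is not None:
        between.append(eb.dS)
    if ew.dS is not None:
        within.append(ew.dS)

res = compare_ds_sets(between, within)
print(f"closest-pair calls: {calls.count('A2/A2')}/{len(calls)} genes A2/A2")
print(f"mean dS A1-vs-A2 = {np.mean(between):.4f}, "
      f"A2-vs-A2 = {np.mean(within):.4f}")
print(f"one-sided t-test: t = {res.t:.3f}, df = {res.df}, p = {res.p:.2g}")
# Under planted suppression the A2 alleles are mutually closest for nearly
# every core gene and between-type dS exceeds within-type dS significantly;
# without suppression the test rejects at the nominal 5% rate only.
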