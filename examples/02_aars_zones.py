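"""Overlay aaRS classes on the chronological order and test for zones.

Each amino acid in the GC-richness order is labeled with the class of the
aminoacyl-tRNA synthetase that charges it. Contiguous same-class runs
("zones") emerge: a lone class I Arg, a class II zone, a class I zone,
then a mixed region. The permutation p-value asks how often a random
assignment of the same labels to positions would produce as few runs.
"""

from codonchron import (
    clustering_pvalue,
    detect_runs,
    load_aars_classes,
    load_standard_code,
    overlay,
    preluca_boundary,
    arrange,
)

order = arrange(load_standard_code())
seq = overlay(order, load_aars_classes())

print("class sequence:",
      " ".join(f"{e.id}:{lbl}" for e, lbl in seq.items))

zones = detect_runs(seq)
print(f"\n{zones.n_runs} runs over the effective sequence "
      "(STOP and dual-class positions dropped):")
for lbl, members in zones.runs:
    print(f"  class {lbl:3}: {', '.join(members)}")

stat = clustering_pvalue(seq, n_permutations=10_000, seed=0)
print(f"\nclustering p-value: {stat.p_value:.4f} "
      f"({stat.observed_runs} observed runs, "
      f"{stat.n_permutations} permutations)")
print("small p = fewer runs than random labeling, i.e. zonal clustering")

ann = preluca_boundary(seq, order)
print(f"\nUGA at rank {ann.uga_rank}, column {ann.uga_column}; "
      f"near the class II -> class I boundary: {ann.near_boundary}")
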