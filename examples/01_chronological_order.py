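"""Arrange the universal genetic code from GC-rich (early) to AU-rich (late).

Builds the chronological arrangement from the packaged standard code and
prints one line per entry: its group, column (entries sharing a column are
tied — same inferred period), and codon family. The first column holds
Arg (6 GC-rich codons), the last holds single-codon Met.
"""

from codonchron import arrange, load_standard_code

order = arrange(load_standard_code())
print(f"{'entry':8} {'group':8} col rank n_codons codons")
for e in order.flattened:
    print(f"{e.id:8} {e.group.value:8} {e.column:3d} {e.rank:4d} "
          f"{e.n_codons:8d} {','.join(e.codons)}")

print("\nColumns (ties share a column; in-column order is arbitrary):")
for i, col in enumerate(order.columns):
    print(f"  {i:2d}: {[e.id for e in col]}")
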