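"""FPKM and the Audic-Claverie test for two-library read counts.

Builds a tiny count table by hand, computes FPKM, and calls differential
expression of the hybrid against each parent with the two-fold criterion.
"""

import pandas as pd

from polyhyb import ExpressionSet, audic_claverie_p, call_degs, fpkm

print("FPKM of 10 reads on a 1 kb gene in a 1M-read library:", fpkm(10, 1000, 1_000_000))
print("Two-sided p for counts 5 vs 0, equal libraries:", audic_claverie_p(5, 0))
print("Two-sided p for counts 50 vs 10, equal libraries:", audic_claverie_p(50, 10, 1e6, 1e6))

genes = pd.Index([f"g{i}" for i in range(4)], name="gene_id")
expr = ExpressionSet(
    counts=pd.DataFrame(
        {"maternal": [100, 10, 0, 40], "paternal": [100, 90, 60, 10], "hybrid": [400, 11, 30, 25]},
        index=genes,
    ),
    lengths=pd.Series([1000, 1000, 500, 2000], index=genes),
    library_sizes=pd.Series({"maternal": 1e6, "paternal": 1e6, "hybrid": 1e6}),
)
table, totals = call_degs(expr, "maternal", "hybrid")
print("\nHybrid vs maternal parent:")
print(table[["fpkm_a", "fpkm_b", "log2_ratio", "p_value", "status"]])
print("totals:", totals)

# g0 (100 -> 400 reads) is up-regulated: a four-fold change, log2 ratio 2,
# with a tiny Audic-Claverie p; g1 (10 -> 11) is unchanged.
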