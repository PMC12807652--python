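"""Shannon-entropy cell-type specificity of an SE signal matrix.

For each SE locus the per-cell-line length-normalized signals are turned
into proportions and scored with H = -sum p log2 p. H near log2(n) means the
SE is active everywhere (common); H near 0 means activity concentrates in
one cell line (specific).
"""
import pandas as pd

from seforge import entropy_specificity

matrix = pd.DataFrame(
    {
        "HepG2": [10.1, 12.0, 0.05],
        "K562": [9.8, 0.1, 0.04],
        "GM12878": [10.5, 0.2, 0.03],
        "HeLa": [9.9, 0.1, 9.7],
    },
    index=["SE_housekeeping", "SE_liver", "SE_hela"],
)
print(matrix, "\n")
for se_id, row in matrix.iterrows():
    p = entropy_specificity(row.to_numpy(), tuple(matrix.columns), se_id=se_id)
    print(f"{se_id:16s} H = {p.entropy_bits:.3f} bits "
          f"(max {p.max_entropy_bits:.0f}) -> {p.classification}")
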