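"""Merge super-enhancer calls from two identification factors.

Calls SEs independently from H3K27ac and BRD4 peaks over the same loci,
then merges calls whose overlap exceeds 70% of the shorter region, keeping
the higher-signal call as representative, and drops anything under 1 kb.
Each consolidated locus lists which factors supported it.
"""
import tempfile

from seforge import (
    SimulationConfig,
    call_super_enhancers,
    filter_short,
    merge_cross_factor,
    read_gene_models,
    read_peaks,
    simulate_dataset,
)

with tempfile.TemporaryDirectory() as td:
    ds = simulate_dataset(
        SimulationConfig(seed=2, n_se_loci=4, cell_lines=("K562",)), td
    )
    genes, _ = read_gene_models(ds.gene_file)
    se_sets = {}
    for factor in ("H3K27ac", "BRD4"):
        peaks, _ = read_peaks(ds.peak_files[("K562", factor)], factor, "K562")
        se_sets[factor] = [
            s for s in call_super_enhancers(peaks, genes) if s.is_super
        ]

n_in = sum(len(v) for v in se_sets.values())
merged = merge_cross_factor(se_sets, min_overlap_frac=0.70)
kept, n_removed = filter_short(merged, min_len=1000)
print(f"{n_in} per-factor SE calls -> {len(merged)} consolidated loci "
      f"({n_removed} dropped as < 1 kb)")
for c in kept:
    iv = c.interval
    print(f"  {iv.chrom}:{iv.start}-{iv.end}  signal={c.total_signal:8.2f}  "
          f"factors={','.join(sorted(c.supporting_factors))}")
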