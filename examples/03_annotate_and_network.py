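"""Annotate consolidated SEs and export the first-order regulatory network.

Each SE gets: genes within 500 kb (candidate targets, with edge-to-edge
distance), TFBS inside the SE, overlapping ATAC peaks, and heterochromatin
blocks within 500 kb. The network table lists SE->enhancer, SE->gene and
TF->SE edges.
"""
import tempfile

from seforge import (
    SimulationConfig,
    annotate,
    build_network,
    call_super_enhancers,
    filter_short,
    merge_cross_factor,
    read_gene_models,
    read_intervals,
    read_peaks,
    read_tfbs,
    simulate_dataset,
)

with tempfile.TemporaryDirectory() as td:
    ds = simulate_dataset(SimulationConfig(seed=3, n_se_loci=3, cell_lines=("K562",)), td)
    genes, _ = read_gene_models(ds.gene_file)
    tfbs, _ = read_tfbs(ds.tfbs_file)
    atac, _ = read_peaks(ds.atac_file, factor="ATAC")
    het, _ = read_intervals(ds.heterochromatin_file)
    se_sets = {}
    for factor in ("H3K27ac", "BRD4"):
        peaks, _ = read_peaks(ds.peak_files[("K562", factor)], factor, "K562")
        se_sets[factor] = [s for s in call_super_enhancers(peaks, genes) if s.is_super]

ses, _ = filter_short(merge_cross_factor(se_sets))
annotations = annotate(ses, genes=genes, tfbs=tfbs, atac_peaks=atac, heterochromatin=het)
for ann in annotations:
    nearest = ann.nearby_genes[0] if ann.nearby_genes else None
    print(f"{ann.se.se_id}: {len(ann.nearby_genes)} gene(s) in 500 kb "
          f"(nearest {nearest.gene_name} at {nearest.distance} bp), "
          f"{len(ann.tfbs)} TFBS, {len(ann.accessible)} ATAC peak(s), "
          f"{len(ann.heterochromatin_hits)} heterochromatin block(s)")

edges = build_network(annotations)
print(f"\nnetwork: {len(edges)} edges")
print(edges.groupby("edge_type").size().to_string())
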