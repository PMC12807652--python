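# seforge

Super-enhancer calling, consolidation, annotation and scoring from
peak-level epigenomic data.

Super-enhancers (SEs) are large clusters of enhancers with unusually dense
occupancy of transcriptional machinery — marked by H3K27ac, H3K4me1, BRD4,
p300 and Med1 — that drive cell-identity genes and are frequently hijacked in
disease. `seforge` builds an SE catalog from per-factor peak calls (the
output of an upstream peak caller such as MACS2) and characterizes it:

1. **Calling** (per factor and cell type): peaks fully inside a ±2.5 kb
   window around any transcription start site are removed, survivors within
   12.5 kb of each other are stitched into candidate regions, and regions
   are split into super vs. typical enhancers at the elbow of the
   signal-rank curve — both axes min-max rescaled to [0, 1], cutoff at the
   point where a slope-1 line is tangent to the curve from below, i.e.
   argmin(y − x); regions with signal strictly above the tangent-point
   signal are super.
2. **Consolidation** (per cell type): SE calls from different factors whose
   genomic overlap exceeds 70% (of the shorter region, by default) are
   merged transitively; each merged locus keeps its highest-signal call as
   representative; consolidated SEs shorter than 1 kb are discarded.
3. **Annotation**: genes within 500 kb (candidate targets), TFBS inside the
   SE, overlapping ATAC peaks, heterochromatin blocks within 500 kb, and a
   first-order regulatory network (SE→enhancer, SE→gene, TF→SE edges).
4. **Specificity**: per SE locus and cell line, the length-normalized
   signal S_c = Σᵢ signalᵢ · overlapᵢ/length(SE) is converted to
   proportions p_c = S_c/ΣS and scored with Shannon entropy
   H = −Σ p_c log₂ p_c. H ≈ log₂(n) over n cell lines means a common SE;
   H ≈ 0 means a cell-type-specific one (ratio H/log₂ n ≤ 0.5 → specific,
   ≥ 0.9 → common).
5. **Activity score**: each SE's activity element (constituent enhancers,
   accessible regions, TFBS) is scored as

   score_AE = Σ(Peak_En·length_En)/L + Σ(Peak_CA·length_CA)/L + Σ(Score_TF·count_TF)/L

   with L the SE length and effective lengths clipped to the SE.

A deterministic synthetic-data generator plants SE loci with known
locations, cell-line memberships and specificity classes, so the whole
pipeline is testable without any external data.

## Worked example

```bash
python examples/01_call_super_enhancers.py
```

```
50 peaks -> 25 stitched regions
                  region total_signal  rank  super
      chr1:150702-160915        58.60     1   True
       chr1:99745-110702        54.08     2   True
        chr1:50000-59745        53.79     3   True
       chr2:97968-108470        45.11     4   True
        chr2:50000-57968        41.52     5   True
      chr1:235844-236886         1.52     6  False
      chr1:331474-332773         1.38     7  False
      chr1:368928-369773         1.36     8  False
cutoff signal at the rank-curve elbow: 1.52
```

Five planted loci (stitched totals ≈ 5 peaks × 10-fold enrichment) separate
cleanly from ~1-unit background regions; the elbow cutoff lands at the top
of the background shelf, so exactly the five planted loci are flagged super.
The other scripts in `examples/` walk through consolidation, annotation and
the network, the entropy statistic, the activity score, and the full
pipeline; each prints the numbers it computes and what they mean.

The same stages are available as a CLI for file-based workflows:

```bash
seforge simulate --seed 1 -o fixtures/
seforge call --peaks fixtures/cellA_H3K27ac.narrowPeak --genes fixtures/genes.gtf \
             --factor H3K27ac --cell-type cellA -o cellA_H3K27ac_SE.bed
seforge run --config pipeline.yaml -o out/   # all stages + manifest.json
```

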