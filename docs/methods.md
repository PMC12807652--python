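# Methods

## Coordinate conventions

All region math uses 0-based, half-open intervals (BED convention); GTF/GFF3
input (1-based, inclusive) is converted on read. Overlap of `[a, b)` and
`[c, d)` is `max(0, min(b, d) − max(a, c))`; abutting intervals overlap by 0
and do not count as overlapping anywhere in the toolkit. Chromosome names are
never normalized — a two-column alias table can be supplied where inputs
disagree — because silent renaming corrupts joins across files.

Peak signal is whatever scalar the upstream peak caller emitted: the
narrowPeak `signalValue` column for 10-column files, the BED score column
otherwise (overridable). The toolkit deliberately never re-derives signal
from reads; any per-peak enrichment scalar works, and all downstream
quantities are linear in it.

## SE calling

Per factor and cell type, three steps:

**Promoter exclusion.** The promoter window is `[tss − w, tss + w + 1)` with
`w = 2500` bp; the TSS is strand-aware (interval start on `+`, `end − 1` on
`−`). A peak is removed only when *fully contained* in a single window —
matching ROSE's behavior — so a large distal element that merely brushes a
promoter survives. An `any-overlap` mode is available for stricter filtering.
Exclusion runs on constituent peaks *before* stitching; post-stitch exclusion
would delete entire distal regions that touch one promoter.

**Stitching.** A single left-to-right sweep per chromosome joins a peak to
the growing region when its gap to the region end is ≤ 12 500 bp (boundary
inclusive; overlapping peaks always join). Chaining is transitive, so a
region can grow far beyond 12.5 kb. Two invariants are tested: the partition
equals the connected components of the pairwise gap graph, and summed region
signal equals summed peak signal.

**Rank-curve cutoff.** Region totals are sorted ascending and both axes
min-max rescaled to [0, 1]. The sorted curve is a convex hockey stick lying
on or below the diagonal; the cutoff is the index where a slope-1 line is
tangent from below — the argmin of (y − x), ties broken toward the higher
index (fewer SEs, the conservative side). Regions whose total signal
*strictly exceeds* the signal at the tangent point are super. Degenerate
inputs: fewer than three regions define no curve and are all flagged super
with a warning; all-equal signals put the cutoff at the shared value, nothing
exceeds it, and nothing is flagged (logged). The cutoff is checked against an
independent exhaustive scan of the tangent objective, and flagging is
monotone: raising one region's signal never lowers its rank or demotes it.

## Consolidation

Within one cell type, SE calls from all factors form a graph with an edge
wherever the overlap fraction strictly exceeds 0.70. The fraction's
denominator is the *shorter* region's length (default): this is symmetric
and merges a small SE nested inside a larger one, which is the intended
biology; `reciprocal` (longer region) and `union` (Jaccard) modes exist
because the 70% threshold's reference is a genuine modeling choice.
Connected components merge transitively — pairwise keep-one merging would be
order-dependent — and each component keeps its maximal-total-signal member
as representative (ties: longer region, then lowest coordinate, for
determinism). "Signal" of a multi-peak region is its stitched total; a
max-constituent alternative is exposed where single sharp peaks should win.
Finally, consolidated SEs shorter than 1000 bp are dropped (strict: length
exactly 1000 is kept). The component partition is tested against a
brute-force union-find oracle and is permutation-invariant.

## Annotation and network

Genes qualify as nearby when the edge-to-edge gap between gene body and SE
is ≤ 500 kb (0 when overlapping); distance is that gap and the relation
(upstream/downstream/overlapping) is strand-agnostic chromosome order. The
anchor is the gene body by default, with a TSS anchor option, since
flank-annotation tools differ on this. TFBS and ATAC peaks attach when they
overlap the SE by ≥ 1 bp; heterochromatin blocks attach within the same
500 kb window, as repressive-context annotation. The first-order network has
typed nodes (SE, enhancer, TF, gene) and deduplicated SE→enhancer, SE→gene
and TF→SE edges; it carries no weights by default because the underlying
relation is qualitative.

## Specificity

For SE locus `r` of length `L` and one cell line, the normalized signal is
`S = Σᵢ signalᵢ · |peakᵢ ∩ r| / L` — each constituent peak weighted by its
effective length proportion — making short and long SEs comparable. Across
`n ≥ 2` cell lines, `p_c = S_c / Σ S` and `H = −Σ p_c log₂ p_c` (bits;
`0·log 0 := 0`). `H = log₂ n` iff the signal is uniform and positive;
`H = 0` iff exactly one cell line has signal. The qualitative limits are made
operational with thresholds on `H / log₂ n`: ≤ 0.5 specific, ≥ 0.9 common,
else intermediate; both are configuration, not biology, and can be tuned.
An all-zero vector is an *error*, not `H = 0`: absence everywhere is not
specificity. A `pseudocount` option softens this for sparse matrices.

Which per-cell-line regions count as "the same SE" is decided by unioning
overlapping SE intervals across cell lines (any overlap); the merged locus
is then re-quantified in every cell line from its retained (post-promoter-
exclusion) peaks, so a cell line that never called the SE still contributes
its honest signal level.

## Activity score

`score_AE = Σ Peak_En·length_En/L + Σ Peak_CA·length_CA/L + Σ Score_TF·count_TF/L`,
the three terms normalized by the SE length separately and summed. Effective
lengths are clipped to the SE. TFBS are grouped per TF (score × site count);
per-site grouping is equivalent when each site carries its own score and is
available as a switch. The modalities keep their native units (ChIP signal,
ATAC signal, motif enrichment); no cross-modality rescaling is applied by
default, so the score is a length-normalized weighted coverage, not a
calibrated activity measurement — an optional per-modality min-max
normalization exists but is off. Tested properties: empty element → 0,
additivity over modalities, strict dilution with growing L at fixed content,
and homogeneity of degree 1 in the signals.

## Synthetic data

The generator lays out each chromosome deterministically from the seed:
planted SE loci (clusters of `peaks_per_se` peaks, widths 600–1500 bp,
intra-cluster gaps 0.5–2 kb, well under the stitching threshold), separated
by 40 kb spacers; isolated background peaks spaced so that no two can stitch
(gap > 12.5 kb); one gene per spacer 20 kb downstream of its locus (within
the 500 kb annotation window) with a low-signal decoy peak centered on each
TSS to exercise promoter exclusion; TFBS and one ATAC peak inside each
locus; heterochromatin blocks in the background zones. Signals are
log-normal (σ = 0.25 on the log scale) around 1 for background and around
`signal_fold` (default 10) for planted peaks — the heavy right tail mimics
ChIP enrichment and gives the rank curve a realistic shelf. A
`specific_fraction` (default 0.5) of loci carry signal in exactly one cell
line; non-member lines see trace noise at 1% of the planted level, so
specificity reflects proportions rather than hard zeros. The remaining loci
are common to all lines. Ground truth (locus coordinates, memberships,
expected class) is written alongside and round-trips through the evaluation
harness, which scores recall/precision at ≥ 50% reciprocal-of-shorter
overlap.

What the generator does *not* emulate: read-level noise, peak-width biases
between assays, copy-number or mappability artifacts, correlated background,
or promoter-overlapping enhancers. Passing tests therefore demonstrate the
correctness of the region algebra, the cutoff geometry and the statistics —
not robustness to real ChIP-seq pathologies.

One known edge of the defaults: with `specific_fraction = 1` a cell line may
own no planted locus at all; its rank curve is then pure background and the
elbow still flags a top tail, producing a handful of false-positive calls
that overlap no planted locus. This is inherent to rank-cutoff calling on
signal-free data, not a defect of the generator; recall and specificity
classification are unaffected, and precision is quoted under the default
mixed (specific + common) conditions.

## Pipeline

Stages communicate through files (BED/TSV) so each is independently runnable;
`manifest.json` records the tool version, a config snapshot, SHA-256 input
checksums and per-stage counts (peaks read, TSS-excluded, regions stitched,
SEs called, merged, length-filtered, annotated). Consolidation operates on
super-flagged calls only — the catalog is of SEs, typical enhancers remain
available in the per-factor call tables. Specificity runs when the config
lists ≥ 2 cell lines. Outputs contain no timestamps, so two runs on
identical inputs are byte-identical (the manifest, which carries wall-clock
times, is the documented exception).

## Problem sizes

Tests and the acceptance script run on simulated data sized for interactive
iteration: 2 chromosomes of 1 Mb, 4–6 planted loci of 5 peaks, ≤ 20
background peaks, 4 cell lines × 2 factors; oracle-equivalence checks use
100 random instances of up to a few hundred peaks/regions. All quantities
scale linearly (sweeps) or near-quadratically (brute-force oracles only), so
these sizes exercise every code path while keeping the full suite under a
minute.
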