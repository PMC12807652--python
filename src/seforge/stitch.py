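"""ROSE-style construction of candidate super-enhancers from one factor's peaks.

The procedure, applied per factor and cell type:

1. drop peaks fully contained in the +/- 2.5 kb promoter window around any TSS
   (promoter-proximal signal would otherwise dominate the ranking);
2. stitch the surviving peaks left-to-right, joining any peak whose gap to the
   growing region is at most 12.5 kb (chaining may grow a region well beyond
   12.5 kb overall);
3. rank the stitched regions by total signal and separate super-enhancers from
   typical enhancers at the point of the min-max-rescaled ascending rank curve
   where a line of slope 1 is tangent from below — the hockey-stick elbow,
   equivalently the argmin of (y - x) over the rescaled curve. Regions whose
   signal strictly exceeds the signal at the tangent point are super.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from intervaltree import IntervalTree

from .core import GeneModel, GenomicInterval, Peak, span

logger = logging.getLogger(__name__)

DEFAULT_MAX_GAP = 12_500
DEFAULT_TSS_WINDOW = 2_500


@dataclass(frozen=True)
class StitchedRegion:
    """A maximal run of peaks whose successive gaps are all <= max_gap.

    The interval spans min(start)..max(end) of the constituents and
    ``total_signal`` is the plain sum of constituent signals.
    """

    interval: GenomicInterval
    constituents: tuple[Peak, ...]
    factor: str
    cell_type: str

    @property
    def total_signal(self) -> float:
        return sum(p.signal for p in self.constituents)


@dataclass(frozen=True)
class SuperEnhancer:
    """A stitched region with its rank-curve verdict.

    ``rank`` 1 is the highest-signal region of its run; ``is_super`` holds
    exactly when ``total_signal`` strictly exceeds ``cutoff_signal``, the
    signal at the slope-1 tangent point of the rescaled rank curve (runs too
    small to define a curve flag everything super instead).
    """

    region: StitchedRegion
    rank: int
    is_super: bool
    cutoff_signal: float

    @property
    def interval(self) -> GenomicInterval:
        return self.region.interval

    @property
    def total_signal(self) -> float:
        return self.region.total_signal

    @property
    def factor(self) -> str:
        return self.region.factor

    @property
    def cell_type(self) -> str:
        return self.region.cell_type

    @property
    def se_id(self) -> str:
        iv = self.interval
        return f"{self.cell_type}:{self.factor}:{iv.chrom}:{iv.start}-{iv.end}"


def exclude_promoter_proximal(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    window: int = DEFAULT_TSS_WINDOW,
    mode: Literal["contained", "any-overlap"] = "contained",
) -> list[Peak]:
    """Remove promoter-proximal peaks before stitching.

    A promoter window is ``[tss - window, tss + window + 1)`` around each
    gene's TSS. In the default ``contained`` mode a peak is dropped only when
    it lies fully inside some single promoter window; peaks merely touching a
    promoter are retained, so large distal elements are not deleted for
    brushing a TSS. ``any-overlap`` drops on >= 1 bp overlap instead.
    """
    if window <= 0:
        raise ValueError(f"window must be > 0, got {window}")
    if not genes:
        logger.warning("no gene models supplied; promoter exclusion is a no-op")
        return list(peaks)
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        lo = max(0, g.tss - window)
        hi = g.tss + window + 1
        trees.setdefault(g.interval.chrom, IntervalTree()).addi(lo, hi)
    kept: list[Peak] = []
    for p in peaks:
        tree = trees.get(p.interval.chrom)
        if tree is None:
            kept.append(p)
            continue
        hits = tree.overlap(p.interval.start, p.interval.end)
        if mode == "any-overlap":
            drop = bool(hits)
        else:
            drop = any(
                h.begin <= p.interval.start and p.interval.end <= h.end for h in hits
            )
        if not drop:
            kept.append(p)
    return kept


def stitch(peaks: Sequence[Peak], max_gap: int = DEFAULT_MAX_GAP) -> list[StitchedRegion]:
    """Stitch sorted peaks of one factor/cell type into candidate regions.

    Single left-to-right pass per chromosome: a peak joins the current region
    iff ``peak.start - region.end <= max_gap`` (overlapping peaks always
    join). Chaining is transitive. Signal is conserved: the total over all
    regions equals the sum over all input peaks.
    """
    factors = {p.factor for p in peaks}
    cells = {p.cell_type for p in peaks}
    if len(factors) > 1 or len(cells) > 1:
        raise ValueError(
            f"stitch expects one factor and one cell type, got {factors} x {cells}"
        )
    ordered = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end, p.name))
    regions: list[StitchedRegion] = []
    current: list[Peak] = []

    def flush() -> None:
        if current:
            regions.append(
                StitchedRegion(
                    interval=span([p.interval for p in current]),
                    constituents=tuple(current),
                    factor=current[0].factor,
                    cell_type=current[0].cell_type,
                )
            )

    cur_chrom: str | None = None
    cur_end = 0
    for p in ordered:
        if current and p.interval.chrom == cur_chrom and p.interval.start - cur_end <= max_gap:
            current.append(p)
            cur_end = max(cur_end, p.interval.end)
        else:
            flush()
            current = [p]
            cur_chrom = p.interval.chrom
            cur_end = p.interval.end
    flush()
    return regions


def rose_cutoff_index(signals: Sequence[float]) -> int:
    """Index of the slope-1 tangent point on the ascending rescaled rank curve.

    With signals sorted ascending, both axes are min-max rescaled to [0, 1].
    The sorted curve is a convex hockey stick lying on or below the diagonal,
    so the point where a 45-degree line touches it from below is the argmin
    of (y - x) — the elbow separating the flat typical-enhancer shelf from
    the steep super-enhancer tail. Ties break toward the higher index (fewer
    super-enhancers). Assumes ``len(signals) >= 2`` and not all values equal.
    """
    s = np.asarray(sorted(signals), dtype=float)
    n = s.size
    x = np.arange(n) / (n - 1)
    y = (s - s[0]) / (s[-1] - s[0])
    diff = y - x
    # argmin with ties broken toward the higher index
    return int(n - 1 - np.argmin(diff[::-1]))


def rank_and_cut(regions: Sequence[StitchedRegion]) -> list[SuperEnhancer]:
    """Rank stitched regions by total signal and flag the super-enhancer tail.

    Regions whose total signal strictly exceeds the signal at the tangent
    point of the rescaled rank curve are flagged ``is_super``. Fewer than
    three regions cannot define a curve: all are flagged super with a
    warning. Equal signals everywhere are degenerate: the cutoff sits at the
    shared value (last index) and nothing exceeds it, logged as such.
    """
    if not regions:
        return []
    order = sorted(
        regions,
        key=lambda r: (-r.total_signal, -(r.interval.length), r.interval.chrom, r.interval.start),
    )
    signals = [r.total_signal for r in regions]
    if len(regions) < 3:
        logger.warning(
            "only %d stitched region(s): rank curve undefined, all flagged super",
            len(regions),
        )
        return [
            SuperEnhancer(region=r, rank=i + 1, is_super=True, cutoff_signal=min(signals))
            for i, r in enumerate(order)
        ]
    if max(signals) == min(signals):
        logger.warning(
            "all %d regions share signal %g: degenerate rank curve, none super",
            len(regions),
            signals[0],
        )
        cutoff = signals[0]
    else:
        ascending = sorted(signals)
        cutoff = ascending[rose_cutoff_index(ascending)]
    return [
        SuperEnhancer(
            region=r,
            rank=i + 1,
            is_super=r.total_signal > cutoff,
            cutoff_signal=cutoff,
        )
        for i, r in enumerate(order)
    ]


def call_super_enhancers(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    max_gap: int = DEFAULT_MAX_GAP,
    tss_window: int = DEFAULT_TSS_WINDOW,
    tss_mode: Literal["contained", "any-overlap"] = "contained",
) -> list[SuperEnhancer]:
    """TSS exclusion, stitching and rank cutoff in one call."""
    retained = exclude_promoter_proximal(peaks, genes, tss_window, tss_mode)
    return rank_and_cut(stitch(retained, max_gap))
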