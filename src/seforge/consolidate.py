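"""Cross-factor consolidation of super-enhancer calls within one cell type.

Super-enhancers called from different identification factors (H3K27ac, BRD4,
p300, Med1, H3K4me1) frequently describe the same locus. Calls whose genomic
overlap exceeds 70% are merged transitively; each merge group keeps the
member with the higher signal as its representative. Finally, consolidated
regions shorter than 1 kb are discarded as spurious.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

from .core import GenomicInterval, overlap_length
from .stitch import SuperEnhancer

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP_FRAC = 0.70
DEFAULT_MIN_LENGTH = 1_000

OverlapMode = Literal["min", "reciprocal", "union"]


@dataclass(frozen=True)
class ConsolidatedSE:
    """One merged super-enhancer locus.

    ``representative`` is the highest-signal member of its merge group (ties:
    longer region, then lowest (chrom, start)); ``merged_from`` lists every
    member's identifier; ``supporting_factors`` is the union of member
    factors.
    """

    representative: SuperEnhancer
    supporting_factors: frozenset[str]
    merged_from: tuple[str, ...]

    @property
    def interval(self) -> GenomicInterval:
        return self.representative.interval

    @property
    def total_signal(self) -> float:
        return self.representative.total_signal

    @property
    def se_id(self) -> str:
        iv = self.interval
        return f"{self.representative.cell_type}:{iv.chrom}:{iv.start}-{iv.end}"


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def overlap_fraction(
    a: GenomicInterval, b: GenomicInterval, mode: OverlapMode = "min"
) -> float:
    """Overlap of two intervals as a fraction of a reference length.

    ``min`` (default): fraction of the shorter interval — symmetric, and a
    small region nested inside a large one scores 1.0. ``reciprocal``:
    fraction of the longer interval (both must individually exceed the
    threshold for the pair to merge). ``union``: Jaccard-style fraction of
    the union length.
    """
    ov = overlap_length(a, b)
    if ov == 0:
        return 0.0
    if mode == "min":
        return ov / min(a.length, b.length)
    if mode == "reciprocal":
        return ov / max(a.length, b.length)
    if mode == "union":
        return ov / (a.length + b.length - ov)
    raise ValueError(f"unknown overlap mode {mode!r}")


def merge_cross_factor(
    se_sets: Mapping[str, Sequence[SuperEnhancer]],
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
    mode: OverlapMode = "min",
) -> list[ConsolidatedSE]:
    """Merge per-factor super-enhancer calls at strictly > ``min_overlap_frac``.

    Builds a graph over all input SEs with an edge wherever the overlap
    fraction exceeds the threshold (strict inequality), takes connected
    components so merging is transitive and order-independent, and keeps the
    highest-signal member of each component as the representative.

    Components are returned sorted by representative coordinate. A single
    input factor passes through unmerged (logged).
    """
    if not (0 < min_overlap_frac <= 1):
        raise ValueError(f"min_overlap_frac must be in (0, 1], got {min_overlap_frac}")
    cells = {se.cell_type for ses in se_sets.values() for se in ses}
    if len(cells) > 1:
        raise ValueError(f"consolidation expects one cell type, got {sorted(cells)}")
    if len(se_sets) == 1:
        logger.info("single factor %s: pass-through", next(iter(se_sets)))

    members: list[SuperEnhancer] = [
        se for factor in sorted(se_sets) for se in se_sets[factor]
    ]
    # canonical order so the component partition is permutation-invariant
    members.sort(
        key=lambda s: (s.interval.chrom, s.interval.start, s.interval.end, s.factor)
    )
    uf = _UnionFind(len(members))
    # sorted sweep: only pairs whose intervals can overlap are examined
    for i, a in enumerate(members):
        for j in range(i + 1, len(members)):
            b = members[j]
            if b.interval.chrom != a.interval.chrom or b.interval.start >= a.interval.end:
                break
            if overlap_fraction(a.interval, b.interval, mode) > min_overlap_frac:
                uf.union(i, j)

    groups: dict[int, list[SuperEnhancer]] = {}
    for i, se in enumerate(members):
        groups.setdefault(uf.find(i), []).append(se)

    out: list[ConsolidatedSE] = []
    for root in sorted(groups):
        group = groups[root]
        rep = min(
            group,
            key=lambda s: (
                -s.total_signal,
                -s.interval.length,
                s.interval.chrom,
                s.interval.start,
            ),
        )
        out.append(
            ConsolidatedSE(
                representative=rep,
                supporting_factors=frozenset(s.factor for s in group),
                merged_from=tuple(sorted(s.se_id for s in group)),
            )
        )
    out.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    return out


def filter_short(
    ses: Sequence[ConsolidatedSE], min_len: int = DEFAULT_MIN_LENGTH
) -> tuple[list[ConsolidatedSE], int]:
    """Drop consolidated SEs whose representative is shorter than ``min_len``.

    Returns the retained SEs and the count removed. The comparison is strict:
    length ``min_len`` itself is retained.
    """
    if min_len <= 0:
        raise ValueError(f"min_len must be > 0, got {min_len}")
    kept = [se for se in ses if se.interval.length >= min_len]
    n_removed = len(ses) - len(kept)
    if n_removed:
        logger.info("filtered %d consolidated SE(s) shorter than %d bp", n_removed, min_len)
    return kept, n_removed
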