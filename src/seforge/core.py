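"""Coordinate types and interval arithmetic shared by every stage.

All coordinates are 0-based, half-open (BED convention). GTF input, which is
1-based inclusive, is converted on read by :mod:`seforge.io`. Chromosome names
are used verbatim; no "chr" prefix normalization is performed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

#: Recognized identification-factor labels. ``OTHER`` is the catch-all.
FACTOR_VOCABULARY = ("H3K27ac", "H3K4me1", "BRD4", "p300", "Med1", "ATAC", "OTHER")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open span ``[start, end)`` on a named chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name, used verbatim.
    start : int
        0-based inclusive start (bp); must be >= 0.
    end : int
        0-based exclusive end (bp); must be > ``start``.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Peak:
    """A single peak call: an interval with a scalar signal and provenance.

    ``signal`` is whatever per-peak scalar the upstream peak caller emitted
    (e.g. MACS2 signalValue or a BED score); the toolkit treats it as an
    enrichment magnitude and never re-derives it from reads.
    """

    interval: GenomicInterval
    name: str
    signal: float
    factor: str = "OTHER"
    cell_type: str = ""

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"peak signal must be >= 0, got {self.signal}")
        if self.factor not in FACTOR_VOCABULARY:
            raise ValueError(
                f"unknown factor {self.factor!r}; expected one of {FACTOR_VOCABULARY}"
            )


@dataclass(frozen=True)
class GeneModel:
    """Gene (or transcript) body with a strand-aware transcription start site.

    The TSS is the 5' end of the interval: ``start`` on the + strand and
    ``end - 1`` on the - strand.
    """

    interval: GenomicInterval
    gene_name: str
    strand: str = "+"

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1


@dataclass(frozen=True)
class TfbsRecord:
    """A predicted transcription-factor binding site with an enrichment score."""

    interval: GenomicInterval
    tf_name: str
    enrichment_score: float

    def __post_init__(self) -> None:
        if self.enrichment_score < 0:
            raise ValueError(
                f"enrichment score must be >= 0, got {self.enrichment_score}"
            )


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length in bp of the overlap of two half-open intervals (0 if disjoint
    or on different chromosomes). Symmetric in its arguments."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def interval_gap(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Gap in bp between two intervals on the same chromosome; 0 when they
    overlap or abut, ``None`` when chromosomes differ."""
    if a.chrom != b.chrom:
        return None
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def span(intervals: Sequence[GenomicInterval]) -> GenomicInterval:
    """Smallest interval covering all inputs (which must share a chromosome)."""
    if not intervals:
        raise ValueError("span of an empty interval collection is undefined")
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise ValueError(f"intervals span multiple chromosomes: {sorted(chroms)}")
    return GenomicInterval(
        intervals[0].chrom,
        min(iv.start for iv in intervals),
        max(iv.end for iv in intervals),
    )


def sort_peaks(peaks: Iterable[Peak]) -> list[Peak]:
    """Deterministic total ordering by (chrom, start, end, name)."""
    return sorted(
        peaks,
        key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end, p.name),
    )
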