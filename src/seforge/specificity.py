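"""Shannon-entropy cell-type specificity of super-enhancers.

A super-enhancer present at comparable strength in every cell line is a
"common" element; one active in a single cell line is "specific". The
statistic: for each SE locus, a per-cell-line signal S_c is computed as the
sum of constituent peak signals weighted by each peak's effective length
proportion of the SE (so long and short SEs are comparable), the vector is
normalized to probabilities p_c = S_c / sum(S), and the Shannon entropy
H = -sum p_c log2 p_c is taken. H approaches log2(n) for a common SE over n
cell lines and 0 for a perfectly specific one. Classification uses the
ratio H / log2(n): <= 0.5 specific, >= 0.9 common, otherwise intermediate.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, Peak, overlap_length

SPECIFIC_MAX_RATIO = 0.5
COMMON_MIN_RATIO = 0.9


@dataclass(frozen=True)
class SpecificityProfile:
    """Per-SE normalized signal vector across cell lines with its entropy."""

    se_id: str
    cell_lines: tuple[str, ...]
    normalized_signal: tuple[float, ...]
    probabilities: tuple[float, ...]
    entropy_bits: float
    classification: str

    @property
    def max_entropy_bits(self) -> float:
        return float(np.log2(len(self.cell_lines)))


def normalized_signal(
    se_interval: GenomicInterval, peaks: Sequence[Peak]
) -> float:
    """Length-proportion-weighted signal of one cell line's peaks over an SE.

    S = sum_i signal_i * overlap(peak_i, SE) / length(SE). Peaks not
    overlapping the SE contribute nothing; a single peak exactly covering
    the SE contributes its full signal.
    """
    se_len = se_interval.length
    return sum(
        p.signal * overlap_length(p.interval, se_interval) / se_len for p in peaks
    )


def entropy_specificity(
    signals: Sequence[float],
    cell_lines: Sequence[str] | None = None,
    se_id: str = "",
    specific_max_ratio: float = SPECIFIC_MAX_RATIO,
    common_min_ratio: float = COMMON_MIN_RATIO,
    pseudocount: float = 0.0,
) -> SpecificityProfile:
    """Shannon-entropy specificity of one SE's cross-cell-line signal vector.

    Zero-probability terms contribute 0 (the 0*log 0 := 0 convention). An
    all-zero vector is an error — absence everywhere is not specificity —
    unless a positive ``pseudocount`` is supplied.
    """
    S = np.asarray(signals, dtype=float) + pseudocount
    n = S.size
    if n < 2:
        raise ValueError("specificity requires signals from at least 2 cell lines")
    if np.any(S < 0):
        raise ValueError("normalized signals must be >= 0")
    total = S.sum()
    if total == 0:
        raise ValueError("SE absent from all cell lines (all-zero signal vector)")
    p = S / total
    nz = p[p > 0]
    H = float(-(nz * np.log2(nz)).sum() + 0.0)  # +0.0 normalizes -0.0
    ratio = H / np.log2(n)
    if ratio <= specific_max_ratio:
        cls = "specific"
    elif ratio >= common_min_ratio:
        cls = "common"
    else:
        cls = "intermediate"
    labels = tuple(cell_lines) if cell_lines is not None else tuple(
        f"cell_{i}" for i in range(n)
    )
    if len(labels) != n:
        raise ValueError("cell_lines length does not match signal vector")
    return SpecificityProfile(
        se_id=se_id,
        cell_lines=labels,
        normalized_signal=tuple(float(x) for x in S),
        probabilities=tuple(float(x) for x in p),
        entropy_bits=H,
        classification=cls,
    )


def merge_loci_across_cell_lines(
    intervals: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """Collapse per-cell-line SE intervals into shared loci.

    Two SEs from different cell lines are "the same" locus when their
    intervals overlap (any overlap); overlapping intervals are unioned so
    each locus is one maximal merged interval.
    """
    out: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if out and iv.chrom == out[-1].chrom and iv.start < out[-1].end:
            prev = out[-1]
            out[-1] = GenomicInterval(prev.chrom, prev.start, max(prev.end, iv.end))
        else:
            out.append(iv)
    return out


def signal_matrix(
    loci: Sequence[GenomicInterval],
    peaks_by_cell_line: Mapping[str, Sequence[Peak]],
) -> pd.DataFrame:
    """Locus x cell-line matrix of length-normalized signals.

    Index is ``chrom:start-end`` per locus; one column per cell line.
    """
    cell_lines = sorted(peaks_by_cell_line)
    data = {
        cl: [normalized_signal(iv, peaks_by_cell_line[cl]) for iv in loci]
        for cl in cell_lines
    }
    index = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in loci]
    return pd.DataFrame(data, index=pd.Index(index, name="se_id"))


def profile_matrix(
    matrix: pd.DataFrame,
    specific_max_ratio: float = SPECIFIC_MAX_RATIO,
    common_min_ratio: float = COMMON_MIN_RATIO,
    pseudocount: float = 0.0,
) -> list[SpecificityProfile]:
    """Entropy profiles for every row of an SE x cell-line signal matrix.

    Rows that are all-zero are skipped (the SE was detected in no cell
    line's peak set); callers wanting them as errors should validate first.
    """
    profiles = []
    cell_lines = tuple(matrix.columns)
    for se_id, row in matrix.iterrows():
        if row.sum() == 0 and pseudocount == 0:
            continue
        profiles.append(
            entropy_specificity(
                row.to_numpy(),
                cell_lines,
                se_id=str(se_id),
                specific_max_ratio=specific_max_ratio,
                common_min_ratio=common_min_ratio,
                pseudocount=pseudocount,
            )
        )
    return profiles


def profiles_to_frame(profiles: Sequence[SpecificityProfile]) -> pd.DataFrame:
    rows = [
        {
            "se_id": p.se_id,
            "entropy_bits": p.entropy_bits,
            "max_entropy_bits": p.max_entropy_bits,
            "entropy_ratio": p.entropy_bits / p.max_entropy_bits,
            "classification": p.classification,
            **{f"signal_{cl}": s for cl, s in zip(p.cell_lines, p.normalized_signal)},
        }
        for p in profiles
    ]
    return pd.DataFrame(rows)
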