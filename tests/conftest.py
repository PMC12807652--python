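import numpy as np
import pytest

from seforge import GenomicInterval, Peak


def make_peak(chrom, start, end, signal=1.0, name=None, factor="H3K27ac", cell_type="K562"):
    return Peak(
        GenomicInterval(chrom, start, end),
        name or f"p_{chrom}_{start}",
        signal,
        factor,
        cell_type,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_peaks(rng, n, chroms=("chr1", "chr2"), max_pos=2_000_000):
    """n random peaks with random widths and signals, sorted."""
    peaks = []
    for i in range(n):
        chrom = str(rng.choice(list(chroms)))
        start = int(rng.integers(0, max_pos))
        width = int(rng.integers(100, 3_000))
        peaks.append(make_peak(chrom, start, start + width, float(rng.lognormal(0, 1)), f"p{i}"))
    return sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end, p.name))
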