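"""Promoter exclusion, stitching and the rank-curve cutoff."""
import numpy as np
import pytest

from seforge import (
    GeneModel,
    GenomicInterval,
    exclude_promoter_proximal,
    rank_and_cut,
    rose_cutoff_index,
    stitch,
)
from seforge.stitch import StitchedRegion

from conftest import make_peak, random_peaks


def gene(chrom, start, end, name="G", strand="+"):
    return GeneModel(GenomicInterval(chrom, start, end), name, strand)


# ---------------------------------------------------------------- oracles
def stitch_oracle(peaks, max_gap):
    """Brute-force O(n^2) pairwise gap graph -> connected components."""
    n = len(peaks)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = peaks[i].interval, peaks[j].interval
            if a.chrom != b.chrom:
                continue
            gap = max(0, max(a.start, b.start) - min(a.end, b.end))
            if gap <= max_gap:
                adj[i].append(j)
                adj[j].append(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], []
        seen.add(i)
        while stack:
            k = stack.pop()
            comp.append(k)
            for m in adj[k]:
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        comps.append(frozenset(comp))
    return set(comps)


def cutoff_oracle(signals):
    """Exhaustive scan for the slope-1 tangent point on the rescaled curve:
    the extremal (y - x) index, ties toward the higher index."""
    s = sorted(signals)
    n = len(s)
    best_idx, best = 0, float("inf")
    for i in range(n):
        x = i / (n - 1)
        y = (s[i] - s[0]) / (s[-1] - s[0])
        if y - x <= best:  # <= keeps the highest index among ties
            best, best_idx = y - x, i
    return best_idx


# ------------------------------------------------------- promoter exclusion
class TestExcludePromoterProximal:
    def test_fully_contained_peak_excluded(self):
        peaks = [make_peak("chr1", 9000, 9400)]
        genes = [gene("chr1", 10000, 20000)]  # TSS 10000, window [7500, 12501)
        assert exclude_promoter_proximal(peaks, genes, 2500) == []

    def test_spanning_peak_retained(self):
        peaks = [make_peak("chr1", 7000, 13000)]
        genes = [gene("chr1", 10000, 20000)]
        assert exclude_promoter_proximal(peaks, genes, 2500) == peaks

    def test_other_chromosome_retained(self):
        peaks = [make_peak("chr2", 9000, 9400)]
        genes = [gene("chr1", 10000, 20000)]
        assert exclude_promoter_proximal(peaks, genes, 2500) == peaks

    def test_empty_gene_set_is_noop(self):
        peaks = [make_peak("chr1", 0, 100)]
        assert exclude_promoter_proximal(peaks, [], 2500) == peaks

    def test_any_overlap_mode_drops_touching_peak(self):
        peaks = [make_peak("chr1", 7000, 13000)]
        genes = [gene("chr1", 10000, 20000)]
        assert exclude_promoter_proximal(peaks, genes, 2500, mode="any-overlap") == []

    def test_minus_strand_tss_at_gene_end(self):
        # TSS of a - strand gene [10000, 20000) is 19999
        peaks = [make_peak("chr1", 18000, 19000)]
        genes = [gene("chr1", 10000, 20000, strand="-")]
        assert exclude_promoter_proximal(peaks, genes, 2500) == []


# ------------------------------------------------------------------ stitch
class TestStitch:
    def test_gap_below_threshold_joins(self):
        peaks = [make_peak("chr1", 0, 1000, 2.0), make_peak("chr1", 5000, 6000, 3.0)]
        regions = stitch(peaks, 12500)
        assert len(regions) == 1
        assert regions[0].interval == GenomicInterval("chr1", 0, 6000)
        assert regions[0].total_signal == 5.0

    def test_gap_above_threshold_splits(self):
        peaks = [make_peak("chr1", 0, 1000), make_peak("chr1", 14000, 15000)]
        assert len(stitch(peaks, 12500)) == 2

    def test_gap_exactly_threshold_joins(self):
        peaks = [make_peak("chr1", 0, 1000), make_peak("chr1", 13500, 14000)]
        assert len(stitch(peaks, 12500)) == 1

    def test_mixed_factor_rejected(self):
        peaks = [make_peak("chr1", 0, 100), make_peak("chr1", 200, 300, factor="BRD4")]
        with pytest.raises(ValueError):
            stitch(peaks)

    @pytest.mark.parametrize("max_gap", [500, 5_000, 12_500])
    def test_matches_gap_graph_oracle(self, rng, max_gap):
        for _ in range(10):
            peaks = random_peaks(rng, 100, max_pos=500_000)
            regions = stitch(peaks, max_gap)
            got = {
                frozenset(peaks.index(p) for p in r.constituents) for r in regions
            }
            assert got == stitch_oracle(peaks, max_gap)

    def test_idempotent(self, rng):
        peaks = random_peaks(rng, 200)
        regions = stitch(peaks, 12500)
        again = stitch(
            [make_peak(r.interval.chrom, r.interval.start, r.interval.end, r.total_signal)
             for r in regions],
            12500,
        )
        assert [r.interval for r in again] == [r.interval for r in regions]

    def test_signal_conservation(self, rng):
        peaks = random_peaks(rng, 300)
        regions = stitch(peaks, 12500)
        assert sum(r.total_signal for r in regions) == pytest.approx(
            sum(p.signal for p in peaks)
        )
        assert sum(len(r.constituents) for r in regions) == len(peaks)


# ------------------------------------------------------------ rank and cut
def region_with_signal(i, signal):
    p = make_peak("chr1", i * 100_000, i * 100_000 + 1000, signal, f"r{i}")
    return StitchedRegion(p.interval, (p,), p.factor, p.cell_type)


class TestRankAndCut:
    def test_single_outlier_is_only_super(self):
        regions = [region_with_signal(i, s) for i, s in enumerate([1, 1, 1, 1, 100])]
        ses = rank_and_cut(regions)
        supers = [s for s in ses if s.is_super]
        assert len(supers) == 1 and supers[0].total_signal == 100

    def test_cutoff_signal_on_every_record(self):
        regions = [region_with_signal(i, s) for i, s in enumerate([1, 1, 1, 1, 100])]
        ses = rank_and_cut(regions)
        assert {s.cutoff_signal for s in ses} == {1.0}

    def test_ranks_unique_and_ordered(self):
        regions = [region_with_signal(i, s) for i, s in enumerate([5, 9, 1, 7, 3])]
        ses = rank_and_cut(regions)
        assert sorted(s.rank for s in ses) == [1, 2, 3, 4, 5]
        best = next(s for s in ses if s.rank == 1)
        assert best.total_signal == 9

    def test_all_equal_degenerate(self):
        regions = [region_with_signal(i, 5.0) for i in range(6)]
        ses = rank_and_cut(regions)
        assert all(not s.is_super for s in ses)
        assert all(s.cutoff_signal == 5.0 for s in ses)

    def test_fewer_than_three_all_super(self):
        regions = [region_with_signal(0, 1.0), region_with_signal(1, 9.0)]
        ses = rank_and_cut(regions)
        assert all(s.is_super for s in ses)

    def test_geometric_signals_match_oracle(self):
        signals = [2.0**k for k in range(11)]
        assert rose_cutoff_index(signals) == cutoff_oracle(signals)

    def test_random_vectors_match_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 60))
            signals = rng.lognormal(0, 1.5, n).tolist()
            if int(rng.integers(0, 2)):  # inject ties
                signals[: n // 2] = [signals[0]] * (n // 2)
            if max(signals) == min(signals):
                continue
            assert rose_cutoff_index(signals) == cutoff_oracle(signals)

    def test_monotone_raising_signal_never_demotes(self, rng):
        for _ in range(50):
            signals = rng.lognormal(0, 1.5, 20)
            regions = [region_with_signal(i, float(s)) for i, s in enumerate(signals)]
            ses = {s.region.interval.start: s for s in rank_and_cut(regions)}
            k = int(rng.integers(20))
            bumped = signals.copy()
            bumped[k] *= float(rng.uniform(1.1, 4.0))
            regions2 = [region_with_signal(i, float(s)) for i, s in enumerate(bumped)]
            ses2 = {s.region.interval.start: s for s in rank_and_cut(regions2)}
            key = k * 100_000
            if ses[key].is_super:
                assert ses2[key].is_super
            assert ses2[key].rank <= ses[key].rank
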