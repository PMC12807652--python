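"""Gene/feature annotation and the first-order regulatory network."""
import pytest

from seforge import (
    GeneModel,
    GenomicInterval,
    TfbsRecord,
    annotate,
    annotate_genes,
    annotate_intervals,
    build_network,
)
from seforge.annotate import GeneHit
from seforge.consolidate import ConsolidatedSE
from seforge.core import interval_gap
from seforge.stitch import StitchedRegion, SuperEnhancer

from conftest import make_peak


def make_consolidated(chrom="chr1", start=0, end=10_000, signal=50.0, n_constituents=1):
    width = (end - start) // (2 * n_constituents)
    peaks = tuple(
        make_peak(chrom, start + 2 * i * width, start + (2 * i + 1) * width,
                  signal / n_constituents, f"enh{i}")
        for i in range(n_constituents)
    )
    region = StitchedRegion(GenomicInterval(chrom, start, end), peaks, "H3K27ac", "K562")
    rep = SuperEnhancer(region, 1, True, 0.0)
    return ConsolidatedSE(rep, frozenset({"H3K27ac"}), (rep.se_id,))


def gene(chrom, start, end, name, strand="+"):
    return GeneModel(GenomicInterval(chrom, start, end), name, strand)


class TestAnnotateGenes:
    def test_window_boundary(self):
        se = make_consolidated("chr1", 0, 10_000)
        inside = gene("chr1", 510_000, 520_000, "IN")     # gap 500000
        outside = gene("chr1", 600_000, 610_000, "OUT")   # gap 590000
        hits = annotate_genes(se, [inside, outside], window=500_000)
        assert [h.gene_name for h in hits] == ["IN"]
        assert hits[0].distance == 500_000 and hits[0].relation == "downstream"

    def test_overlapping_gene(self):
        se = make_consolidated("chr1", 0, 10_000)
        hits = annotate_genes(se, [gene("chr1", 5_000, 20_000, "OV")])
        assert hits == [GeneHit("OV", 0, "overlapping")]

    def test_upstream_relation_and_sorting(self):
        se = make_consolidated("chr1", 100_000, 110_000)
        genes = [
            gene("chr1", 0, 50_000, "LEFT"),
            gene("chr1", 120_000, 130_000, "RIGHT"),
            gene("chr1", 105_000, 106_000, "MID"),
        ]
        hits = annotate_genes(se, genes)
        assert [h.gene_name for h in hits] == ["MID", "RIGHT", "LEFT"]
        assert [h.relation for h in hits] == ["overlapping", "downstream", "upstream"]

    def test_matches_brute_force_on_random_genes(self, rng):
        se = make_consolidated("chr1", 200_000, 250_000)
        genes = []
        for i in range(200):
            s = int(rng.integers(0, 1_500_000))
            genes.append(gene("chr1", s, s + int(rng.integers(1_000, 50_000)), f"G{i}"))
        hits = annotate_genes(se, genes, window=500_000)
        expected = sorted(
            (
                (interval_gap(se.interval, g.interval), g.gene_name)
                for g in genes
                if interval_gap(se.interval, g.interval) <= 500_000
            ),
        )
        assert [(h.distance, h.gene_name) for h in hits] == expected

    def test_translation_invariance(self, rng):
        offset = 123_456
        se = make_consolidated("chr1", 50_000, 60_000)
        se_shifted = make_consolidated("chr1", 50_000 + offset, 60_000 + offset)
        genes = [gene("chr1", 100_000, 130_000, "G1"), gene("chr1", 0, 10_000, "G2")]
        shifted = [
            gene("chr1", g.interval.start + offset, g.interval.end + offset, g.gene_name)
            for g in genes
        ]
        assert annotate_genes(se, genes) == annotate_genes(se_shifted, shifted)

    def test_tss_anchor(self):
        se = make_consolidated("chr1", 0, 10_000)
        g = gene("chr1", 400_000, 900_000, "G", strand="-")  # TSS at 899999
        assert annotate_genes(se, [g], anchor="body")  # body gap 390000
        assert not annotate_genes(se, [g], anchor="tss")  # TSS gap 889999


class TestAnnotateIntervals:
    def test_tfbs_inside_se_reported(self):
        se = make_consolidated("chr1", 0, 10_000)
        site = TfbsRecord(GenomicInterval("chr1", 100, 110), "TF1", 2.0)
        assert annotate_intervals(se, [site], "within_se") == [site]

    def test_heterochromatin_within_window(self):
        se = make_consolidated("chr1", 0, 10_000)
        block = GenomicInterval("chr1", 410_000, 420_000)  # 400 kb away
        assert annotate_intervals(se, [block], "within_window", 500_000) == [block]
        far = GenomicInterval("chr1", 600_000, 610_000)
        assert annotate_intervals(se, [far], "within_window", 500_000) == []

    def test_abutting_feature_not_reported_within_se(self):
        se = make_consolidated("chr1", 0, 10_000)
        block = GenomicInterval("chr1", 10_000, 11_000)  # gap 0, overlap 0
        assert annotate_intervals(se, [block], "within_se") == []
        assert annotate_intervals(se, [block], "within_window", 100) == [block]

    def test_matches_brute_force_scan(self, rng):
        se = make_consolidated("chr1", 100_000, 150_000)
        feats = []
        for _ in range(500):
            s = int(rng.integers(0, 400_000))
            feats.append(GenomicInterval("chr1", s, s + int(rng.integers(10, 5_000))))
        got = annotate_intervals(se, feats, "within_se")
        from seforge import overlap_length
        expected = [f for f in feats if overlap_length(se.interval, f) >= 1]
        assert got == expected


class TestBuildNetwork:
    def test_edge_counts(self):
        se = make_consolidated(n_constituents=2)
        ann = annotate(
            [se],
            genes=[gene("chr1", 20_000, 30_000, "G1")],
            tfbs=[TfbsRecord(GenomicInterval("chr1", 100, 110), "TF1", 2.0)],
        )
        edges = build_network(ann)
        assert len(edges) == 4  # SE->2 enhancers, SE->gene, TF->SE
        assert set(edges["edge_type"]) == {"SE-enhancer", "SE-gene", "TF-SE"}

    def test_empty_annotations(self):
        edges = build_network([])
        assert len(edges) == 0 and list(edges.columns) == ["source", "target", "edge_type"]

    def test_duplicate_tfbs_single_edge(self):
        se = make_consolidated()
        sites = [
            TfbsRecord(GenomicInterval("chr1", 100, 110), "TF1", 2.0),
            TfbsRecord(GenomicInterval("chr1", 500, 510), "TF1", 2.0),
        ]
        ann = annotate([se], tfbs=sites)
        edges = build_network(ann)
        tf_edges = edges[edges["edge_type"] == "TF-SE"]
        assert len(tf_edges) == 1

    def test_endpoints_exist_and_permutation_invariant(self, rng):
        ses = [make_consolidated("chr1", i * 100_000, i * 100_000 + 10_000, n_constituents=2)
               for i in range(5)]
        genes = [gene("chr1", i * 100_000 + 20_000, i * 100_000 + 30_000, f"G{i}")
                 for i in range(5)]
        sites = [TfbsRecord(GenomicInterval("chr1", i * 100_000 + 50, i * 100_000 + 60),
                            f"TF{i % 2}", 1.0) for i in range(5)]
        ann = annotate(ses, genes=genes, tfbs=sites)
        e1 = build_network(ann)
        e2 = build_network(list(reversed(ann)))
        assert len(e1) == len(e2)
        assert set(map(tuple, e1.values)) == set(map(tuple, e2.values))
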