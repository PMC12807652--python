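"""Functional annotation of consolidated super-enhancers.

Each SE is annotated with: genes whose bodies lie within a 500 kb window
(candidate regulatory targets), TFBS overlapping the SE, accessible-chromatin
peaks overlapping the SE, and heterochromatin blocks within the same 500 kb
window (contextual evidence of a repressive neighborhood). Annotations feed
the first-order regulatory network (SE, constituent enhancer, TF and gene
nodes) and the activity-element score.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

from .consolidate import ConsolidatedSE
from .core import GeneModel, GenomicInterval, Peak, TfbsRecord, interval_gap, overlap_length

DEFAULT_GENE_WINDOW = 500_000

Relation = Literal["overlapping", "upstream", "downstream"]


@dataclass(frozen=True)
class GeneHit:
    gene_name: str
    distance: int
    relation: Relation


@dataclass
class SEAnnotation:
    """All annotation attached to one consolidated super-enhancer."""

    se: ConsolidatedSE
    nearby_genes: list[GeneHit] = field(default_factory=list)
    tfbs: list[TfbsRecord] = field(default_factory=list)
    accessible: list[Peak] = field(default_factory=list)
    heterochromatin_hits: list[GenomicInterval] = field(default_factory=list)


def annotate_genes(
    se: ConsolidatedSE,
    genes: Sequence[GeneModel],
    window: int = DEFAULT_GENE_WINDOW,
    anchor: Literal["body", "tss"] = "body",
) -> list[GeneHit]:
    """Genes within ``window`` bp of the SE, sorted by distance then name.

    Distance is the edge-to-edge gap between the SE interval and the gene
    body (0 when they overlap); with ``anchor="tss"`` the gap is measured to
    the 1-bp TSS position instead. Relation is strand-agnostic: a gene
    entirely left of the SE on the chromosome is ``upstream``, entirely right
    is ``downstream``.
    """
    if window <= 0:
        raise ValueError(f"window must be > 0, got {window}")
    se_iv = se.interval
    hits: list[GeneHit] = []
    for g in genes:
        g_iv = (
            g.interval
            if anchor == "body"
            else GenomicInterval(g.interval.chrom, g.tss, g.tss + 1)
        )
        gap = interval_gap(se_iv, g_iv)
        if gap is None or gap > window:
            continue
        if overlap_length(se_iv, g_iv) > 0:
            relation: Relation = "overlapping"
        elif g_iv.end <= se_iv.start:
            relation = "upstream"
        else:
            relation = "downstream"
        hits.append(GeneHit(g.gene_name, gap, relation))
    hits.sort(key=lambda h: (h.distance, h.gene_name))
    return hits


def annotate_intervals(
    se: ConsolidatedSE,
    features: Sequence,
    mode: Literal["within_se", "within_window"] = "within_se",
    window: int | None = None,
):
    """Features overlapping the SE (``within_se``, >= 1 bp overlap) or lying
    within ``window`` bp of it (``within_window``, edge-to-edge gap).

    Features may be bare :class:`GenomicInterval` objects or records with an
    ``interval`` attribute (peaks, TFBS); input order is preserved.
    """
    if mode == "within_window":
        if window is None or window <= 0:
            raise ValueError("within_window mode requires window > 0")
    se_iv = se.interval
    out = []
    for f in features:
        iv = getattr(f, "interval", f)
        if mode == "within_se":
            if overlap_length(se_iv, iv) >= 1:
                out.append(f)
        else:
            gap = interval_gap(se_iv, iv)
            if gap is not None and gap <= window:
                out.append(f)
    return out


def annotate(
    ses: Sequence[ConsolidatedSE],
    genes: Sequence[GeneModel] = (),
    tfbs: Sequence[TfbsRecord] = (),
    atac_peaks: Sequence[Peak] = (),
    heterochromatin: Sequence[GenomicInterval] = (),
    gene_window: int = DEFAULT_GENE_WINDOW,
    het_window: int = DEFAULT_GENE_WINDOW,
    anchor: Literal["body", "tss"] = "body",
) -> list[SEAnnotation]:
    """Annotate every SE with genes, TFBS, accessibility and heterochromatin."""
    return [
        SEAnnotation(
            se=se,
            nearby_genes=annotate_genes(se, genes, gene_window, anchor),
            tfbs=annotate_intervals(se, tfbs, "within_se"),
            accessible=annotate_intervals(se, atac_peaks, "within_se"),
            heterochromatin_hits=annotate_intervals(
                se, heterochromatin, "within_window", het_window
            ),
        )
        for se in ses
    ]


def build_network(annotations: Iterable[SEAnnotation]) -> pd.DataFrame:
    """First-order regulatory network as a typed edge table.

    Nodes are SEs, their constituent enhancers, nearby genes and TFs with a
    binding site in the SE. Edges: SE->enhancer, SE->gene, TF->SE; duplicates
    (e.g. several sites for one TF in one SE) collapse to a single edge.
    Columns: source, target, edge_type.
    """
    edges: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str, str]] = set()

    def add(src: str, dst: str, kind: str) -> None:
        e = (src, dst, kind)
        if e not in seen:
            seen.add(e)
            edges.append(e)

    for ann in annotations:
        se_id = ann.se.se_id
        for enh in ann.se.representative.region.constituents:
            add(se_id, enh.name, "SE-enhancer")
        for hit in ann.nearby_genes:
            add(se_id, hit.gene_name, "SE-gene")
        for site in ann.tfbs:
            add(site.tf_name, se_id, "TF-SE")
    return pd.DataFrame(edges, columns=["source", "target", "edge_type"])


def annotations_to_frame(annotations: Iterable[SEAnnotation]) -> pd.DataFrame:
    """Flat per-SE annotation summary table (one row per SE)."""
    rows = []
    for ann in annotations:
        iv = ann.se.interval
        rows.append(
            {
                "se_id": ann.se.se_id,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "total_signal": ann.se.total_signal,
                "supporting_factors": ",".join(sorted(ann.se.supporting_factors)),
                "n_constituents": len(ann.se.representative.region.constituents),
                "nearby_genes": ";".join(
                    f"{h.gene_name}:{h.distance}:{h.relation}" for h in ann.nearby_genes
                ),
                "n_tfbs": len(ann.tfbs),
                "n_accessible": len(ann.accessible),
                "n_heterochromatin": len(ann.heterochromatin_hits),
            }
        )
    return pd.DataFrame(rows)
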