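"""Composite activity-element score for super-enhancers.

An SE activity element comprises the SE's constituent enhancer peaks, the
accessible-chromatin peaks it overlaps, and the TFBS it contains. Its score
sums three per-modality terms, each normalized by the SE length L:

    score_AE = sum(Peak_En * length_En) / L
             + sum(Peak_CA * length_CA) / L
             + sum(Score_TF * count_TF) / L

where length_En / length_CA are effective lengths (the bp of each peak that
actually overlap the SE), Score_TF is a TF's enrichment score and count_TF
its number of sites in the SE. The three modalities carry their native units
(ChIP signal, ATAC signal, motif enrichment); no cross-modality rescaling is
applied by default, so the score is a length-normalized weighted coverage
rather than a calibrated activity measurement.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import pandas as pd

from .annotate import SEAnnotation
from .core import GenomicInterval, overlap_length


@dataclass
class ActivityElement:
    """Inputs to the composite score for one SE.

    ``enhancers`` and ``accessibility`` hold (signal, effective length bp)
    pairs; ``tfbs_groups`` holds (enrichment score, site count) pairs, one
    per TF by default.
    """

    se_interval: GenomicInterval
    enhancers: list[tuple[float, int]] = field(default_factory=list)
    accessibility: list[tuple[float, int]] = field(default_factory=list)
    tfbs_groups: list[tuple[float, int]] = field(default_factory=list)
    score_AE: float | None = None

    @property
    def length_SE(self) -> int:
        return self.se_interval.length


def compute_activity_score(element: ActivityElement) -> float:
    """Evaluate the three-term composite score and store it on the element.

    Each term is normalized by the SE length separately and the terms are
    summed; an element with no enhancers, accessibility or TFBS scores 0.
    Negative signals, lengths or counts are rejected — all inputs are
    enrichment magnitudes.
    """
    L = element.length_SE
    for label, pairs in (
        ("enhancer", element.enhancers),
        ("accessibility", element.accessibility),
        ("tfbs", element.tfbs_groups),
    ):
        for a, b in pairs:
            if a < 0 or b < 0:
                raise ValueError(f"negative {label} term ({a}, {b})")
    term_en = sum(sig * eff for sig, eff in element.enhancers) / L
    term_ca = sum(sig * eff for sig, eff in element.accessibility) / L
    term_tf = sum(score * count for score, count in element.tfbs_groups) / L
    element.score_AE = term_en + term_ca + term_tf
    return element.score_AE


def score_terms(element: ActivityElement) -> tuple[float, float, float]:
    """The three separately normalized terms (enhancer, accessibility, TFBS)."""
    L = element.length_SE
    return (
        sum(s * e for s, e in element.enhancers) / L,
        sum(s * e for s, e in element.accessibility) / L,
        sum(s * c for s, c in element.tfbs_groups) / L,
    )


def assemble_activity_element(
    annotation: SEAnnotation,
    tfbs_grouping: Literal["by_tf", "per_site"] = "by_tf",
) -> ActivityElement:
    """Build an ActivityElement from an annotated SE.

    Effective lengths are each peak's overlap with the SE interval, so a
    peak hanging past the SE edge contributes only its in-SE portion. TFBS
    are grouped per TF (score x site count) by default; ``per_site`` keeps
    one group of count 1 per site, equivalent when every site carries its
    own score.
    """
    se_iv = annotation.se.interval
    element = ActivityElement(se_interval=se_iv)
    for peak in annotation.se.representative.region.constituents:
        eff = overlap_length(peak.interval, se_iv)
        if eff > 0:
            element.enhancers.append((peak.signal, eff))
    for peak in annotation.accessible:
        eff = overlap_length(peak.interval, se_iv)
        if eff > 0:
            element.accessibility.append((peak.signal, eff))
    if tfbs_grouping == "by_tf":
        groups: dict[str, tuple[float, int]] = {}
        for site in annotation.tfbs:
            score, count = groups.get(site.tf_name, (site.enrichment_score, 0))
            groups[site.tf_name] = (score, count + 1)
        element.tfbs_groups = [groups[tf] for tf in sorted(groups)]
    else:
        element.tfbs_groups = [(s.enrichment_score, 1) for s in annotation.tfbs]
    return element


def score_annotations(
    annotations: Sequence[SEAnnotation],
    tfbs_grouping: Literal["by_tf", "per_site"] = "by_tf",
) -> pd.DataFrame:
    """Score every annotated SE; returns a per-SE table of terms and score_AE."""
    rows = []
    for ann in annotations:
        element = assemble_activity_element(ann, tfbs_grouping)
        t_en, t_ca, t_tf = score_terms(element)
        compute_activity_score(element)
        rows.append(
            {
                "se_id": ann.se.se_id,
                "length_SE": element.length_SE,
                "term_enhancer": t_en,
                "term_accessibility": t_ca,
                "term_tfbs": t_tf,
                "score_AE": element.score_AE,
            }
        )
    return pd.DataFrame(rows)
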