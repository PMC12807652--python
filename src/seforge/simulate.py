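"""Deterministic synthetic epigenomic datasets with planted super-enhancers.

The generator lays out each chromosome as a series of planted SE loci —
clusters of high-signal peaks whose intra-cluster gaps stay under the 12.5 kb
stitching threshold — separated by spacers wider than the threshold, with
isolated low-signal background peaks (typical enhancers) and promoter decoy
peaks beyond them. Genes are placed in the spacers so every planted SE has a
nearby annotatable gene and every decoy sits squarely in a promoter window.
TFBS, accessible-chromatin peaks and heterochromatin blocks are planted
inside or near the loci. A ground-truth table records every planted locus,
its cell-line membership and its expected specificity class.

Signals are log-normal: background around mean 1, planted peaks around
``signal_fold``, mimicking the heavy right tail of ChIP enrichment that the
rank-curve cutoff relies on. Cell-line structure: a ``specific_fraction`` of
loci carry signal in exactly one cell line (the rest of the lines see only
trace noise at 1% of the planted level); the remainder carry signal in all
lines. With a fixed seed the emitted files are byte-identical across runs;
per-track random streams are keyed by (seed, track-name hash) so adding a
track never perturbs existing ones.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, overlap_length

# layout constants (bp)
_CHROM_MARGIN = 50_000
_PEAK_W = (600, 1_500)        # planted/background peak width range
_INTRA_GAP = (500, 2_000)     # gaps inside a planted locus (< 12.5 kb)
_LOCUS_SPACING = 40_000       # spacer between loci (> 12.5 kb + promoter zone)
_BG_SPACING = (14_500, 22_000)  # gap stays > 12.5 kb after subtracting peak width
_GENE_OFFSET = 20_000         # TSS position inside each spacer
_NOISE_LEVEL = 0.01           # trace signal in non-member cell lines


@dataclass
class SimulationConfig:
    """Knobs of the synthetic dataset; defaults give a small two-factor,
    four-cell-line study with clearly separable planted loci."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_se_loci: int = 6
    peaks_per_se: int = 5
    background_peaks: int = 20
    signal_fold: float = 10.0
    cell_lines: tuple[str, ...] = ("cellA", "cellB", "cellC", "cellD")
    factors: tuple[str, ...] = ("H3K27ac", "BRD4")
    specific_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.signal_fold <= 1:
            raise ValueError("signal_fold must exceed 1")
        if not (0 <= self.specific_fraction <= 1):
            raise ValueError("specific_fraction must lie in [0, 1]")
        for name, v in (
            ("n_chroms", self.n_chroms),
            ("n_se_loci", self.n_se_loci),
            ("peaks_per_se", self.peaks_per_se),
            ("background_peaks", self.background_peaks),
        ):
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


@dataclass
class SimulatedDataset:
    """Paths of the emitted files plus the in-memory ground truth."""

    outdir: Path
    peak_files: dict[tuple[str, str], Path]  # (cell_line, factor) -> narrowPeak
    gene_file: Path
    tfbs_file: Path
    atac_file: Path
    heterochromatin_file: Path
    ground_truth_file: Path
    ground_truth: pd.DataFrame


def _track_rng(seed: int, track: str) -> np.random.Generator:
    digest = hashlib.sha256(track.encode()).digest()
    return np.random.default_rng([seed, int.from_bytes(digest[:4], "big")])


def _narrowpeak_line(chrom: str, start: int, end: int, name: str, signal: float) -> str:
    return (
        f"{chrom}\t{start}\t{end}\t{name}\t0\t.\t{signal:.4f}\t-1\t-1\t-1\n"
    )


def _required_length(cfg: SimulationConfig, loci_on_chrom: int, bg_on_chrom: int) -> int:
    locus_slot = cfg.peaks_per_se * (_PEAK_W[1] + _INTRA_GAP[1])
    return (
        2 * _CHROM_MARGIN
        + loci_on_chrom * (locus_slot + _LOCUS_SPACING)
        + bg_on_chrom * _BG_SPACING[1]
    )


def simulate_dataset(config: SimulationConfig, outdir: str | Path) -> SimulatedDataset:
    """Generate the full synthetic file set plus ground truth.

    Emits one narrowPeak per (cell line, factor), a GTF of gene models, a
    TFBS BED, an ATAC narrowPeak, a heterochromatin BED and a ground-truth
    TSV. Raises if ``chrom_length`` cannot hold the requested loci and
    background peaks, stating the minimum required length.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_layout = _track_rng(config.seed, "layout")

    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    loci_per_chrom = [0] * config.n_chroms
    for i in range(config.n_se_loci):
        loci_per_chrom[i % config.n_chroms] += 1
    bg_per_chrom = [0] * config.n_chroms
    for i in range(config.background_peaks):
        bg_per_chrom[i % config.n_chroms] += 1

    for ci, chrom in enumerate(chroms):
        need = _required_length(config, loci_per_chrom[ci], bg_per_chrom[ci])
        if need > config.chrom_length:
            raise ValueError(
                f"{chrom} too short for {loci_per_chrom[ci]} loci and "
                f"{bg_per_chrom[ci]} background peaks: need >= {need} bp, "
                f"have {config.chrom_length}"
            )

    # ---- lay out loci, genes and background positions ----------------------
    loci: list[dict] = []          # planted locus records
    genes: list[tuple[str, int, int, str]] = []  # chrom, start(0-based), end, name
    background: list[tuple[str, int, int]] = []
    het_blocks: list[tuple[str, int, int]] = []
    locus_idx = 0
    for ci, chrom in enumerate(chroms):
        pos = _CHROM_MARGIN
        for _ in range(loci_per_chrom[ci]):
            widths = rng_layout.integers(_PEAK_W[0], _PEAK_W[1], config.peaks_per_se)
            gaps = rng_layout.integers(_INTRA_GAP[0], _INTRA_GAP[1], config.peaks_per_se)
            peak_spans = []
            p = pos
            for w, g in zip(widths, gaps):
                peak_spans.append((p, p + int(w)))
                p += int(w) + int(g)
            locus_start, locus_end = peak_spans[0][0], peak_spans[-1][1]
            loci.append(
                {
                    "locus_id": f"locus_{locus_idx}",
                    "chrom": chrom,
                    "start": locus_start,
                    "end": locus_end,
                    "peak_spans": peak_spans,
                }
            )
            # gene in the spacer downstream of the locus
            tss = locus_end + _GENE_OFFSET
            genes.append((chrom, tss, tss + 5_000, f"GENE_{locus_idx}"))
            locus_idx += 1
            pos = locus_end + _LOCUS_SPACING
        for bi in range(bg_per_chrom[ci]):
            w = int(rng_layout.integers(_PEAK_W[0], _PEAK_W[1]))
            background.append((chrom, pos, pos + w))
            if bi % 5 == 0:
                het_blocks.append((chrom, pos + 3_000, pos + 8_000))
            pos += int(rng_layout.integers(*_BG_SPACING))

    # ---- cell-line membership and expected class ---------------------------
    rng_members = _track_rng(config.seed, "membership")
    n_specific = int(round(config.specific_fraction * len(loci)))
    specific_ids = set(
        rng_members.choice(len(loci), size=n_specific, replace=False).tolist()
    )
    n_lines = len(config.cell_lines)
    truth_rows = []
    for li, locus in enumerate(loci):
        if li in specific_ids and n_lines >= 2:
            members = (config.cell_lines[int(rng_members.integers(n_lines))],)
            expected = "specific"
        else:
            members = tuple(config.cell_lines)
            expected = "common" if n_lines >= 2 else "specific"
        locus["members"] = members
        truth_rows.append(
            {
                "locus_id": locus["locus_id"],
                "chrom": locus["chrom"],
                "start": locus["start"],
                "end": locus["end"],
                "cell_lines": ",".join(members),
                "expected_class": expected,
            }
        )
    truth = pd.DataFrame(truth_rows)

    # ---- per (cell line, factor) peak tracks -------------------------------
    peak_files: dict[tuple[str, str], Path] = {}
    for cell in config.cell_lines:
        for factor in config.factors:
            rng = _track_rng(config.seed, f"peaks/{cell}/{factor}")
            lines = []
            records = []
            for locus in loci:
                member = cell in locus["members"]
                for start, end in locus["peak_spans"]:
                    mean = config.signal_fold if member else config.signal_fold * _NOISE_LEVEL
                    signal = float(rng.lognormal(np.log(mean), 0.25))
                    records.append((locus["chrom"], start, end, signal))
            for chrom, start, end in background:
                signal = float(rng.lognormal(0.0, 0.25))
                records.append((chrom, start, end, signal))
            # promoter decoys: low-signal peaks centered on each TSS
            for chrom, tss, _end, _name in genes:
                signal = float(rng.lognormal(0.0, 0.25))
                records.append((chrom, tss - 400, tss + 400, signal))
            records.sort(key=lambda r: (r[0], r[1], r[2]))
            for i, (chrom, start, end, signal) in enumerate(records):
                lines.append(
                    _narrowpeak_line(chrom, start, end, f"{cell}_{factor}_p{i}", signal)
                )
            path = outdir / f"{cell}_{factor}.narrowPeak"
            path.write_text("".join(lines))
            peak_files[(cell, factor)] = path

    # ---- gene models (GTF, 1-based inclusive) ------------------------------
    gene_path = outdir / "genes.gtf"
    with open(gene_path, "w") as fh:
        for chrom, start, end, name in sorted(genes):
            fh.write(
                f"{chrom}\tsynth\tgene\t{start + 1}\t{end}\t.\t+\t.\t"
                f'gene_id "{name}"; gene_name "{name}";\n'
            )

    # ---- TFBS inside each planted locus ------------------------------------
    rng_tfbs = _track_rng(config.seed, "tfbs")
    tf_pool = [f"TF{i + 1}" for i in range(5)]
    tfbs_path = outdir / "tfbs.bed"
    with open(tfbs_path, "w") as fh:
        for locus in loci:
            n_sites = int(rng_tfbs.integers(2, 5))
            for _ in range(n_sites):
                s = int(rng_tfbs.integers(locus["start"], max(locus["start"] + 1, locus["end"] - 20)))
                tf = tf_pool[int(rng_tfbs.integers(len(tf_pool)))]
                score = float(rng_tfbs.uniform(1.0, 5.0))
                fh.write(f"{locus['chrom']}\t{s}\t{s + 15}\t{tf}\t{score:.4f}\n")

    # ---- ATAC accessibility over each planted locus ------------------------
    rng_atac = _track_rng(config.seed, "atac")
    atac_path = outdir / "atac.narrowPeak"
    with open(atac_path, "w") as fh:
        for i, locus in enumerate(loci):
            mid = (locus["start"] + locus["end"]) // 2
            w = int(rng_atac.integers(800, 2_000))
            signal = float(rng_atac.lognormal(np.log(5.0), 0.25))
            fh.write(
                _narrowpeak_line(locus["chrom"], max(0, mid - w // 2), mid + w // 2, f"atac_p{i}", signal)
            )

    het_path = outdir / "heterochromatin.bed"
    with open(het_path, "w") as fh:
        for chrom, s, e in het_blocks:
            fh.write(f"{chrom}\t{s}\t{e}\n")

    truth_path = outdir / "ground_truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)

    return SimulatedDataset(
        outdir=outdir,
        peak_files=peak_files,
        gene_file=gene_path,
        tfbs_file=tfbs_path,
        atac_file=atac_path,
        heterochromatin_file=het_path,
        ground_truth_file=truth_path,
        ground_truth=truth,
    )


def load_ground_truth(path: str | Path) -> pd.DataFrame:
    """Round-trip the ground-truth table written by :func:`simulate_dataset`."""
    return pd.read_csv(path, sep="\t")


def evaluate_recovery(
    truth: pd.DataFrame,
    called: Sequence[GenomicInterval],
    min_overlap_frac: float = 0.5,
) -> dict[str, float]:
    """Recall and precision of called SE intervals against planted loci.

    A truth locus is recovered when some called interval overlaps it by at
    least ``min_overlap_frac`` of the shorter of the two; a called interval
    is a true positive under the same rule. Returns recall, precision and
    the raw counts.
    """
    truth_ivs = [
        GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in truth.itertuples()
    ]

    def matches(a: GenomicInterval, b: GenomicInterval) -> bool:
        ov = overlap_length(a, b)
        return ov >= min_overlap_frac * min(a.length, b.length)

    recovered = sum(1 for t in truth_ivs if any(matches(t, c) for c in called))
    true_pos = sum(1 for c in called if any(matches(c, t) for t in truth_ivs))
    return {
        "recall": recovered / len(truth_ivs) if truth_ivs else float("nan"),
        "precision": true_pos / len(called) if called else float("nan"),
        "n_truth": len(truth_ivs),
        "n_called": len(called),
    }
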