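"""End-to-end orchestration: call -> consolidate -> annotate -> specificity -> score.

Stages communicate through files (BED/TSV) so each is independently runnable;
a JSON run manifest records the tool version, a config snapshot, input
checksums and per-stage record counts. Given identical inputs and config,
every primary output is byte-identical across runs — no stage consumes
unseeded randomness.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .activity import score_annotations
from .annotate import annotate, annotations_to_frame, build_network
from .consolidate import (
    DEFAULT_MIN_LENGTH,
    DEFAULT_MIN_OVERLAP_FRAC,
    ConsolidatedSE,
    filter_short,
    merge_cross_factor,
)
from .core import FACTOR_VOCABULARY, GenomicInterval, Peak
from .io import (
    format_signal,
    read_chrom_aliases,
    read_gene_models,
    read_intervals,
    read_peaks,
    read_tfbs,
)
from .specificity import (
    COMMON_MIN_RATIO,
    SPECIFIC_MAX_RATIO,
    merge_loci_across_cell_lines,
    profile_matrix,
    profiles_to_frame,
    signal_matrix,
)
from .stitch import (
    DEFAULT_MAX_GAP,
    DEFAULT_TSS_WINDOW,
    SuperEnhancer,
    exclude_promoter_proximal,
    rank_and_cut,
    stitch,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Configuration file fails schema validation."""


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    tool_version: str
    config: dict
    input_checksums: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, Any] = field(default_factory=dict)
    started_at: str = ""
    finished_at: str = ""

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


_PARAM_DEFAULTS = {
    "max_gap": DEFAULT_MAX_GAP,
    "tss_window": DEFAULT_TSS_WINDOW,
    "tss_mode": "contained",
    "overlap": DEFAULT_MIN_OVERLAP_FRAC,
    "overlap_mode": "min",
    "min_len": DEFAULT_MIN_LENGTH,
    "gene_window": 500_000,
    "het_window": 500_000,
    "gene_anchor": "body",
    "specific_max_ratio": SPECIFIC_MAX_RATIO,
    "common_min_ratio": COMMON_MIN_RATIO,
    "pseudocount": 0.0,
}


def validate_config(cfg: Mapping[str, Any], base: Path) -> dict:
    """Validate a pipeline config mapping; raises ConfigError with the field."""
    if not isinstance(cfg, Mapping):
        raise ConfigError("config root must be a mapping")
    out = dict(cfg)
    cell_lines = out.get("cell_lines")
    if not cell_lines or not isinstance(cell_lines, list):
        raise ConfigError("cell_lines: a non-empty list is required")
    if "genes" not in out:
        raise ConfigError("genes: a gene-model file (GTF/BED6) is required")

    def resolve(key: str, value: str) -> str:
        p = Path(value)
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise ConfigError(f"{key}: file not found: {p}")
        return str(p)

    out["genes"] = resolve("genes", out["genes"])
    for key in ("tfbs", "atac", "heterochromatin", "chrom_alias"):
        if out.get(key):
            out[key] = resolve(key, out[key])
    for i, cl in enumerate(cell_lines):
        if not isinstance(cl, Mapping) or "name" not in cl:
            raise ConfigError(f"cell_lines[{i}]: requires a 'name'")
        peaks = cl.get("peaks")
        if not peaks or not isinstance(peaks, Mapping):
            raise ConfigError(f"cell_lines[{i}].peaks: a factor->file mapping is required")
        for factor, path in peaks.items():
            if factor not in FACTOR_VOCABULARY:
                raise ConfigError(
                    f"cell_lines[{i}].peaks: unknown factor {factor!r} "
                    f"(expected one of {FACTOR_VOCABULARY})"
                )
            peaks[factor] = resolve(f"cell_lines[{i}].peaks.{factor}", path)
    params = dict(_PARAM_DEFAULTS)
    user_params = out.get("params") or {}
    unknown = set(user_params) - set(params)
    if unknown:
        raise ConfigError(f"params: unknown keys {sorted(unknown)}")
    params.update(user_params)
    out["params"] = params
    return out


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw, path.parent.resolve())


def write_se_calls(ses: Sequence[SuperEnhancer], path: Path) -> None:
    """BED-style SE call table: chrom, start, end, name, total_signal,
    is_super, rank, cutoff_signal."""
    rows = sorted(ses, key=lambda s: (s.interval.chrom, s.interval.start, s.interval.end))
    with open(path, "w") as fh:
        for se in rows:
            iv = se.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{se.se_id}"
                f"\t{format_signal(se.total_signal)}\t{int(se.is_super)}"
                f"\t{se.rank}\t{format_signal(se.cutoff_signal)}\n"
            )


def write_constituents(ses: Sequence[SuperEnhancer], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("se_id\tpeak_name\tchrom\tstart\tend\tsignal\n")
        for se in sorted(ses, key=lambda s: (s.interval.chrom, s.interval.start)):
            for p in se.region.constituents:
                fh.write(
                    f"{se.se_id}\t{p.name}\t{p.interval.chrom}\t{p.interval.start}"
                    f"\t{p.interval.end}\t{format_signal(p.signal)}\n"
                )


def write_consolidated(ses: Sequence[ConsolidatedSE], path: Path) -> None:
    with open(path, "w") as fh:
        for se in ses:
            iv = se.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{se.se_id}"
                f"\t{format_signal(se.total_signal)}"
                f"\t{','.join(sorted(se.supporting_factors))}"
                f"\t{','.join(se.merged_from)}\n"
            )


def run_pipeline(config: str | Path | Mapping[str, Any], output_dir: str | Path | None = None) -> Path:
    """Execute the full pipeline described by a YAML config (path or mapping).

    Returns the output directory. All stage outputs plus ``manifest.json``
    are written there; see the config schema in the package documentation.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
        base = Path(config).parent.resolve()
    else:
        cfg = validate_config(config, Path.cwd())
        base = Path.cwd()
    outdir = Path(output_dir or cfg.get("output_dir") or (base / "seforge_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    params = cfg["params"]
    manifest = RunManifest(
        tool_version=__version__,
        config={k: v for k, v in cfg.items() if k != "output_dir"},
        started_at=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    aliases = read_chrom_aliases(cfg["chrom_alias"]) if cfg.get("chrom_alias") else None

    for key in ("genes", "tfbs", "atac", "heterochromatin"):
        if cfg.get(key):
            manifest.input_checksums[key] = _sha256(Path(cfg[key]))

    genes, _ = read_gene_models(cfg["genes"], aliases=aliases)
    tfbs, _ = read_tfbs(cfg["tfbs"], aliases=aliases) if cfg.get("tfbs") else ([], None)
    het, _ = (
        read_intervals(cfg["heterochromatin"], aliases=aliases)
        if cfg.get("heterochromatin")
        else ([], None)
    )

    all_annotations = []
    retained_peaks_by_cell: dict[str, list[Peak]] = {}
    super_by_cell: dict[str, list[ConsolidatedSE]] = {}
    counts: dict[str, Any] = {}
    for cl in cfg["cell_lines"]:
        cell = cl["name"]
        logger.info("[call] cell line %s", cell)
        atac_peaks: list[Peak] = []
        if cfg.get("atac"):
            atac_peaks, _ = read_peaks(cfg["atac"], factor="ATAC", cell_type=cell, aliases=aliases)
            manifest.input_checksums["atac"] = _sha256(Path(cfg["atac"]))
        se_sets: dict[str, list[SuperEnhancer]] = {}
        retained_all: list[Peak] = []
        ccounts: dict[str, Any] = {}
        for factor, path in sorted(cl["peaks"].items()):
            peaks, report = read_peaks(path, factor=factor, cell_type=cell, aliases=aliases)
            manifest.input_checksums[f"{cell}/{factor}"] = _sha256(Path(path))
            retained = exclude_promoter_proximal(
                peaks, genes, params["tss_window"], params["tss_mode"]
            )
            regions = stitch(retained, params["max_gap"])
            ses = rank_and_cut(regions)
            se_sets[factor] = ses
            retained_all.extend(retained)
            write_se_calls(ses, outdir / f"{cell}_{factor}_SE.bed")
            write_constituents(ses, outdir / f"{cell}_{factor}_constituents.tsv")
            ccounts[factor] = {
                "peaks_read": len(peaks),
                "peaks_tss_excluded": len(peaks) - len(retained),
                "regions_stitched": len(regions),
                "ses_called": sum(1 for s in ses if s.is_super),
            }
        retained_peaks_by_cell[cell] = retained_all
        logger.info("[consolidate] cell line %s", cell)
        super_only = {
            f: [s for s in ses if s.is_super] for f, ses in se_sets.items()
        }
        merged = merge_cross_factor(super_only, params["overlap"], params["overlap_mode"])
        kept, n_removed = filter_short(merged, params["min_len"])
        super_by_cell[cell] = kept
        write_consolidated(kept, outdir / f"{cell}_consolidated.bed")
        ccounts["ses_merged"] = len(merged)
        ccounts["ses_length_filtered"] = n_removed
        ccounts["ses_final"] = len(kept)
        counts[cell] = ccounts

        logger.info("[annotate] cell line %s", cell)
        anns = annotate(
            kept,
            genes=genes,
            tfbs=tfbs,
            atac_peaks=atac_peaks,
            heterochromatin=het,
            gene_window=params["gene_window"],
            het_window=params["het_window"],
            anchor=params["gene_anchor"],
        )
        all_annotations.extend(anns)
        ccounts["ses_annotated"] = len(anns)

    ann_frame = annotations_to_frame(all_annotations)
    ann_frame.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    build_network(all_annotations).to_csv(outdir / "network.tsv", sep="\t", index=False)
    score_annotations(all_annotations).to_csv(outdir / "scores.tsv", sep="\t", index=False)

    if len(cfg["cell_lines"]) >= 2:
        logger.info("[specificity] %d cell lines", len(cfg["cell_lines"]))
        loci = merge_loci_across_cell_lines(
            [se.interval for ses in super_by_cell.values() for se in ses]
        )
        matrix = signal_matrix(loci, retained_peaks_by_cell)
        matrix.to_csv(outdir / "specificity_matrix.tsv", sep="\t")
        profiles = profile_matrix(
            matrix,
            specific_max_ratio=params["specific_max_ratio"],
            common_min_ratio=params["common_min_ratio"],
            pseudocount=params["pseudocount"],
        )
        profiles_to_frame(profiles).to_csv(outdir / "specificity.tsv", sep="\t", index=False)
        counts["specificity_loci"] = len(loci)
    else:
        logger.info("[specificity] skipped: needs >= 2 cell lines")

    manifest.stage_counts = counts
    manifest.finished_at = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(outdir / "manifest.json")
    return outdir
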