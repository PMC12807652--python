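"""Readers and writers for the tab-delimited genomics formats the toolkit consumes.

Supported inputs: ENCODE narrowPeak (10 columns), BED3/5/6, and GTF/GFF3 gene
models. ``#``-prefixed lines are skipped everywhere. Malformed data lines are
rejected individually and reported with their line numbers; a file in which
more than half of the data lines are malformed is treated as unreadable.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .core import GeneModel, GenomicInterval, Peak, TfbsRecord, sort_peaks

logger = logging.getLogger(__name__)


@dataclass
class ParseReport:
    """Per-file accounting of accepted and rejected lines."""

    path: str
    n_records: int = 0
    skipped_lines: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped_lines)


class MalformedFileError(ValueError):
    """Raised when more than half of a file's data lines are unparsable."""


def read_chrom_aliases(path: str | Path) -> dict[str, str]:
    """Read a 2-column (from, to) chromosome alias table."""
    aliases: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        src, dst = line.split("\t")[:2]
        aliases[src] = dst
    return aliases


def _apply_alias(chrom: str, aliases: Mapping[str, str] | None) -> str:
    return aliases.get(chrom, chrom) if aliases else chrom


def _iter_data_lines(path: str | Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("track"):
                continue
            yield lineno, line


def _finalize(report: ParseReport, n_total: int) -> None:
    for lineno, reason in report.skipped_lines:
        logger.warning("%s:%d skipped: %s", report.path, lineno, reason)
    if n_total == 0:
        logger.warning("%s: file contains no data lines", report.path)
    elif report.n_skipped * 2 > n_total:
        raise MalformedFileError(
            f"{report.path}: {report.n_skipped}/{n_total} data lines malformed"
        )


def read_peaks(
    path: str | Path,
    factor: str = "OTHER",
    cell_type: str = "",
    signal_column: int | None = None,
    aliases: Mapping[str, str] | None = None,
) -> tuple[list[Peak], ParseReport]:
    """Read peaks from a narrowPeak or BED file, sorted by (chrom, start).

    The signal is taken from the narrowPeak ``signalValue`` column (7th) for
    10-column files and from the BED ``score`` column (5th) otherwise; pass
    ``signal_column`` (1-based) to override the automatic choice. Lines with
    non-numeric coordinates, ``end <= start`` or negative signal are skipped
    and reported; an empty file yields an empty collection with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    report = ParseReport(str(path))
    peaks: list[Peak] = []
    n_total = 0
    for lineno, line in _iter_data_lines(path):
        n_total += 1
        fields = line.split("\t")
        try:
            if len(fields) < 5:
                raise ValueError(f"expected >= 5 columns, got {len(fields)}")
            chrom = _apply_alias(fields[0], aliases)
            start, end = int(fields[1]), int(fields[2])
            if signal_column is not None:
                sig_idx = signal_column - 1
            else:
                sig_idx = 6 if len(fields) >= 10 else 4
            signal = float(fields[sig_idx])
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end),
                    name=fields[3],
                    signal=signal,
                    factor=factor,
                    cell_type=cell_type,
                )
            )
        except (ValueError, IndexError) as exc:
            report.skipped_lines.append((lineno, str(exc)))
    _finalize(report, n_total)
    peaks = sort_peaks(peaks)
    report.n_records = len(peaks)
    return peaks, report


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    if "=" in attr and '"' not in attr:  # GFF3 key=value
        for item in attr.rstrip(";").split(";"):
            if "=" in item:
                k, v = item.split("=", 1)
                out[k.strip()] = v.strip()
    else:  # GTF key "value"
        for item in attr.rstrip(";").split(";"):
            item = item.strip()
            if not item:
                continue
            parts = item.split(None, 1)
            if len(parts) == 2:
                out[parts[0]] = parts[1].strip().strip('"')
    return out


_GENE_FEATURES = {"gene", "transcript", "mRNA"}
_GENE_NAME_KEYS = ("gene_name", "gene_id", "Name", "ID", "transcript_id")


def read_gene_models(
    path: str | Path, aliases: Mapping[str, str] | None = None
) -> tuple[list[GeneModel], ParseReport]:
    """Read gene models from GTF/GFF3 (``gene``/``transcript`` records) or BED6.

    GTF/GFF3 coordinates (1-based inclusive) are converted to 0-based
    half-open. Unknown strand characters are treated as ``+`` with a warning.
    Duplicate gene names are permitted (multiple transcripts).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    is_gtf = path.suffix.lower() in {".gtf", ".gff", ".gff3"}
    report = ParseReport(str(path))
    genes: list[GeneModel] = []
    n_total = 0
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t")
        try:
            # Files without a telling extension are sniffed per row: GTF rows
            # have 9 columns with a non-numeric source column.
            if is_gtf or (len(fields) == 9 and _looks_gtf(fields)):
                if fields[2] not in _GENE_FEATURES:
                    continue
                n_total += 1
                chrom = _apply_alias(fields[0], aliases)
                start = int(fields[3]) - 1  # 1-based inclusive -> 0-based
                end = int(fields[4])
                strand = fields[6]
                attrs = _parse_gtf_attributes(fields[8])
                name = next(
                    (attrs[k] for k in _GENE_NAME_KEYS if k in attrs), f"gene_{lineno}"
                )
            else:
                n_total += 1
                if len(fields) < 6:
                    raise ValueError(f"expected BED6 or GTF, got {len(fields)} columns")
                chrom = _apply_alias(fields[0], aliases)
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                strand = fields[5]
            if strand not in {"+", "-"}:
                logger.warning(
                    "%s:%d unknown strand %r, treating as +", path, lineno, strand
                )
                strand = "+"
            genes.append(
                GeneModel(GenomicInterval(chrom, start, end), name, strand)
            )
        except (ValueError, IndexError) as exc:
            report.skipped_lines.append((lineno, str(exc)))
    _finalize(report, n_total)
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start, g.gene_name))
    report.n_records = len(genes)
    return genes, report


def _looks_gtf(fields: Sequence[str]) -> bool:
    try:
        int(fields[3]), int(fields[4])
    except ValueError:
        return False
    return not fields[1].lstrip("-").isdigit()


def read_tfbs(
    path: str | Path, aliases: Mapping[str, str] | None = None
) -> tuple[list[TfbsRecord], ParseReport]:
    """Read TFBS records from a BED file: chrom, start, end, tf_name, score."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    report = ParseReport(str(path))
    records: list[TfbsRecord] = []
    n_total = 0
    for lineno, line in _iter_data_lines(path):
        n_total += 1
        fields = line.split("\t")
        try:
            if len(fields) < 5:
                raise ValueError(f"expected >= 5 columns, got {len(fields)}")
            chrom = _apply_alias(fields[0], aliases)
            records.append(
                TfbsRecord(
                    GenomicInterval(chrom, int(fields[1]), int(fields[2])),
                    tf_name=fields[3],
                    enrichment_score=float(fields[4]),
                )
            )
        except (ValueError, IndexError) as exc:
            report.skipped_lines.append((lineno, str(exc)))
    _finalize(report, n_total)
    records.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.tf_name))
    report.n_records = len(records)
    return records, report


def read_intervals(
    path: str | Path, aliases: Mapping[str, str] | None = None
) -> tuple[list[GenomicInterval], ParseReport]:
    """Read plain intervals from a BED3+ file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    report = ParseReport(str(path))
    out: list[GenomicInterval] = []
    n_total = 0
    for lineno, line in _iter_data_lines(path):
        n_total += 1
        fields = line.split("\t")
        try:
            out.append(
                GenomicInterval(
                    _apply_alias(fields[0], aliases), int(fields[1]), int(fields[2])
                )
            )
        except (ValueError, IndexError) as exc:
            report.skipped_lines.append((lineno, str(exc)))
    _finalize(report, n_total)
    out.sort()
    report.n_records = len(out)
    return out, report


def format_signal(x: float) -> str:
    """Render a signal value without float noise: integers stay integral."""
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as 5-column BED (chrom, start, end, name, signal).

    Round-trips bit-exactly through :func:`read_peaks` for valid inputs.
    """
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                f"\t{p.name}\t{format_signal(p.signal)}\n"
            )


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write plain intervals as BED3."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
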