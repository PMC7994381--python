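"""Readers and writers for the plain-text genomic formats the pipeline touches.

All records are held internally in a single coordinate convention: 0-based,
half-open intervals.  GTF input (1-based, closed) is converted exactly once,
at the parsing boundary.  Every writer emits a tab-delimited, UTF-8 file with
a header line where the format has one (segment/count/clinical tables; GTF and
narrowPeak are header-less by convention).

Formats
-------
* segment table  -- TSV with columns ``sample, chrom, start, end, ploidy``;
  one row per copy-number segment, coordinates 0-based half-open.
* narrowPeak     -- ENCODE BED6+4; column 7 (signalValue) is interpreted as
  the peak fold enrichment (FE), which is where MACS2 writes it.
* GTF            -- only ``gene`` features are read; the transcription start
  site is derived from the strand (start for ``+``, end-1 for ``-``).
* counts table   -- TSV, genes x samples, non-negative integers.
* clinical table -- TSV, one row per sample with survival endpoints and
  binary prognostic covariates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GenomicInterval",
    "GenomicSegment",
    "PeakRecord",
    "GeneModel",
    "read_segments",
    "write_segments",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_gene_models",
    "write_gene_models",
    "read_counts",
    "write_counts",
    "read_clinical",
    "write_clinical",
    "segments_by_sample",
    "CLINICAL_COLUMNS",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of '+', '-', '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GenomicSegment:
    """One sample's copy-number segment with its average ploidy ``n``."""

    sample_id: str
    interval: GenomicInterval
    ploidy: float

    def __post_init__(self) -> None:
        if not (self.ploidy >= 0):
            raise ValueError(f"ploidy must be >= 0, got {self.ploidy}")


@dataclass(frozen=True)
class PeakRecord:
    """A called peak; ``fold_enrichment`` is narrowPeak column 7 (signalValue)."""

    interval: GenomicInterval
    name: str
    fold_enrichment: float
    qvalue: float | None = None
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if not (self.fold_enrichment >= 0):
            raise ValueError(
                f"fold_enrichment must be >= 0, got {self.fold_enrichment}"
            )


@dataclass(frozen=True)
class GeneModel:
    """A gene with a strand-aware transcription start site (0-based)."""

    gene_id: str
    interval: GenomicInterval
    tss: int = field(init=False)

    def __post_init__(self) -> None:
        if self.interval.strand == "-":
            object.__setattr__(self, "tss", self.interval.end - 1)
        else:
            object.__setattr__(self, "tss", self.interval.start)


# ---------------------------------------------------------------------------
# segment tables
# ---------------------------------------------------------------------------

_SEGMENT_HEADER = ["sample", "chrom", "start", "end", "ploidy"]


def _validate_non_overlapping(segments: Sequence[GenomicSegment]) -> None:
    by_key: dict[tuple[str, str], list[GenomicSegment]] = {}
    for seg in segments:
        by_key.setdefault((seg.sample_id, seg.interval.chrom), []).append(seg)
    for (sample, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.interval.start)
        for a, b in zip(segs, segs[1:]):
            if b.interval.start < a.interval.end:
                raise FormatError(
                    f"overlapping segments for sample {sample!r} on {chrom}: "
                    f"[{a.interval.start}, {a.interval.end}) and "
                    f"[{b.interval.start}, {b.interval.end})"
                )


def read_segments(path: str | Path) -> list[GenomicSegment]:
    """Read a segment TSV; validates per-sample, per-chromosome non-overlap."""
    segments: list[GenomicSegment] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _SEGMENT_HEADER:
            raise FormatError(
                f"line 1: expected header {_SEGMENT_HEADER}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise FormatError(f"line {lineno}: expected 5 columns, got {len(fields)}")
            sample, chrom, start_s, end_s, ploidy_s = fields
            try:
                start, end = int(start_s), int(end_s)
                ploidy = float(ploidy_s)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
            try:
                segments.append(
                    GenomicSegment(sample, GenomicInterval(chrom, start, end), ploidy)
                )
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
    _validate_non_overlapping(segments)
    return segments


def write_segments(segments: Iterable[GenomicSegment], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_SEGMENT_HEADER) + "\n")
        for seg in segments:
            fh.write(
                f"{seg.sample_id}\t{seg.interval.chrom}\t{seg.interval.start}\t"
                f"{seg.interval.end}\t{seg.ploidy:.10g}\n"
            )


def segments_by_sample(
    segments: Iterable[GenomicSegment],
) -> dict[str, list[GenomicSegment]]:
    """Group segments by sample id (stable order)."""
    out: dict[str, list[GenomicSegment]] = {}
    for seg in segments:
        out.setdefault(seg.sample_id, []).append(seg)
    return out


# ---------------------------------------------------------------------------
# narrowPeak
# ---------------------------------------------------------------------------


def read_narrowpeak(path: str | Path) -> list[PeakRecord]:
    """Read an ENCODE narrowPeak (BED6+4) file; column 7 is the FE."""
    peaks: list[PeakRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 10:
                raise FormatError(
                    f"line {lineno}: narrowPeak requires 10 columns, got {len(fields)}"
                )
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
                fe = float(fields[6])
                qvalue = float(fields[8])
                summit = int(fields[9])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
            if strand not in ("+", "-", "."):
                strand = "."
            try:
                peaks.append(
                    PeakRecord(
                        GenomicInterval(chrom, start, end, strand),
                        name=name,
                        fold_enrichment=fe,
                        qvalue=None if qvalue < 0 else qvalue,
                        summit_offset=None if summit < 0 else summit,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
    return peaks


def write_narrowpeak(peaks: Iterable[PeakRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pk in peaks:
            q = -1.0 if pk.qvalue is None else pk.qvalue
            s = -1 if pk.summit_offset is None else pk.summit_offset
            fh.write(
                f"{pk.interval.chrom}\t{pk.interval.start}\t{pk.interval.end}\t"
                f"{pk.name}\t0\t{pk.interval.strand}\t{pk.fold_enrichment:.10g}\t"
                f"-1\t{q:.10g}\t{s}\n"
            )


# ---------------------------------------------------------------------------
# GTF gene models
# ---------------------------------------------------------------------------

_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]+)"')


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read ``gene`` features from a GTF; converts to 0-based half-open."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"line {lineno}: GTF requires 9 columns")
            if fields[2] != "gene":
                continue
            m = _GENE_ID_RE.search(fields[8])
            if m is None:
                raise FormatError(f"line {lineno}: missing gene_id attribute")
            gene_id = m.group(1)
            if gene_id in seen:
                raise FormatError(f"line {lineno}: duplicated gene_id {gene_id!r}")
            seen.add(gene_id)
            try:
                start = int(fields[3]) - 1  # GTF is 1-based closed
                end = int(fields[4])
                strand = fields[6]
                genes.append(GeneModel(gene_id, GenomicInterval(fields[0], start, end, strand)))
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tnbscreen\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tgene_id \"{g.gene_id}\";\n"
            )


# ---------------------------------------------------------------------------
# count and clinical tables
# ---------------------------------------------------------------------------


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples count table (TSV, first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicated gene identifiers: {dup}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicated sample identifiers: {dup}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError("counts must be numeric")
    if (values < 0).any() or not np.allclose(values, np.round(values)):
        raise FormatError("counts must be non-negative integers")
    return df.astype(np.int64)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


CLINICAL_COLUMNS = [
    "os_time",
    "os_event",
    "efs_time",
    "efs_event",
    "stage_advanced",
    "age_over_18m",
    "mycn_amplified",
]

_BINARY_COLUMNS = CLINICAL_COLUMNS[1:2] + CLINICAL_COLUMNS[3:]


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a per-sample clinical table (TSV, first column = sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"clinical table missing columns: {missing}")
    if df.index.duplicated().any():
        raise FormatError("duplicated sample identifiers in clinical table")
    for col in ("os_time", "efs_time"):
        if not (df[col] > 0).all():
            raise FormatError(f"{col} must be > 0 for every sample")
    for col in _BINARY_COLUMNS:
        if not df[col].isin([0, 1]).all():
            raise FormatError(f"{col} must be binary (0/1)")
    return df[CLINICAL_COLUMNS].copy()


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index_label="sample", float_format="%.10g")
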