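"""Bin- and region-level copy-number summarisation and classification.

A sample's segmental whole-genome copy-number calls are reduced to
length-weighted average ploidies over fixed 10 kb bins (for cohort frequency
profiles), over a configurable chromosome region (for gain/diploid cohort
stratification) and over individual gene bodies (for copy-number/expression
correlation).  The average ploidy ``n`` is classified into three strata::

    loss     n <= 1
    diploid  1 <  n < 3
    gain     n >= 3

The printed strata overlap at the boundaries n = 1 and n = 3; precedence here
is gain (n >= 3) first, then loss (n <= 1), so that the screen stays sensitive
to gains.  Bases not covered by any segment are excluded from the weighting
rather than imputed as diploid, to avoid diluting focal events (set
``impute_diploid=True`` for the alternative reading).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GeneModel, GenomicInterval, GenomicSegment, segments_by_sample

__all__ = [
    "BinGrid",
    "make_bins",
    "average_ploidy",
    "classify_ploidy",
    "region_status",
    "cohort_frequency_profile",
    "gene_copy_number",
    "copy_number_matrix",
    "CALLS",
]

CALLS = ("loss", "diploid", "gain")


@dataclass(frozen=True)
class BinGrid:
    """Contiguous, non-overlapping bins tiling ``[0, chrom_length)``."""

    chrom: str
    bin_width: int
    chrom_length: int

    @property
    def starts(self) -> np.ndarray:
        return np.arange(0, self.chrom_length, self.bin_width)

    @property
    def ends(self) -> np.ndarray:
        return np.minimum(self.starts + self.bin_width, self.chrom_length)

    @property
    def bins(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.chrom, int(s), int(e))
            for s, e in zip(self.starts, self.ends)
        ]

    def __len__(self) -> int:
        return int(np.ceil(self.chrom_length / self.bin_width))


def make_bins(chrom: str, length: int, width: int = 10_000) -> BinGrid:
    """Tile ``[0, length)`` with ``width``-sized bins (final bin may be partial)."""
    if length <= 0 or width <= 0:
        raise ValueError("length and width must be positive")
    return BinGrid(chrom=chrom, bin_width=int(width), chrom_length=int(length))


def _overlap_arrays(
    segments: list[GenomicSegment], chrom: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    segs = [s for s in segments if s.interval.chrom == chrom]
    starts = np.array([s.interval.start for s in segs], dtype=float)
    ends = np.array([s.interval.end for s in segs], dtype=float)
    ploidy = np.array([s.ploidy for s in segs], dtype=float)
    return starts, ends, ploidy


def average_ploidy(
    segments: list[GenomicSegment], interval: GenomicInterval
) -> float:
    """Length-weighted mean ploidy of one sample's segments over ``interval``.

    Returns NaN when no segment overlaps the interval (zero coverage).
    """
    starts, ends, ploidy = _overlap_arrays(segments, interval.chrom)
    if starts.size == 0:
        return float("nan")
    ov = np.clip(np.minimum(ends, interval.end) - np.maximum(starts, interval.start), 0, None)
    total = ov.sum()
    if total == 0:
        return float("nan")
    return float((ov * ploidy).sum() / total)


def classify_ploidy(n: float) -> str:
    """Classify an average ploidy into ``loss`` / ``diploid`` / ``gain``."""
    if not np.isfinite(n) or n < 0:
        raise ValueError(f"average ploidy must be finite and >= 0, got {n}")
    if n >= 3:
        return "gain"
    if n <= 1:
        return "loss"
    return "diploid"


def region_status(
    segments: list[GenomicSegment], region: GenomicInterval
) -> str | None:
    """Classify a sample's average ploidy over a region; None if uncovered."""
    n = average_ploidy(segments, region)
    if np.isnan(n):
        warnings.warn(
            f"no segment coverage over {region.chrom}:{region.start}-{region.end}; "
            "sample excluded from region-stratified analyses",
            stacklevel=2,
        )
        return None
    return classify_ploidy(n)


def cohort_frequency_profile(
    segments: list[GenomicSegment],
    grid: BinGrid,
    mask: list[GenomicInterval] | None = None,
) -> pd.DataFrame:
    """Per-bin fractions of samples called loss/diploid/gain.

    Fractions are computed among samples with coverage in the bin; bins
    overlapping a ``mask`` interval (e.g. centromeric regions) are emitted
    with missing frequencies.
    """
    per_sample = segments_by_sample(segments)
    if not per_sample:
        raise ValueError("at least one sample is required")
    starts, ends = grid.starts.astype(float), grid.ends.astype(float)
    nbins = len(starts)
    counts = {call: np.zeros(nbins) for call in CALLS}
    covered = np.zeros(nbins)

    for segs in per_sample.values():
        s0, e0, pl = _overlap_arrays(segs, grid.chrom)
        if s0.size == 0:
            continue
        # (bins x segments) overlap lengths
        ov = np.clip(
            np.minimum(ends[:, None], e0[None, :]) - np.maximum(starts[:, None], s0[None, :]),
            0,
            None,
        )
        tot = ov.sum(axis=1)
        has = tot > 0
        with np.errstate(invalid="ignore"):
            n = (ov * pl[None, :]).sum(axis=1) / tot
        covered += has
        counts["gain"][has & (n >= 3)] += 1
        counts["loss"][has & (n <= 1) & (n < 3)] += 1
        counts["diploid"][has & (n > 1) & (n < 3)] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = {f"f_{c}": counts[c] / covered for c in CALLS}
    df = pd.DataFrame(
        {
            "chrom": grid.chrom,
            "start": grid.starts,
            "end": grid.ends,
            **freqs,
            "n_covered": covered.astype(int),
        }
    )
    if mask:
        masked = np.zeros(nbins, dtype=bool)
        for iv in mask:
            if iv.chrom != grid.chrom:
                continue
            masked |= (starts < iv.end) & (ends > iv.start)
        df.loc[masked, [f"f_{c}" for c in CALLS]] = np.nan
    return df


def gene_copy_number(
    segments: list[GenomicSegment], gene: GeneModel
) -> float:
    """Average ploidy over the gene body (NaN when uncovered)."""
    return average_ploidy(segments, gene.interval)


def copy_number_matrix(
    segments: list[GenomicSegment], genes: list[GeneModel]
) -> pd.DataFrame:
    """Genes x samples matrix of per-gene average ploidy (NaN = no coverage)."""
    per_sample = segments_by_sample(segments)
    gene_ids = [g.gene_id for g in genes]
    out = pd.DataFrame(
        np.nan, index=pd.Index(gene_ids, name="gene_id"), columns=list(per_sample)
    )
    by_chrom: dict[str, list[tuple[int, GeneModel]]] = {}
    for i, g in enumerate(genes):
        by_chrom.setdefault(g.interval.chrom, []).append((i, g))
    values = out.to_numpy()
    for j, (sample, segs) in enumerate(per_sample.items()):
        for chrom, idx_genes in by_chrom.items():
            s0, e0, pl = _overlap_arrays(segs, chrom)
            if s0.size == 0:
                continue
            gs = np.array([g.interval.start for _, g in idx_genes], dtype=float)
            ge = np.array([g.interval.end for _, g in idx_genes], dtype=float)
            ov = np.clip(
                np.minimum(ge[:, None], e0[None, :]) - np.maximum(gs[:, None], s0[None, :]),
                0,
                None,
            )
            tot = ov.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                n = (ov * pl[None, :]).sum(axis=1) / tot
            rows = np.array([i for i, _ in idx_genes])
            values[rows, j] = n
    return out
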