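"""ChIP-seq coactivator-target screen.

Starting from called peaks for five marks -- the coactivator itself (ALYREF),
MYCN, RNA Pol II, H3K27ac and H3K4me3 -- genes are screened for:

1. promoter co-occupancy of all five marks (promoter = strand-aware
   -1000/+100 bp around the TSS, presence = >= 1 bp peak overlap),
2. coactivator fold enrichment strictly greater than 5 (per gene, the
   maximum FE over its assigned coactivator peaks),
3. association of expression with poor patient outcome (median
   dichotomisation, HR > 1, log-rank p < 0.05),
4. positive correlation with MYCN expression (Bonferroni, r > 0),
5. membership of a user-supplied functional gene set (e.g. ubiquitination
   machinery; no curated database is bundled).

Genes passing criterion 2 are ranked by descending fold enrichment (ties by
gene id); the final candidate list is the all-five-criteria genes in FE-rank
order.  An E-box scanner annotates canonical (CACGTG) and non-canonical
(CANNTG) MYC-family binding motifs in promoter sequences; both patterns are
reverse-complement palindromic as patterns, so a single-strand scan suffices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import association, survival
from .io_formats import GeneModel, GenomicInterval, PeakRecord

__all__ = [
    "PromoterWindow",
    "EBoxHit",
    "promoter_windows",
    "assign_peaks",
    "occupancy_matrix",
    "fe_filter",
    "ebox_scan",
    "chip_target_screen",
    "MARKS",
]

MARKS = ("alyref", "mycn", "polii", "h3k27ac", "h3k4me3")

PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 100


@dataclass(frozen=True)
class PromoterWindow:
    """Strand-aware [TSS-1000, TSS+100) window in transcription orientation."""

    gene_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class EBoxHit:
    position: int
    kind: str  # "canonical" | "non_canonical"
    sequence: str


def promoter_windows(genes: list[GeneModel]) -> list[PromoterWindow]:
    """-1000/+100 bp promoter windows, clipped at the chromosome start."""
    windows = []
    for g in genes:
        if g.interval.strand == "-":
            start = g.tss - PROMOTER_DOWNSTREAM
            end = g.tss + PROMOTER_UPSTREAM
        else:
            start = g.tss - PROMOTER_UPSTREAM
            end = g.tss + PROMOTER_DOWNSTREAM
        start = max(start, 0)
        windows.append(
            PromoterWindow(g.gene_id, GenomicInterval(g.interval.chrom, start, end, g.interval.strand))
        )
    return windows


def assign_peaks(
    peaks: list[PeakRecord], windows: list[PromoterWindow]
) -> dict[str, list[PeakRecord]]:
    """Assign each peak to every promoter window it overlaps by >= 1 base.

    A peak may be assigned to multiple genes.  Raises when the peak and
    window chromosome name sets are disjoint (a naming-convention mismatch).
    """
    peak_chroms = {p.interval.chrom for p in peaks}
    window_chroms = {w.interval.chrom for w in windows}
    if peaks and windows and not (peak_chroms & window_chroms):
        raise ValueError(
            "chromosome names do not match between peaks and gene models: "
            f"peaks use {sorted(peak_chroms)}, genes use {sorted(window_chroms)}"
        )
    by_chrom: dict[str, list[PeakRecord]] = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    assignments: dict[str, list[PeakRecord]] = {w.gene_id: [] for w in windows}
    for w in windows:
        for p in by_chrom.get(w.interval.chrom, ()):
            if p.interval.start < w.interval.end and w.interval.start < p.interval.end:
                assignments[w.gene_id].append(p)
    return assignments


def occupancy_matrix(
    assignments: dict[str, dict[str, list[PeakRecord]]]
) -> pd.DataFrame:
    """Genes x marks boolean occupancy plus the per-gene max coactivator FE.

    ``assignments`` maps mark name -> (gene -> assigned peaks) and must
    contain every mark in ``MARKS``; ``alyref_fe`` is NaN for genes without
    coactivator occupancy.
    """
    missing = [m for m in MARKS if m not in assignments]
    if missing:
        raise ValueError(f"missing peak assignments for marks: {missing}")
    genes = sorted({g for m in MARKS for g in assignments[m]})
    data = {m: [bool(assignments[m].get(g)) for g in genes] for m in MARKS}
    fe = [
        max((p.fold_enrichment for p in assignments["alyref"].get(g, [])), default=np.nan)
        for g in genes
    ]
    df = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    df["alyref_fe"] = fe
    return df


def fe_filter(matrix: pd.DataFrame, threshold: float = 5.0) -> pd.DataFrame:
    """Strict FE filter: pass iff alyref_fe > threshold; rank FE descending.

    Returns the passing genes with an ``fe_rank`` column (1 = highest FE,
    ties broken by gene id).
    """
    passing = (
        matrix.loc[matrix["alyref_fe"] > threshold]
        .reset_index()
        .sort_values(["alyref_fe", "gene_id"], ascending=[False, True], kind="stable")
        .set_index("gene_id")
    )
    passing["fe_rank"] = np.arange(1, len(passing) + 1)
    return passing


_VALID_BASES = frozenset("ACGTN")


def ebox_scan(sequence: str) -> list[EBoxHit]:
    """All 6-mer E-box matches (CANNTG) in a DNA string.

    CACGTG windows are canonical, every other CANNTG match non-canonical;
    windows containing N never match.  Case-insensitive.
    """
    seq = sequence.upper()
    invalid = set(seq) - _VALID_BASES
    if invalid:
        raise ValueError(f"invalid characters in sequence: {sorted(invalid)}")
    hits = []
    for i in range(len(seq) - 5):
        w = seq[i : i + 6]
        if w.startswith("CA") and w.endswith("TG") and "N" not in w:
            kind = "canonical" if w == "CACGTG" else "non_canonical"
            hits.append(EBoxHit(i, kind, w))
    return hits


def chip_target_screen(
    matrix: pd.DataFrame,
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    gene_set,
    mycn_gene: str = "MYCN",
    fe_threshold: float = 5.0,
    endpoint: str = "os",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score candidate genes on the five coactivator-target criteria.

    Parameters
    ----------
    matrix : occupancy matrix from :func:`occupancy_matrix`.
    expr : genes x samples log2 normalised expression (must include
        ``mycn_gene``).
    clinical : per-sample clinical table aligned to ``expr`` columns.
    gene_set : iterable of gene ids satisfying the functional criterion.
    fe_threshold : strict coactivator FE cutoff (default 5).

    Returns a DataFrame indexed by gene with the five criterion flags,
    ``alyref_fe``, ``fe_rank`` (NaN for genes failing the FE filter),
    ``final_pass`` and supporting statistics; sorted with the final
    candidates first in FE-rank order.
    """
    if mycn_gene not in expr.index:
        raise ValueError(f"MYCN gene id {mycn_gene!r} not present in expression matrix")
    gene_set = set(gene_set)
    if not gene_set:
        warnings.warn("empty gene set: no gene can satisfy the functional criterion",
                      stacklevel=2)
    genes = [g for g in matrix.index if g in expr.index]
    dropped = len(matrix) - len(genes)
    if dropped:
        warnings.warn(f"{dropped} occupancy genes missing from expression matrix",
                      stacklevel=2)
    mat = matrix.loc[genes]

    co_occupied = mat[list(MARKS)].all(axis=1)
    fe_pass = mat["alyref_fe"] > fe_threshold
    ranked = fe_filter(mat, threshold=fe_threshold)

    surv = survival.survival_filter(expr.loc[genes], clinical, endpoint=endpoint, alpha=alpha)
    corr = association.correlation_filter(expr.loc[genes], expr.loc[mycn_gene], alpha=alpha)

    out = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    out["co_occupancy"] = co_occupied
    out["fe_pass"] = fe_pass
    out["survival_pass"] = surv["passes"].reindex(genes).fillna(False).astype(bool)
    out["mycn_corr_pass"] = corr["passes"].reindex(genes).fillna(False).astype(bool)
    out["in_gene_set"] = [g in gene_set for g in genes]
    out["final_pass"] = out[
        ["co_occupancy", "fe_pass", "survival_pass", "mycn_corr_pass", "in_gene_set"]
    ].all(axis=1)
    out["alyref_fe"] = mat["alyref_fe"]
    out["fe_rank"] = ranked["fe_rank"].reindex(genes)
    out["hr"] = surv["hr"].reindex(genes)
    out["logrank_p"] = surv["logrank_p"].reindex(genes)
    out["r_mycn"] = corr["r"].reindex(genes)
    out["padj_mycn"] = corr["p_adj"].reindex(genes)
    return out.sort_values(
        ["final_pass", "fe_rank", "gene_id"],
        ascending=[False, True, True],
        kind="stable",
        na_position="last",
    )
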