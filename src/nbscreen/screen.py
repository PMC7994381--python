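"""The five-criterion cohort screen for region driver genes.

Given segmental copy-number calls, a gene-level count matrix, clinical
annotations and gene models, every gene inside a recurrently gained region
(e.g. 17q21-ter) is scored on five boolean criteria:

1. differential over-expression in region-gain vs region-diploid tumours,
2. differential over-expression in MYCN-amplified vs non-amplified tumours,
3. positive expression/copy-number correlation,
4. positive correlation with MYCN expression,
5. association with poor outcome (median-dichotomised HR > 1, log-rank
   p < 0.05).

The score is the number of criteria met (0-5); a gene "passes the screen"
only at score 5.  Differential expression (criteria 1-2) is run
transcriptome-wide -- over every gene in the count table -- with each
stratification computing its own data-dependent log2FC threshold, and the
resulting gene sets are then restricted to the region.  The correlation
criteria use a Bonferroni family of all genes tested in the run.  Only
up-regulation can pass the DE criteria (the threshold is a quantile of the
positive fold-changes), matching a search for over-expressed drivers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import association, cnv_profile, diffexpr, survival
from .io_formats import GeneModel, GenomicInterval, GenomicSegment, segments_by_sample

__all__ = ["five_criteria_screen", "rank_genes", "region_gain_status"]

CRITERIA = ["c1_de_gain", "c2_de_amp", "c3_cn_corr", "c4_mycn_corr", "c5_survival"]


def region_gain_status(
    segments: list[GenomicSegment], region: GenomicInterval
) -> pd.Series:
    """Per-sample region classification (loss/diploid/gain; None uncovered)."""
    per_sample = segments_by_sample(segments)
    return pd.Series(
        {s: cnv_profile.region_status(segs, region) for s, segs in per_sample.items()},
        name="region_status",
        dtype=object,
    )


def five_criteria_screen(
    segments: list[GenomicSegment],
    counts: pd.DataFrame,
    clinical: pd.DataFrame,
    genes: list[GeneModel],
    region: GenomicInterval,
    mycn_gene: str = "MYCN",
    endpoint: str = "os",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score every region gene on the five criteria.

    Returns a DataFrame indexed by gene_id (region genes only), with the five
    boolean criterion flags, the integer ``score``, the deterministic
    ``rank`` and the per-criterion evidence columns (log2FCs and adjusted
    p-values, correlations, HR and log-rank p).
    """
    if mycn_gene not in counts.index:
        raise ValueError(f"MYCN gene id {mycn_gene!r} not present in the count table")
    region_genes = [g for g in genes if g.interval.overlaps(region)]
    if not region_genes:
        raise ValueError("no gene model overlaps the region")
    region_ids = [g.gene_id for g in region_genes]
    missing_counts = [g for g in region_ids if g not in counts.index]
    if missing_counts:
        raise ValueError(f"region genes missing from counts: {missing_counts[:5]}")

    sf = diffexpr.size_factors(counts)
    expr = diffexpr.log2_normalized(counts, sf)

    # --- criterion 1: DE in region-gain vs region-diploid samples ----------
    status = region_gain_status(segments, region).reindex(counts.columns)
    gain_samples = status.index[status == "gain"]
    diploid_samples = status.index[status == "diploid"]
    for name, arm in (("gain", gain_samples), ("diploid", diploid_samples)):
        if len(arm) < 2:
            raise ValueError(
                f"region stratification arm '{name}' has fewer than 2 samples"
            )
    c1_samples = list(diploid_samples) + list(gain_samples)
    c1_labels = np.r_[np.zeros(len(diploid_samples)), np.ones(len(gain_samples))]
    de_gain = diffexpr.nb_wald_test(counts[c1_samples], c1_labels, sf=sf[c1_samples])
    de_gain["p_adj"] = diffexpr.adjust_pvalues(de_gain["p"], method="BH")
    c1_set = diffexpr.de_filter(de_gain, alpha=alpha)

    # --- criterion 2: DE in MYCN-amplified vs non-amplified samples --------
    amp = clinical.loc[counts.columns, "mycn_amplified"].to_numpy(dtype=int)
    for name, m in (("amplified", amp == 1), ("non-amplified", amp == 0)):
        if m.sum() < 2:
            raise ValueError(
                f"amplification stratification arm '{name}' has fewer than 2 samples"
            )
    de_amp = diffexpr.nb_wald_test(counts, amp, sf=sf)
    de_amp["p_adj"] = diffexpr.adjust_pvalues(de_amp["p"], method="BH")
    c2_set = diffexpr.de_filter(de_amp, alpha=alpha)

    # --- criterion 3: expression vs own copy number ------------------------
    cn = cnv_profile.copy_number_matrix(segments, genes)
    cn = cn.reindex(index=expr.index, columns=expr.columns)
    corr_cn = association.correlation_filter(expr, cn, alpha=alpha)

    # --- criterion 4: expression vs MYCN expression ------------------------
    corr_mycn = association.correlation_filter(expr, expr.loc[mycn_gene], alpha=alpha)

    # --- criterion 5: expression vs outcome --------------------------------
    surv = survival.survival_filter(
        expr.loc[region_ids], clinical, endpoint=endpoint, alpha=alpha
    )

    out = pd.DataFrame(index=pd.Index(region_ids, name="gene_id"))
    out["c1_de_gain"] = [g in c1_set for g in region_ids]
    out["c2_de_amp"] = [g in c2_set for g in region_ids]
    out["c3_cn_corr"] = corr_cn["passes"].reindex(region_ids).fillna(False).astype(bool)
    out["c4_mycn_corr"] = corr_mycn["passes"].reindex(region_ids).fillna(False).astype(bool)
    out["c5_survival"] = surv["passes"].reindex(region_ids).fillna(False).astype(bool)
    out["score"] = out[CRITERIA].sum(axis=1).astype(int)

    out["log2fc_gain"] = de_gain["log2fc"].reindex(region_ids)
    out["padj_gain"] = de_gain["p_adj"].reindex(region_ids)
    out["log2fc_amp"] = de_amp["log2fc"].reindex(region_ids)
    out["padj_amp"] = de_amp["p_adj"].reindex(region_ids)
    out["r_cn"] = corr_cn["r"].reindex(region_ids)
    out["padj_cn"] = corr_cn["p_adj"].reindex(region_ids)
    out["r_mycn"] = corr_mycn["r"].reindex(region_ids)
    out["padj_mycn"] = corr_mycn["p_adj"].reindex(region_ids)
    out["hr"] = surv["hr"].reindex(region_ids)
    out["logrank_p"] = surv["logrank_p"].reindex(region_ids)
    return rank_genes(out)


def rank_genes(results: pd.DataFrame) -> pd.DataFrame:
    """Deterministic ranking: score desc, HR desc, DE adjusted p asc, gene id.

    Input-order independent; NaN evidence sorts last within its tie group.
    """
    df = results.copy()
    hr_key = df["hr"].fillna(-np.inf) if "hr" in df else pd.Series(-np.inf, index=df.index)
    padj_key = (
        df["padj_gain"].fillna(np.inf) if "padj_gain" in df else pd.Series(np.inf, index=df.index)
    )
    keys = pd.DataFrame(
        {
            "neg_score": -df["score"].to_numpy(),
            "neg_hr": -hr_key.to_numpy(),
            "padj": padj_key.to_numpy(),
            "gene": df.index.to_numpy(),
        },
        index=df.index,
    )
    order = keys.sort_values(["neg_score", "neg_hr", "padj", "gene"], kind="stable").index
    df = df.loc[order]
    df["rank"] = np.arange(1, len(df) + 1)
    return df
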