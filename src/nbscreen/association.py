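"""Pearson-correlation screening criteria.

Each gene's expression (log2 normalised counts) is correlated against either
its own copy number or the expression of a reference gene (MYCN).  Raw
two-sided p-values come from the exact t transform of the sample correlation;
family-wise control is Bonferroni over all genes tested in the run, and a
gene passes only with adjusted p < 0.05 AND r > 0 (positive association).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import adjust_pvalues

__all__ = ["pearson", "correlation_filter"]


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r and two-sided p after pairwise missing-value removal.

    The p-value uses t = r * sqrt((N-2) / (1-r^2)) on N-2 degrees of freedom.
    Raises for fewer than 3 complete pairs or zero variance in either vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("at least 3 complete pairs are required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlation_filter(
    expr: pd.DataFrame,
    target,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate every gene's expression against a target vector (or matrix).

    Parameters
    ----------
    expr : genes x samples expression matrix (log2 normalised counts).
    target : either a per-sample Series (one common target, e.g. MYCN
        expression) or a genes x samples DataFrame giving each gene its own
        target vector (e.g. its copy number profile).
    alpha : family-wise significance level for the Bonferroni-adjusted p.

    Returns a DataFrame indexed by gene with ``r``, ``p``, ``p_adj`` and
    ``passes`` (adjusted p < alpha AND r > 0).  Genes with an undefined
    correlation (fewer than 3 complete pairs, zero variance) get NaN
    statistics and are excluded from the Bonferroni family.
    """
    genes = expr.index
    r = np.full(len(genes), np.nan)
    p = np.full(len(genes), np.nan)
    if isinstance(target, pd.DataFrame):
        target = target.reindex(index=genes, columns=expr.columns)
        per_gene = True
    else:
        target = pd.Series(target, index=expr.columns).astype(float)
        per_gene = False

    ev = expr.to_numpy(dtype=float)
    tv = target.to_numpy(dtype=float)
    for i in range(len(genes)):
        t = tv[i] if per_gene else tv
        try:
            r[i], p[i] = pearson(ev[i], t)
        except ValueError:
            continue
    p_adj = adjust_pvalues(p, method="Bonferroni")
    passes = np.where(np.isnan(p_adj), False, (p_adj < alpha) & (r > 0))
    return pd.DataFrame(
        {"r": r, "p": p, "p_adj": p_adj, "passes": passes},
        index=genes.rename("gene_id"),
    )
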