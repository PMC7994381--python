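"""Two-group negative-binomial differential expression on raw counts.

The model for gene *g* in sample *i* is

    K_gi ~ NB(mean = s_i * exp(b0_g + b1_g * x_i), dispersion = alpha_g)

with ``x_i`` the binary group label and ``s_i`` a median-of-ratios size
factor.  ``b1`` (the log fold-change) is tested with a two-sided Wald
chi-squared test.  The per-gene dispersion is a plain method-of-moments
estimate on normalised counts, floored at 1e-8 -- deliberately *without*
the shrinkage used by DESeq2-style tools, so the stage is self-contained.

Downstream filtering follows a data-dependent rule: genes pass when their
BH-adjusted p-value is < 0.05 AND their log2 fold-change is at least the
lower quartile of all *positive* log2 fold-changes among the adjusted-p
significant genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "size_factors",
    "nb_wald_test",
    "adjust_pvalues",
    "lfc_threshold",
    "de_filter",
    "log2_normalized",
]

_LN2 = np.log(2.0)
_MIN_DISPERSION = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Only genes with nonzero counts in every sample enter the pseudo-reference;
    raises if no such gene exists.
    """
    k = counts.to_numpy(dtype=float)
    samples = counts.columns
    if k.shape[1] == 1:
        return pd.Series([1.0], index=samples, name="size_factor")
    expressed = (k > 0).all(axis=1)
    if not expressed.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; a pseudo-reference "
            "fallback (e.g. poscounts) would be required"
        )
    logk = np.log(k[expressed])
    log_ratios = logk - logk.mean(axis=1, keepdims=True)
    log_sf = np.median(log_ratios, axis=0)
    log_sf -= log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=samples, name="size_factor")


def _mom_dispersion(y: np.ndarray, group_masks: list[np.ndarray]) -> np.ndarray:
    """Pooled within-group method-of-moments dispersion per gene."""
    num = np.zeros(y.shape[0])
    den = 0.0
    for mask in group_masks:
        n_g = int(mask.sum())
        if n_g < 2:
            continue
        yg = y[:, mask]
        m = yg.mean(axis=1)
        v = yg.var(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            contrib = np.where(m > 0, (v - m) / np.square(m), 0.0)
        num += (n_g - 1) * np.nan_to_num(contrib)
        den += n_g - 1
    alpha = num / den if den > 0 else np.zeros(y.shape[0])
    return np.maximum(alpha, _MIN_DISPERSION)


def _fit_group_log_mean(
    k: np.ndarray, s: np.ndarray, alpha: np.ndarray, max_iter: int = 100, tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene NB MLE of the group log-mean via Fisher scoring.

    Returns (eta, info) with ``eta`` the fitted log mean (per normalised
    count) and ``info`` the Fisher information for it.  Groups whose counts
    sum to zero are floored at half a count so the Wald contrast stays finite.
    """
    tot = np.maximum(k.sum(axis=1), 0.5)
    eta = np.log(tot / s.sum())
    a = alpha[:, None]
    for _ in range(max_iter):
        mu = s[None, :] * np.exp(eta)[:, None]
        denom = 1.0 + a * mu
        score = ((k - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = score / info
        np.clip(step, -5.0, 5.0, out=step)
        eta = eta + step
        if np.max(np.abs(step)) < tol:
            break
    mu = s[None, :] * np.exp(eta)[:, None]
    info = (mu / (1.0 + a * mu)).sum(axis=1)
    return eta, info


def nb_wald_test(
    counts: pd.DataFrame,
    groups,
    sf: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test of group 1 vs group 0.

    Parameters
    ----------
    counts : genes x samples integer DataFrame.
    groups : binary labels aligned to ``counts.columns`` (0 = reference).
    sf : optional precomputed size factors.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (group 1 over
    group 0), ``se`` (of log2fc), ``p``, ``dispersion``.  Genes with zero
    counts in both groups are untestable: their statistics are NaN and they
    are excluded from any subsequent multiplicity adjustment.
    """
    x = np.asarray(groups)
    if x.shape[0] != counts.shape[1]:
        raise ValueError("groups must align with counts columns")
    x = x.astype(int)
    if not np.isin(x, [0, 1]).all():
        raise ValueError("groups must be binary (0/1)")
    m0, m1 = x == 0, x == 1
    if not m0.any() or not m1.any():
        raise ValueError("both groups must be non-empty")
    if sf is None:
        sf = size_factors(counts)
    s = sf.to_numpy(dtype=float)
    k = counts.to_numpy(dtype=float)
    y = k / s[None, :]
    testable = k.sum(axis=1) > 0

    alpha = _mom_dispersion(y, [m0, m1])
    eta0, info0 = _fit_group_log_mean(k[:, m0], s[m0], alpha)
    eta1, info1 = _fit_group_log_mean(k[:, m1], s[m1], alpha)
    beta1 = eta1 - eta0
    se = np.sqrt(1.0 / info0 + 1.0 / info1)
    wald = np.square(beta1 / se)
    p = stats.chi2.sf(wald, df=1)

    out = pd.DataFrame(
        {
            "log2fc": beta1 / _LN2,
            "se": se / _LN2,
            "p": p,
            "dispersion": alpha,
        },
        index=counts.index.rename("gene_id"),
    )
    out.loc[~testable, ["log2fc", "se", "p"]] = np.nan
    return out


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg (``BH``) or ``Bonferroni`` adjustment.

    NaN entries (untestable genes) are passed through and do not count
    towards the family size.  Order-preserving.
    """
    p = np.asarray(p, dtype=float)
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    key = method.strip().lower()
    try:
        sm_method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[key]
    except KeyError:
        raise ValueError(f"unknown adjustment method {method!r}") from None
    out = np.full(p.shape, np.nan)
    if finite.any():
        out[finite] = multipletests(p[finite], method=sm_method)[1]
    return out


def lfc_threshold(results: pd.DataFrame, alpha: float = 0.05) -> float:
    """Lower quartile of positive log2FCs among adjusted-p significant genes.

    ``results`` must carry ``log2fc`` and ``p_adj`` columns.  Returns NaN when
    no gene qualifies (the filter is then vacuous).
    """
    qualifying = results.loc[
        (results["p_adj"] < alpha) & (results["log2fc"] > 0), "log2fc"
    ].to_numpy()
    if qualifying.size == 0:
        return float("nan")
    return float(np.quantile(qualifying, 0.25))  # linear interpolation


def de_filter(results: pd.DataFrame, alpha: float = 0.05) -> set[str]:
    """Genes with ``p_adj < alpha`` and ``log2fc >=`` the quartile threshold."""
    thr = lfc_threshold(results, alpha=alpha)
    if np.isnan(thr):
        return set()
    passing = results.index[(results["p_adj"] < alpha) & (results["log2fc"] >= thr)]
    return set(passing)


def log2_normalized(counts: pd.DataFrame, sf: pd.Series | None = None) -> pd.DataFrame:
    """log2(count / size_factor + 1) expression matrix."""
    if sf is None:
        sf = size_factors(counts)
    return np.log2(counts / sf + 1.0)
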