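"""Negative-binomial differential expression for tumor-vs-normal counts.

A self-contained NB Wald test: median-of-ratios size factors, gene-wise
method-of-moments dispersion on normalized counts, log2 fold change with a
0.5 pseudocount, delta-method standard error, two-sided normal p, and
Benjamini-Hochberg FDR.  A gene is significant when FDR < 0.05 and
|log2FC| > 1 (both thresholds configurable).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 1e-8


def normalize_counts(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Parameters
    ----------
    counts : genes x samples non-negative integer matrix.

    Returns
    -------
    (size_factors, normalized) where normalized = counts / size_factor.
    """
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    zero_samples = counts.columns[(mat.sum(axis=0) == 0)]
    if len(zero_samples):
        raise ValueError(f"sample(s) with all-zero counts: {list(zero_samples)}")
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no gene with all-positive counts; cannot form reference")
    log_ref = np.log(mat[all_pos]).mean(axis=1)  # log geometric means
    log_ratios = np.log(mat[all_pos]) - log_ref[:, None]
    sf = np.exp(np.median(log_ratios, axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))  # geometric mean 1
    size_factors = pd.Series(sf, index=counts.columns, name="size_factor")
    normalized = counts / sf
    return size_factors, normalized


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def test_de(
    counts: pd.DataFrame,
    condition: pd.Series,
    fdr_cut: float = 0.05,
    lfc_cut: float = 1.0,
) -> pd.DataFrame:
    """Per-gene NB Wald test of tumor vs normal.

    ``condition`` maps sample -> "tumor" | "normal" and must cover the count
    columns with at least 2 samples per condition.  Genes with all-zero
    counts are excluded from testing and flagged in the ``tested`` column.

    Returns a frame indexed by gene_id with columns log2fc, p_value, fdr,
    significant, tested (fdr/significant are NaN/False for untested genes).
    """
    condition = condition.loc[counts.columns]
    t_cols = condition[condition == "tumor"].index
    n_cols = condition[condition == "normal"].index
    if len(t_cols) < 2 or len(n_cols) < 2:
        raise ValueError("need >=2 samples per condition")

    _, norm = normalize_counts(counts)
    nt = norm[t_cols].to_numpy()
    nn = norm[n_cols].to_numpy()
    mu_t = nt.mean(axis=1)
    mu_n = nn.mean(axis=1)

    tested = (mu_t + mu_n) > 0
    lfc = np.log2((mu_t + PSEUDOCOUNT) / (mu_n + PSEUDOCOUNT))

    # pooled within-group method-of-moments dispersion on normalized counts
    var_t = nt.var(axis=1, ddof=1)
    var_n = nn.var(axis=1, ddof=1)
    w_t, w_n = len(t_cols) - 1, len(n_cols) - 1
    var_pooled = (w_t * var_t + w_n * var_n) / (w_t + w_n)
    mu_pooled = (mu_t * len(t_cols) + mu_n * len(n_cols)) / (len(t_cols) + len(n_cols))
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var_pooled - mu_pooled) / np.square(mu_pooled)
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    # delta-method SE of log2fc from NB variance of each group mean
    mt = mu_t + PSEUDOCOUNT
    mn = mu_n + PSEUDOCOUNT
    var_mean_t = (mu_t + alpha * mu_t**2) / len(t_cols)
    var_mean_n = (mu_n + alpha * mu_n**2) / len(n_cols)
    se = np.sqrt(var_mean_t / mt**2 + var_mean_n / mn**2) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, 0.0, 1.0)

    fdr = np.full(len(counts), np.nan)
    if tested.any():
        fdr[tested] = bh_adjust(p[tested])
    significant = tested & (fdr < fdr_cut) & (np.abs(lfc) > lfc_cut)

    return pd.DataFrame(
        {
            "log2fc": lfc,
            "p_value": np.where(tested, p, np.nan),
            "fdr": fdr,
            "significant": significant,
            "tested": tested,
        },
        index=counts.index,
    )
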