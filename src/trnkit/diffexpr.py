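"""Count normalization and negative-binomial differential expression.

A deliberately simple two-group NB test: median-of-ratios size factors,
method-of-moments gene dispersion with a small floor, a Wald test on the
log fold change, and Benjamini-Hochberg adjustment. No fold-change shrinkage
and no empirical-Bayes dispersion moderation; downstream consumers only use
threshold-gated DEG sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["size_factors", "nb_wald_test", "filter_degs"]

DISPERSION_FLOOR = 1e-8
MIN_NORMALIZED_MEAN = 1.0


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Ratios are taken against the per-gene geometric mean over genes with
    all-positive counts. If no gene is positive in every sample, pass
    ``pseudo_reference=True`` to fall back to a +1-pseudocount reference.
    """
    X = counts.to_numpy(dtype=float)
    positive = (X > 0).all(axis=1)
    if not positive.any():
        if not pseudo_reference:
            raise ValueError(
                "no gene has positive counts in every sample; "
                "re-run with pseudo_reference=True"
            )
        X = X + 1.0
        positive = np.ones(X.shape[0], dtype=bool)
    sub = X[positive]
    gm = np.exp(np.log(sub).mean(axis=1, keepdims=True))
    factors = np.median(sub / gm, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _moment_dispersion(
    a: np.ndarray, b: np.ndarray, mean_a: np.ndarray, mean_b: np.ndarray
) -> np.ndarray:
    """Pooled method-of-moments NB dispersion alpha with a floor.

    Solves var = mu + alpha * mu**2 within each group and pools the excess
    variance weighted by degrees of freedom.
    """
    na, nb = a.shape[1], b.shape[1]
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    num = (na - 1) * (var_a - mean_a) + (nb - 1) * (var_b - mean_b)
    den = (na - 1) * mean_a**2 + (nb - 1) * mean_b**2
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = num / den
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    return np.maximum(alpha, DISPERSION_FLOOR)


def nb_wald_test(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    contrast: tuple[str, str],
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test of `contrast` = (condition, reference).

    Returns a table with gene, baseMean, log2FC, pvalue, padj and a flag
    column. All-zero genes and genes with mean normalized count below
    MIN_NORMALIZED_MEAN are flagged and excluded from testing and from the
    BH denominator.
    """
    condition, reference = contrast
    cond_col = annotation["condition"]
    a_samples = cond_col.index[cond_col == reference]
    b_samples = cond_col.index[cond_col == condition]
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError("both contrast levels need at least 2 samples")

    if factors is None:
        factors = size_factors(counts)
    norm = counts / factors

    A = norm[a_samples].to_numpy(dtype=float)
    B = norm[b_samples].to_numpy(dtype=float)
    na, nb = A.shape[1], B.shape[1]
    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    base_mean = norm.to_numpy().mean(axis=1)

    all_zero = (counts.to_numpy() == 0).all(axis=1)
    low = (np.concatenate([A, B], axis=1).mean(axis=1) < MIN_NORMALIZED_MEAN) & ~all_zero
    tested = ~(all_zero | low)

    eps = 1e-8
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2((mean_b + eps) / (mean_a + eps))
    log2fc[all_zero] = 0.0

    alpha = _moment_dispersion(A, B, np.maximum(mean_a, eps), np.maximum(mean_b, eps))
    # delta-method variance of ln(mean) per group: (1/mu + alpha) / n
    se = np.sqrt(
        (1.0 / np.maximum(mean_a, eps) + alpha) / na
        + (1.0 / np.maximum(mean_b, eps) + alpha) / nb
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (log2fc * np.log(2.0)) / se
    # t reference with pooled df: small-sample guard against the moment
    # dispersion's underestimation at few replicates
    df = na + nb - 2
    pvalue = np.where(tested, 2.0 * stats.t.sf(np.abs(z), df), np.nan)

    padj = np.full(len(pvalue), np.nan)
    if tested.any():
        padj[tested] = multipletests(pvalue[tested], method="fdr_bh")[1]

    flag = np.where(all_zero, "all_zero", np.where(low, "low_count", ""))
    return pd.DataFrame(
        {
            "gene": counts.index,
            "baseMean": base_mean,
            "log2FC": log2fc,
            "pvalue": pvalue,
            "padj": padj,
            "flag": flag,
        }
    ).set_index("gene")


def filter_degs(
    table: pd.DataFrame,
    lfc_min: float = 1.0,
    padj_max: float = 0.01,
    direction: str = "both",
) -> set[str]:
    """Strict-inequality DEG gate: |log2FC| > lfc_min and padj < padj_max."""
    if lfc_min < 0:
        raise ValueError("lfc_min must be >= 0")
    if direction not in ("up", "down", "both"):
        raise ValueError(f"direction must be up/down/both, got {direction!r}")
    if table.empty:
        return set()
    ok_p = table["padj"] < padj_max
    lfc = table["log2FC"]
    if direction == "up":
        ok_l = lfc > lfc_min
    elif direction == "down":
        ok_l = lfc < -lfc_min
    else:
        ok_l = lfc.abs() > lfc_min
    return set(table.index[ok_p & ok_l])
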