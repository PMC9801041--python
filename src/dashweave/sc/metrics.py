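"""Single-cell computations behind the page templates.

Per-cell QC metrics (total counts, detected genes, percent mitochondrial),
categorical aggregation, highly-variable-gene (HVG) selection via a
mean-variance trend, and group-vs-rest marker ranking.

Normalization is a single documented choice used for both HVG selection and
marker scores: counts-per-10k followed by ``log1p`` (CP10K/log1p). The HVG
trend is a rolling-median fit of log-variance against log-mean over
equal-count bins, interpolated per gene; a gene's residual is its
log-variance minus the fitted log-trend, and the top ``n_top`` residuals are
flagged. The trend fit is isolated in :func:`rolling_median_trend` so a
different variance model can be substituted without touching callers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ..errors import ConfigurationError, OptionError
from .dataset import SCDataset

__all__ = [
    "qc_metrics",
    "aggregate_by_group",
    "lognorm_cp10k",
    "rolling_median_trend",
    "mean_variance_hvg",
    "rank_markers",
    "pca_embedding",
]

#: Aggregation functions accepted by :func:`aggregate_by_group`.
AGG_FUNS = ("mean", "median", "sum")

#: Library-size scale factor of the CP10K normalization.
CP10K_SCALE = 1e4


def qc_metrics(ds: SCDataset) -> pd.DataFrame:
    """Per-cell quality metrics.

    Returns one row per cell with ``total_counts`` (sum of counts),
    ``detected_genes`` (genes with count > 0), ``pct_mito`` (percent of
    counts in mitochondria-flagged genes, 0-100) and ``zero_total`` (flag
    for all-zero cells, which get ``pct_mito`` 0).

    Raises
    ------
    ConfigurationError
        If the count matrix has negative entries.
    """
    X = ds.counts
    if sp.issparse(X):
        if X.data.size and X.data.min() < 0:
            raise ConfigurationError("count matrix has negative entries")
        total = np.asarray(X.sum(axis=1)).ravel()
        detected = np.asarray((X > 0).sum(axis=1)).ravel()
        mito_total = np.asarray(X[:, ds.gene_meta["mito"].to_numpy()].sum(axis=1)).ravel()
    else:
        X = np.asarray(X)
        if X.size and X.min() < 0:
            raise ConfigurationError("count matrix has negative entries")
        total = X.sum(axis=1)
        detected = (X > 0).sum(axis=1)
        mito_total = X[:, ds.gene_meta["mito"].to_numpy()].sum(axis=1)
    zero = total == 0
    pct_mito = np.zeros_like(total, dtype=float)
    np.divide(mito_total, total, out=pct_mito, where=~zero)
    return pd.DataFrame(
        {
            "total_counts": total.astype(float),
            "detected_genes": detected.astype(int),
            "pct_mito": pct_mito * 100.0,
            "zero_total": zero,
        }
    )


def aggregate_by_group(values, groups, fun: str = "mean") -> pd.DataFrame:
    """Summarize *values* per level of *groups* with mean, median or sum.

    Returns a table with one row per observed level, in sorted level order,
    with columns ``level`` and ``value``.
    """
    if fun not in AGG_FUNS:
        raise OptionError(
            f"unknown aggregation {fun!r}; valid functions: {', '.join(AGG_FUNS)}"
        )
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ConfigurationError(
            f"values ({len(values)}) and groups ({len(groups)}) differ in length"
        )
    s = pd.Series(values).groupby(pd.Series(groups).astype(str), sort=True)
    agg = getattr(s, fun)()
    return pd.DataFrame({"level": agg.index.to_numpy(), "value": agg.to_numpy()})


def lognorm_cp10k(ds: SCDataset) -> np.ndarray:
    """CP10K/log1p normalized expression, dense cells x genes.

    Each cell's counts are scaled to a library size of 10,000 then
    ``log1p``-transformed; all-zero cells stay all zero.
    """
    X = ds.counts_dense()
    total = X.sum(axis=1, keepdims=True)
    scale = np.divide(CP10K_SCALE, total, out=np.zeros_like(total), where=total > 0)
    return np.log1p(X * scale)


def rolling_median_trend(
    log_mean: np.ndarray, log_var: np.ndarray, n_bins: int = 20
) -> np.ndarray:
    """Rolling-median mean-variance trend.

    Genes are ordered by ``log_mean`` and split into ``n_bins`` equal-count
    bins; each bin contributes (median log-mean, median log-variance); the
    fitted log-variance per gene is the linear interpolation of those knots
    (constant extrapolation beyond the outer knots). Only finite inputs
    contribute to the fit; non-finite genes get a non-finite fit back.
    """
    ok = np.isfinite(log_mean) & np.isfinite(log_var)
    fitted = np.full_like(log_mean, -np.inf, dtype=float)
    if ok.sum() == 0:
        return fitted
    lm, lv = log_mean[ok], log_var[ok]
    order = np.argsort(lm, kind="stable")
    n_bins = max(1, min(n_bins, len(lm) // 2 or 1))
    bins = np.array_split(order, n_bins)
    knots_x = np.array([np.median(lm[b]) for b in bins])
    knots_y = np.array([np.median(lv[b]) for b in bins])
    uniq, idx = np.unique(knots_x, return_index=True)
    fitted[ok] = np.interp(lm, uniq, knots_y[idx])
    return fitted


def mean_variance_hvg(ds: SCDataset, n_top: int, n_bins: int = 20) -> pd.DataFrame:
    """Highly-variable-gene selection from the mean-variance relationship.

    Per gene on CP10K/log1p expression: ``mean``, ``variance`` (ddof=1),
    ``trend_fitted`` (variance predicted by the rolling-median trend),
    ``residual`` (log-variance minus log-trend) and ``hvg_flag``. Exactly
    ``n_top`` genes are flagged: the largest residuals, ties broken by gene
    id in lexicographic order. Genes with zero mean or zero variance have no
    meaningful residual and are never flagged before informative genes.
    """
    if n_top > ds.n_genes:
        raise OptionError(f"n_top={n_top} exceeds gene count {ds.n_genes}")
    if n_top < 1:
        raise OptionError("n_top must be a positive integer")
    Y = lognorm_cp10k(ds)
    mean = Y.mean(axis=0)
    var = Y.var(axis=0, ddof=1) if ds.n_cells > 1 else np.zeros(ds.n_genes)
    with np.errstate(divide="ignore"):
        log_mean = np.log(mean)
        log_var = np.log(var)
    trend_log = rolling_median_trend(log_mean, log_var, n_bins=n_bins)
    with np.errstate(invalid="ignore"):
        residual = log_var - trend_log
    residual = np.where(np.isfinite(residual), residual, -np.inf)
    gene_ids = ds.gene_ids.astype(str)
    # descending residual, ascending gene id on ties
    order = np.lexsort((gene_ids, -residual))
    flag = np.zeros(ds.n_genes, dtype=bool)
    flag[order[:n_top]] = True
    trend_fitted = np.where(np.isfinite(trend_log), np.exp(trend_log), 0.0)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "mean": mean,
            "variance": var,
            "trend_fitted": trend_fitted,
            "residual": residual,
            "hvg_flag": flag,
        }
    )


def rank_markers(ds: SCDataset, group_var: str, n_top: int = 10) -> pd.DataFrame:
    """Group-vs-rest marker ranking.

    For each level of ``cell_meta[group_var]`` and each gene, the score is
    the mean CP10K/log1p expression within the group minus the mean over all
    other cells. Returns the ``n_top`` highest-scoring genes per group (ties
    broken by gene id), with columns ``group``, ``gene_id``, ``score`` and
    ``rank`` (1..n_top, scores non-increasing).
    """
    if group_var not in ds.cell_meta.columns:
        raise OptionError(f"cell_meta has no column {group_var!r}")
    groups = ds.cell_meta[group_var].astype(str).to_numpy()
    levels = sorted(set(groups))
    if len(levels) < 2:
        raise OptionError(
            f"marker ranking needs >= 2 levels of {group_var!r}, found {len(levels)}"
        )
    if n_top < 1 or n_top > ds.n_genes:
        raise OptionError(f"n_top must be in [1, {ds.n_genes}], got {n_top}")
    Y = lognorm_cp10k(ds)
    gene_ids = ds.gene_ids.astype(str)
    rows = []
    for level in levels:
        mask = groups == level
        score = Y[mask].mean(axis=0) - Y[~mask].mean(axis=0)
        order = np.lexsort((gene_ids, -score))[:n_top]
        for rank, gi in enumerate(order, start=1):
            rows.append(
                {"group": level, "gene_id": gene_ids[gi], "score": float(score[gi]), "rank": rank}
            )
    return pd.DataFrame(rows)


def pca_embedding(ds: SCDataset) -> np.ndarray:
    """Deterministic 2D linear projection (top-2 principal directions of the
    CP10K/log1p matrix), the built-in fallback when no embedding is supplied.

    The sign of each direction is fixed so that its largest-magnitude
    loading is positive, making the projection reproducible across runs and
    platforms.
    """
    Y = lognorm_cp10k(ds)
    Yc = Y - Y.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(Yc, full_matrices=False)
    comps = vt[:2]
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return Yc @ comps.T
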