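"""Diagnostic statistics for scRNA-seq count matrices.

The central quantity is the count-depth rate: for each gene, the slope of a
median (least-absolute-deviation) quantile regression of log nonzero
expression on log per-cell sequencing depth.  Under proportional scaling the
slope is one; systematic departures are summarized by splitting genes into
equally sized expression groups, locating the mode of each group's slope
density, and taking the median absolute deviation of the modes from one (the
MAD statistic).

The module also provides detection-rate summaries, depth-matched dataset
comparison, a mean-variance trend decomposition for highly variable genes,
QC cell filters, silhouette summaries of externally produced embeddings, and
a polynomial test for dynamic genes along a supplied pseudotime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import stats
from scipy.stats import gaussian_kde, rankdata
from sklearn.metrics import roc_auc_score, silhouette_samples
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.regression.quantile_regression import QuantReg
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix

ArrayLike = Union[np.ndarray, CountMatrix]

KDE_GRID = np.linspace(-3.0, 3.0, 512)


def _values(counts: ArrayLike) -> np.ndarray:
    return counts.values if isinstance(counts, CountMatrix) else np.asarray(counts)


# ---------------------------------------------------------------------------
# detection rates
# ---------------------------------------------------------------------------

def cell_detection_rates(counts: ArrayLike) -> np.ndarray:
    """Per-cell fraction of genes with nonzero expression."""
    v = _values(counts)
    return np.count_nonzero(v, axis=0) / v.shape[0]


def gene_detection_rates(counts: ArrayLike) -> np.ndarray:
    """Per-gene fraction of cells with nonzero expression."""
    v = _values(counts)
    return np.count_nonzero(v, axis=1) / v.shape[1]


@dataclass
class DetectionSummary:
    cell_rates: np.ndarray
    gene_rates: np.ndarray
    n_detected_all_cells: int
    n_detected_no_cells: int


def detection_summary(counts: ArrayLike) -> DetectionSummary:
    cr = cell_detection_rates(counts)
    gr = gene_detection_rates(counts)
    return DetectionSummary(cell_rates=cr, gene_rates=gr,
                            n_detected_all_cells=int(np.sum(gr == 1.0)),
                            n_detected_no_cells=int(np.sum(gr == 0.0)))


# ---------------------------------------------------------------------------
# depth matching and detection comparison
# ---------------------------------------------------------------------------

def depth_matched_subset(counts_a: ArrayLike, counts_b: ArrayLike,
                         tolerance: Optional[float] = None,
                         min_cells: int = 1):
    """Trim cells so the two datasets have (near-)equal mean sequencing depth.

    Greedy: while the mean depths differ by more than the tolerance (default
    0.5% of the pooled mean depth), remove from the deeper dataset the cell
    whose removal most reduces the gap.  Returns (idx_a, idx_b, achieved_gap).
    """
    da = _values(counts_a).sum(axis=0).astype(float)
    db = _values(counts_b).sum(axis=0).astype(float)
    if da.size < 2 or db.size < 2:
        raise ValueError("need at least 2 cells in each dataset")
    if tolerance is None:
        tolerance = 0.005 * float(np.concatenate([da, db]).mean())
    keep_a = list(range(da.size))
    keep_b = list(range(db.size))
    while True:
        ma, mb = da[keep_a].mean(), db[keep_b].mean()
        gap = abs(ma - mb)
        if gap <= tolerance:
            break
        deeper, keep = (da, keep_a) if ma > mb else (db, keep_b)
        if len(keep) - 1 < min_cells:
            warnings.warn(f"depth matching stopped at the {min_cells}-cell floor; "
                          f"residual gap {gap:.1f}")
            break
        vals = deeper[keep]
        others_mean = (db[keep_b].mean() if deeper is da else da[keep_a].mean())
        # removing cell i changes the deeper mean to (sum - v_i)/(k - 1)
        new_means = (vals.sum() - vals) / (len(keep) - 1)
        best = int(np.argmin(np.abs(new_means - others_mean)))
        keep.pop(best)
    achieved = abs(da[keep_a].mean() - db[keep_b].mean())
    return np.asarray(keep_a), np.asarray(keep_b), float(achieved)


def detection_rate_comparison(counts_a: ArrayLike, counts_b: ArrayLike,
                              n_groups: int = 4):
    """Per-gene detection-rate differences on depth-matched subsets.

    Genes are grouped into n_groups equally sized bins by their nonzero
    median expression in the pooled data.  Returns a dict with per-gene
    'delta' (rate_A - rate_B), 'group' (1-based), and per-group fractions of
    genes increasing / decreasing / tied.
    """
    va, vb = _values(counts_a), _values(counts_b)
    if va.shape[0] != vb.shape[0]:
        raise ValueError("datasets must share the gene universe")
    ia, ib, _ = depth_matched_subset(va, vb)
    dr_a = gene_detection_rates(va[:, ia])
    dr_b = gene_detection_rates(vb[:, ib])
    delta = dr_a - dr_b
    pooled = np.hstack([va, vb])
    med = _nonzero_median(pooled)
    group = _split_into_groups(med, n_groups)
    frac = {}
    for k in range(1, n_groups + 1):
        in_g = group == k
        n = int(in_g.sum())
        frac[k] = {
            "increasing": float(np.sum(delta[in_g] > 0) / n) if n else np.nan,
            "decreasing": float(np.sum(delta[in_g] < 0) / n) if n else np.nan,
            "tied": float(np.sum(delta[in_g] == 0) / n) if n else np.nan,
        }
    return {"delta": delta, "group": group, "group_fractions": frac,
            "cells_a": ia, "cells_b": ib}


# ---------------------------------------------------------------------------
# count-depth rate
# ---------------------------------------------------------------------------

def _split_into_groups(medians: np.ndarray, k: int) -> np.ndarray:
    """Contiguous equal-size (+-1) groups 1..k by ascending median, ties by index."""
    idx = np.arange(medians.size)
    order = idx[np.lexsort((idx, medians))]
    group = np.zeros(medians.size, dtype=int)
    for gi, chunk in enumerate(np.array_split(order, k), start=1):
        group[chunk] = gi
    return group


def _nonzero_median(values: np.ndarray) -> np.ndarray:
    """Median of the nonzero entries per gene (0 for all-zero genes)."""
    out = np.zeros(values.shape[0])
    for g in range(values.shape[0]):
        nz = values[g][values[g] > 0]
        if nz.size:
            out[g] = np.median(nz)
    return out


def filter_genes_for_slopes(counts: ArrayLike, umi_mode: bool = False) -> np.ndarray:
    """Gene mask for count-depth-rate estimation.

    Non-UMI: at least 10 nonzero cells and nonzero median >= 2.  UMI data are
    sparser, so every gene with a nonzero mean is retained.
    """
    v = _values(counts)
    if umi_mode:
        return v.mean(axis=1) > 0
    n_nonzero = np.count_nonzero(v, axis=1)
    med = _nonzero_median(v)
    return (n_nonzero >= 10) & (med >= 2)


def lad_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Slope of the 0.5-quantile (least-absolute-deviation) line of y on x.

    The LAD objective min_{a,b} sum |y - a - b x| is convex and piecewise
    linear in the slope, with breakpoints at the pairwise slopes
    (y_i - y_j)/(x_i - x_j); an optimum is always attained at one of them
    (for fixed slope the optimal intercept is the median residual).  For
    moderate n this enumeration is exact and much faster than iterative
    quantile-regression fitting; large problems fall back to statsmodels.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 2:
        return np.nan
    n = x.size
    if n > 200:
        exog = np.column_stack([np.ones_like(x), x])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(QuantReg(y, exog).fit(q=0.5).params[1])
    ii, jj = np.triu_indices(n, k=1)
    dx = x[ii] - x[jj]
    ok = dx != 0
    cand = np.unique((y[ii] - y[jj])[ok] / dx[ok])
    resid = y[None, :] - cand[:, None] * x[None, :]
    obj = np.abs(resid - np.median(resid, axis=1, keepdims=True)).sum(axis=1)
    return float(cand[int(np.argmin(obj))])  # ties -> smallest slope


def count_depth_slopes(counts: ArrayLike, gene_mask: Optional[np.ndarray] = None,
                       depths: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-gene count-depth-rate slopes (NaN outside the mask or if degenerate).

    For each retained gene, only its nonzero cells enter the fit of
    log(expression) against log(depth); depth is the full per-cell total.
    """
    v = _values(counts)
    if gene_mask is None:
        gene_mask = np.ones(v.shape[0], dtype=bool)
    if depths is None:
        depths = v.sum(axis=0).astype(float)
    log_depth = np.log(np.maximum(depths, 1.0))
    slopes = np.full(v.shape[0], np.nan)
    for g in np.nonzero(gene_mask)[0]:
        nz = v[g] > 0
        if nz.sum() < 2:
            continue
        slopes[g] = lad_slope(log_depth[nz], np.log(v[g, nz].astype(float)))
    return slopes


def group_genes_by_median(counts: ArrayLike, retained: np.ndarray,
                          k: int = 10) -> np.ndarray:
    """Assign retained genes to k contiguous, equally sized (+-1) groups.

    Ordering is by nonzero median expression, ties broken by gene index for
    determinism.  Returns a per-gene group index in 1..k (0 outside the mask).
    """
    v = _values(counts)
    idx = np.nonzero(retained)[0]
    if idx.size < k:
        raise ValueError(f"need at least {k} retained genes, have {idx.size}")
    med = _nonzero_median(v)[idx]
    order = idx[np.lexsort((idx, med))]
    group = np.zeros(v.shape[0], dtype=int)
    for gi, chunk in enumerate(np.array_split(order, k), start=1):
        group[chunk] = gi
    return group


def slope_mode(slopes: np.ndarray) -> float:
    """Mode of the slope density: Gaussian KDE (Silverman bandwidth) argmax
    over a 512-point grid on [-3, 3]; out-of-range slopes are clipped in.
    """
    s = np.asarray(slopes, dtype=float)
    s = s[np.isfinite(s)]
    if s.size == 0:
        raise ValueError("no finite slopes")
    if np.unique(s).size == 1:
        return float(s[0])
    s = np.clip(s, KDE_GRID[0], KDE_GRID[-1])
    kde = gaussian_kde(s, bw_method="silverman")
    density = kde(KDE_GRID)
    return float(KDE_GRID[int(np.argmax(density))])  # ties -> lower grid index


def mad_statistic(modes: np.ndarray) -> float:
    """Median over expression groups of |mode - 1| (1 = proportional scaling)."""
    modes = np.asarray(modes, dtype=float)
    if modes.size == 0:
        raise ValueError("need at least one slope mode")
    return float(np.median(np.abs(modes - 1.0)))


@dataclass
class CountDepthProfile:
    gene_ids: list
    slopes: np.ndarray     # per-gene slope, NaN where not estimated
    group: np.ndarray      # per-gene group 1..k, 0 where filtered out
    modes: np.ndarray      # per-group slope mode
    mad: float


def count_depth_profile(counts: ArrayLike, k: int = 10,
                        umi_mode: bool = False) -> CountDepthProfile:
    """Full count-depth-rate pipeline: filter, fit slopes, group, modes, MAD."""
    v = _values(counts)
    gene_ids = counts.gene_ids if isinstance(counts, CountMatrix) else \
        [f"gene_{g}" for g in range(v.shape[0])]
    mask = filter_genes_for_slopes(v, umi_mode=umi_mode)
    slopes = count_depth_slopes(v, mask)
    ok = mask & np.isfinite(slopes)
    group = group_genes_by_median(v, ok, k=k)
    modes = np.array([slope_mode(slopes[group == gi]) for gi in range(1, k + 1)])
    return CountDepthProfile(gene_ids=list(gene_ids), slopes=slopes, group=group,
                             modes=modes, mad=mad_statistic(modes))


# ---------------------------------------------------------------------------
# mean-variance decomposition / HVG
# ---------------------------------------------------------------------------

def variance_decomposition(log_counts: np.ndarray, span: float = 0.3,
                           fdr_threshold: float = 0.10):
    """Decompose per-gene variance into a mean-dependent technical trend and a
    biological residual.

    A lowess trend of variance on mean (fit on log-scale expression) stands
    for technical variability; the residual above it is biological.
    Significance is an F-ratio of total to trend variance with (n-1, n-1)
    degrees of freedom, Benjamini-Hochberg adjusted; genes at FDR below the
    threshold are flagged highly variable.

    Returns dict with 'mean', 'total', 'trend', 'residual', 'p', 'fdr', 'hvg'.
    """
    x = np.asarray(log_counts, dtype=float)
    if x.ndim != 2:
        raise ValueError("log_counts must be genes x cells")
    n_cells = x.shape[1]
    mean = x.mean(axis=1)
    total = x.var(axis=1, ddof=1)
    fitted = lowess(total, mean, frac=span, return_sorted=False)
    if np.all(~np.isfinite(fitted)):
        raise RuntimeError("trend fit failed")
    trend = np.clip(fitted, 1e-12, None)
    residual = total - trend
    f_ratio = total / trend
    p = stats.f.sf(f_ratio, n_cells - 1, n_cells - 1)
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return {"mean": mean, "total": total, "trend": trend, "residual": residual,
            "p": p, "fdr": fdr, "hvg": fdr < fdr_threshold}


def variability_rank_difference(residuals_a: np.ndarray,
                                residuals_b: np.ndarray) -> np.ndarray:
    """Difference of within-dataset variability ranks (ascending), A minus B."""
    a = np.asarray(residuals_a, dtype=float)
    b = np.asarray(residuals_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("residual vectors must share the gene universe")
    return rankdata(a) - rankdata(b)


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

@dataclass
class QCThresholds:
    min_log10_depth: Optional[float] = None
    max_top50_percent: Optional[float] = None
    n_sd: float = 2.0
    n_mad: float = 5.0


def _qc_metrics(values: np.ndarray):
    depths = values.sum(axis=0).astype(float)
    log_depth = np.log10(np.maximum(depths, 1.0))
    top50 = np.sort(values, axis=0)[::-1][:50].sum(axis=0)
    top50_pct = np.divide(top50, depths, out=np.zeros_like(depths), where=depths > 0) * 100
    return log_depth, top50_pct


def qc_filter_cells(counts: ArrayLike, thresholds: Optional[QCThresholds] = None,
                    method: str = "sd"):
    """Flag low-quality cells on log10 depth and percent counts in top-50 genes.

    method='sd' (default): remove cells with log10 depth below
    median - n_sd*SD, or top-50 percentage above median + n_sd*SD; fixed
    cutoffs in `thresholds` override the derived ones.  method='mad': remove
    cells more than n_mad scaled MADs (x1.4826) from the median on either
    metric.  Returns (keep_mask, report dict).
    """
    v = _values(counts)
    thresholds = thresholds or QCThresholds()
    log_depth, top50_pct = _qc_metrics(v)
    if method == "sd":
        if v.shape[1] < 3 and (thresholds.min_log10_depth is None or
                               thresholds.max_top50_percent is None):
            raise ValueError("need >= 3 cells for automatic thresholds")
        lo = thresholds.min_log10_depth
        if lo is None:
            lo = float(np.median(log_depth) - thresholds.n_sd * np.std(log_depth, ddof=1))
        hi = thresholds.max_top50_percent
        if hi is None:
            hi = float(np.median(top50_pct) + thresholds.n_sd * np.std(top50_pct, ddof=1))
        keep = (log_depth >= lo) & (top50_pct <= hi)
        report = {"min_log10_depth": lo, "max_top50_percent": hi}
    elif method == "mad":
        def outlier(metric):
            med = np.median(metric)
            mad = 1.4826 * np.median(np.abs(metric - med))
            if mad == 0:
                return metric != med   # any deviation is an outlier
            return np.abs(metric - med) > thresholds.n_mad * mad
        keep = ~(outlier(log_depth) | outlier(top50_pct))
        report = {"n_mad": thresholds.n_mad}
    else:
        raise ValueError(f"unknown QC method {method!r}")
    report.update({"n_removed": int(np.sum(~keep)), "log10_depth": log_depth,
                   "top50_percent": top50_pct})
    return keep, report


# ---------------------------------------------------------------------------
# evaluation helpers
# ---------------------------------------------------------------------------

def silhouette_summary(embedding: np.ndarray, labels: np.ndarray):
    """Per-cell silhouette widths (Euclidean) and their median."""
    embedding = np.asarray(embedding, dtype=float)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 distinct labels")
    if np.any(counts < 2):
        warnings.warn("singleton cluster present; its cells get silhouette 0")
    s = silhouette_samples(embedding, labels, metric="euclidean")
    return s, float(np.median(s))


def dynamic_gene_auc(expression: np.ndarray, pseudotime: np.ndarray,
                     truth: np.ndarray):
    """Quadratic-polynomial F-test per gene along pseudotime, plus AUC.

    For each gene, a degree-2 polynomial regression of expression on
    pseudotime is compared with the intercept-only model by F-test; p-values
    are Benjamini-Hochberg adjusted and the AUC of (1 - adjusted p) against
    the ground-truth dynamic labels is reported.

    Returns dict with 'p', 'fdr', 'auc'.
    """
    x = np.asarray(expression, dtype=float)
    t = np.asarray(pseudotime, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("AUC undefined: ground truth has a single class")
    n = t.size
    design = np.column_stack([np.ones(n), t, t * t])
    q, _ = np.linalg.qr(design)
    p_vals = np.ones(x.shape[0])
    df_num, df_den = 2, n - 3
    for g in range(x.shape[0]):
        y = x[g]
        if np.all(y == y[0]):
            continue  # constant gene: p = 1
        fit = q @ (q.T @ y)
        rss1 = float(np.sum((y - fit) ** 2))
        rss0 = float(np.sum((y - y.mean()) ** 2))
        if rss1 <= 0:
            p_vals[g] = 0.0
            continue
        f_stat = ((rss0 - rss1) / df_num) / (rss1 / df_den)
        p_vals[g] = stats.f.sf(f_stat, df_num, df_den)
    _, fdr, _, _ = multipletests(p_vals, method="fdr_bh")
    auc = float(roc_auc_score(truth, 1.0 - fdr))
    return {"p": p_vals, "fdr": fdr, "auc": auc}


def paired_change_summary(counts_a: ArrayLike, counts_b: ArrayLike):
    """Percent change, B relative to A, in mean gene variance and depth SD.

    Returns dict with 'gene_variance_pct_change' (change in the mean over
    genes of the per-gene count variance) and 'depth_sd_pct_change' (change
    in the SD of per-cell total counts).
    """
    va = getattr(counts_a, "counts", None)
    va = _values(counts_a) if va is None else np.asarray(va)
    vb = getattr(counts_b, "counts", None)
    vb = _values(counts_b) if vb is None else np.asarray(vb)
    if va.shape[0] != vb.shape[0]:
        raise ValueError("datasets must share the gene universe")

    def pct(stat_a, stat_b):
        if stat_a == 0:
            return np.nan
        return 100.0 * (stat_b - stat_a) / stat_a

    var_a = float(va.var(axis=1, ddof=1).mean())
    var_b = float(vb.var(axis=1, ddof=1).mean())
    sd_a = float(va.sum(axis=0).std(ddof=1))
    sd_b = float(vb.sum(axis=0).std(ddof=1))
    return {"gene_variance_pct_change": pct(var_a, var_b),
            "depth_sd_pct_change": pct(sd_a, sd_b)}
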