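"""Single-cell statistics: QC residual filter, normalization, resolution
selection, and the pct.delta differential-expression filter.

Cell quality control combines inclusive feature-count and read-count windows
with a covariation rule: because sequencing is a random sampling process,
the number of detected genes should be a smooth function of the number of
counts, so cells whose residual from a penalized-spline fit of features on
counts falls more than three SDs from the mean residual are removed.

For trajectory subclustering, the resolution of the clustering is chosen
with two marker-based criteria: the mean within-cluster SD of marker
expression over expressing cells (count variance) and the SD across clusters
of the percent of cells expressing the marker.  The chosen resolution is the
lowest at which the count variance reaches its plateau near the minimum.

Trajectory DE between two clusters uses a pluggable two-group test (rank-sum
by default; a hurdle-model test can be plugged in), Bonferroni correction,
and an effect filter: |log2FC| >= 0.3 OR pct.delta >= 0.4, where pct.delta
is the difference in percent of cells expressing scaled by the larger
percentage.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "qc_filter",
    "normalize_cells",
    "count_variance",
    "pct_expressing_variance",
    "select_resolution",
    "pct_delta",
    "trajectory_de",
    "kmeans_cluster",
]


def _spline_residuals(n_counts: np.ndarray, n_features: np.ndarray) -> np.ndarray:
    """Residuals of features ~ s(counts); linear fallback on degenerate data."""
    try:
        from statsmodels.gam.api import GLMGam, BSplines
        import statsmodels.api as sm

        x = n_counts.astype(float).reshape(-1, 1)
        df_spline = min(6, max(4, np.unique(x).size - 1))
        basis = BSplines(x, df=[df_spline], degree=[3])
        intercept = np.ones((x.shape[0], 1))
        model = GLMGam(
            n_features.astype(float), exog=intercept, smoother=basis,
            family=sm.families.Gaussian(),
        )
        fit = model.fit()
        return n_features - fit.predict(exog=intercept, exog_smooth=x)
    except Exception:
        warnings.warn("spline fit failed; falling back to a linear fit", RuntimeWarning)
        coeffs = np.polyfit(n_counts.astype(float), n_features.astype(float), 1)
        return n_features - np.polyval(coeffs, n_counts.astype(float))


def qc_filter(
    counts: pd.DataFrame,
    feat_range=(500, 3000),
    count_range=(1000, 30000),
    resid_sd: float = 3.0,
):
    """Retain high-quality cells (cells x genes counts).

    Both ranges are inclusive at both ends.  The residual rule keeps cells
    whose feature-on-count residual lies within ``resid_sd`` standard
    deviations of the mean residual of the range-passing cells.

    Returns (retained cell index, per-cell QC DataFrame).
    """
    if counts.shape[0] < 10:
        raise ValueError("at least 10 cells are required for QC")
    n_counts = counts.sum(axis=1).to_numpy(dtype=float)
    n_features = (counts > 0).sum(axis=1).to_numpy(dtype=float)
    in_range = (
        (n_features >= feat_range[0])
        & (n_features <= feat_range[1])
        & (n_counts >= count_range[0])
        & (n_counts <= count_range[1])
    )
    qc = pd.DataFrame(
        {"n_counts": n_counts, "n_features": n_features, "in_range": in_range},
        index=counts.index,
    )
    resid = np.full(len(counts), np.nan)
    keep = in_range.copy()
    if in_range.sum() >= 10:
        r = _spline_residuals(n_counts[in_range], n_features[in_range])
        resid[in_range] = r
        sd = r.std(ddof=1)
        if sd > 0:
            keep[in_range] = np.abs(r - r.mean()) <= resid_sd * sd
    qc["residual"] = resid
    qc["retained"] = keep
    return counts.index[keep], qc


def normalize_cells(counts: pd.DataFrame, scale: float = 10_000.0) -> pd.DataFrame:
    """Depth-normalized log expression: ln(1 + scale * count / cell total)."""
    totals = counts.sum(axis=1).to_numpy(dtype=float)
    if np.any(totals <= 0):
        raise ValueError("every cell must have positive total counts")
    return np.log1p(counts.div(totals, axis=0) * scale)


def count_variance(marker_expr, labels) -> float:
    """Mean within-cluster SD of marker expression over expressing cells.

    Cells with zero marker expression are excluded, so padding a cluster
    with non-expressing cells cannot change the value; clusters with fewer
    than two expressing cells are skipped.
    """
    marker_expr = np.asarray(marker_expr, dtype=float)
    labels = np.asarray(labels)
    sds = []
    for g in np.unique(labels):
        vals = marker_expr[(labels == g) & (marker_expr > 0)]
        if vals.size >= 2:
            sds.append(np.std(vals, ddof=1))
    return float(np.mean(sds)) if sds else float("nan")


def pct_expressing_variance(marker_expr, labels) -> float:
    """SD across clusters of the fraction of cells expressing the marker.

    A per-cluster percentage is a scalar, so the spread of these
    percentages is measured across clusters; single-cluster input has no
    spread and returns NaN.
    """
    marker_expr = np.asarray(marker_expr, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        return float("nan")
    pcts = [np.mean(marker_expr[labels == g] > 0) for g in uniq]
    return float(np.std(pcts, ddof=1))


def select_resolution(resolutions, labels_per_resolution, marker_expr, tol: float = 0.05):
    """Lowest resolution where the marker count variance plateaus at its minimum.

    For each resolution the count variance is computed; the chosen
    resolution is the lowest whose value lies within ``tol`` (relative) of
    the minimum over all resolutions and whose successor changes the value
    by less than ``tol`` (relative).  If no resolution satisfies the plateau
    rule the last one is returned with a warning.
    """
    resolutions = list(resolutions)
    if len(resolutions) < 3:
        raise ValueError("at least 3 resolutions are required")
    cvars = np.array(
        [count_variance(marker_expr, labels_per_resolution[r]) for r in resolutions]
    )
    if np.all(np.isnan(cvars)):
        raise ValueError("count variance undefined at every resolution")
    vmin = np.nanmin(cvars)
    for i, r in enumerate(resolutions[:-1]):
        c = cvars[i]
        if np.isnan(c) or c > vmin * (1.0 + tol) + 1e-12:
            continue
        nxt = cvars[i + 1]
        denom = c if c > 0 else 1.0
        if not np.isnan(nxt) and abs(nxt - c) <= tol * denom + 1e-12:
            return r, cvars
    warnings.warn("no plateau found; returning the last resolution", RuntimeWarning)
    return resolutions[-1], cvars


def pct_delta(pct_1: float, pct_2: float) -> float:
    """Scaled change in percent expressing: |pct2 - pct1| / max(pct1, pct2).

    Reported as a magnitude so the filter is symmetric in cluster labels;
    undefined (NaN) when neither cluster expresses the gene.
    """
    if pct_1 < 0 or pct_2 < 0:
        raise ValueError("percentages must be non-negative")
    m = max(pct_1, pct_2)
    if m == 0:
        return float("nan")
    return abs(pct_2 - pct_1) / m


def _ranksum_test(x: np.ndarray, y: np.ndarray) -> float:
    try:
        return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    except ValueError:  # all values identical
        return 1.0


def trajectory_de(
    expr_1: pd.DataFrame,
    expr_2: pd.DataFrame,
    test=None,
    alpha_bonferroni: float = 0.05,
    min_lfc: float = 0.3,
    min_pctdelta: float = 0.4,
) -> pd.DataFrame:
    """Two-cluster DE along the trajectory with the fold-change OR pct.delta filter.

    ``expr_1``/``expr_2`` are cells x genes log-normalized matrices for the
    two clusters.  ``test(x, y) -> p`` is pluggable (rank-sum by default; a
    MAST-style hurdle test satisfies the same contract).  Genes absent in
    both clusters are skipped; the Bonferroni denominator is the number of
    genes actually tested.
    """
    if len(expr_1) < 3 or len(expr_2) < 3:
        raise ValueError("both clusters need at least 3 cells")
    test = test or _ranksum_test
    genes = expr_1.columns.intersection(expr_2.columns)
    rows = []
    for gene in genes:
        x = expr_1[gene].to_numpy(dtype=float)
        y = expr_2[gene].to_numpy(dtype=float)
        pct1, pct2 = float(np.mean(x > 0)), float(np.mean(y > 0))
        if pct1 == 0 and pct2 == 0:
            continue
        # fold change on the de-logged scale, as for log-normalized data
        lfc = float(np.log2((np.mean(np.expm1(y)) + 1.0) / (np.mean(np.expm1(x)) + 1.0)))
        rows.append(
            {
                "gene": gene,
                "p": test(x, y),
                "log2fc": lfc,
                "pct_1": pct1,
                "pct_2": pct2,
                "pct_delta": pct_delta(pct1, pct2),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        table["p_adj"] = table.get("p", pd.Series(dtype=float))
        table["significant"] = pd.Series(dtype=bool)
        return table
    n_tested = len(table)
    table["p_adj"] = np.minimum(table["p"] * n_tested, 1.0)
    table["significant"] = (table["p_adj"] <= alpha_bonferroni) & (
        (table["log2fc"].abs() >= min_lfc) | (table["pct_delta"] >= min_pctdelta)
    )
    return table


def kmeans_cluster(matrix: pd.DataFrame, resolution: float, n_pcs: int = 10, seed: int = 0):
    """Built-in cluster-assignment default: principal components + k-means.

    Exists so resolution selection can run without external graph-clustering
    tooling; any callable mapping (matrix, resolution) -> labels satisfies
    the same contract.  k is tied to resolution as max(2, round(10 * r)).
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    X = matrix.to_numpy(dtype=float)
    n_pcs = min(n_pcs, min(X.shape) - 1)
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)
    k = max(2, int(round(10 * resolution)))
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(pcs)
    return pd.Series(km.labels_, index=matrix.index, name="cluster")
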