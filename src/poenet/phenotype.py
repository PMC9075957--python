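"""Phenotype association: residualized correlations, bootstrap CIs, validation ANOVA.

Metabolic phenotypes (basal glucose, glucose-tolerance AUC, serum
cholesterol, necropsy weight, ...) are log10-transformed when a Shapiro-Wilk
test rejects normality and the transform improves it, residualized on sex,
diet, and sex-by-diet so only the cross effect remains, and then correlated
with network-gene expression.  A gene-phenotype pair is carried forward when
|Pearson r| >= 0.5 and its Storey q-value is <= 0.05.  Cross-generation
validation uses percentile bootstrap CIs of r and one-way ANOVAs under three
genotype codings (cross, paternal allele identity, mitochondrial ancestry).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .stats import qvalue_pi0

__all__ = [
    "normalize_phenotype",
    "residualize",
    "correlate_genes",
    "bootstrap_correlation_ci",
    "validation_anova",
    "product_predictor",
    "CODINGS",
]

# ordered maternal|paternal genotype -> group code
CODINGS = {
    "cross": {"LL": 0, "LS": -1, "SL": 1, "SS": 0},
    "paternal_allele": {"LL": 0, "LS": 1, "SL": 0, "SS": 1},
    # F2 cohorts by maternal grandmother's cross, i.e. mitochondrial ancestry
    "mitochondrial": {"LxSxSxL": 0, "SxLxLxS": 1},
}


def normalize_phenotype(y, alpha_sw: float = 0.05):
    """Log10-transform a phenotype when Shapiro-Wilk says it helps.

    The transform is applied iff the raw values fail Shapiro-Wilk at
    ``alpha_sw`` AND the log10 values score a higher Shapiro-Wilk p than the
    raw values.  Non-positive values block the transform (flagged, returned
    untransformed); constant input is flagged untestable.

    Returns (values, status) with status in {"raw", "log10",
    "log_blocked", "untestable"}.
    """
    y = np.asarray(y, dtype=float)
    finite = y[~np.isnan(y)]
    if finite.size < 3 or np.ptp(finite) == 0:
        return y, "untestable"
    p_raw = stats.shapiro(finite).pvalue
    if p_raw >= alpha_sw:
        return y, "raw"
    if np.any(finite <= 0):
        return y, "log_blocked"
    p_log = stats.shapiro(np.log10(finite)).pvalue
    if p_log > p_raw:
        return np.log10(y), "log10"
    return y, "raw"


def _covariate_matrix(design: pd.DataFrame) -> np.ndarray:
    sex = (design["sex"].astype(str).to_numpy() == "M").astype(float)
    diet = (design["diet"].astype(str).to_numpy() == "HF").astype(float)
    return np.column_stack([np.ones(len(design)), sex, diet, sex * diet])


def residualize(y, design: pd.DataFrame) -> np.ndarray:
    """Residuals of y on sex + diet + sex:diet indicator covariates."""
    y = np.asarray(y, dtype=float)
    X = _covariate_matrix(design)
    keep = ~np.isnan(y)
    rank = np.linalg.matrix_rank(X[keep])
    if rank < X.shape[1]:
        names = ["intercept", "sex", "diet", "sex:diet"]
        # name the first aliased column
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[keep][:, : j + 1]) <= np.linalg.matrix_rank(X[keep][:, :j]):
                raise ValueError(f"rank-deficient design: term {names[j]!r} is aliased")
        raise ValueError("rank-deficient design")
    resid = np.full(y.shape, np.nan)
    beta, _, _, _ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
    resid[keep] = y[keep] - X[keep] @ beta
    return resid


def correlate_genes(
    expr: pd.DataFrame,
    residual_phenotypes: pd.DataFrame,
    r_min: float = 0.5,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of every gene with every residual phenotype.

    Complete-case pairing per (gene, phenotype); q-values pooled over all
    pairs; a pair is flagged when |r| >= ``r_min`` and q <= ``fdr_threshold``.
    """
    rows = []
    for pheno in residual_phenotypes.columns:
        y = residual_phenotypes[pheno].to_numpy(dtype=float)
        for gene in expr.index:
            x = expr.loc[gene].to_numpy(dtype=float)
            keep = ~(np.isnan(x) | np.isnan(y))
            if keep.sum() < 5 or np.ptp(x[keep]) == 0 or np.ptp(y[keep]) == 0:
                rows.append({"gene": gene, "phenotype": pheno, "r": np.nan, "p": np.nan})
                continue
            r, p = stats.pearsonr(x[keep], y[keep])
            rows.append({"gene": gene, "phenotype": pheno, "r": r, "p": p})
    table = pd.DataFrame(rows)
    ok = ~table["p"].isna()
    q = np.full(len(table), np.nan)
    if ok.any():
        _, q_ok = qvalue_pi0(table.loc[ok, "p"].to_numpy())
        q[ok.to_numpy()] = q_ok
    table["q"] = q
    table["significant"] = (
        (table["r"].abs() >= r_min) & (table["q"] <= fdr_threshold)
    ).fillna(False)
    return table


def bootstrap_correlation_ci(
    x,
    y,
    n_boot: int = 5000,
    m: int = 10,
    level: float = 0.90,
    seed: int = 0,
    max_redraws: int = 100_000,
):
    """Percentile bootstrap CI for Pearson r over resamples of size m.

    Each resample draws ``m`` individuals with replacement; degenerate
    resamples (zero variance in either variable) are redrawn and counted.
    Returns (lo, hi, n_redrawn).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 2:
        raise ValueError("at least 2 paired observations are required")
    rng = np.random.default_rng(seed)
    rs = np.empty(n_boot)
    n_redrawn = 0
    i = 0
    while i < n_boot:
        idx = rng.integers(0, x.size, size=m)
        xs, ys = x[idx], y[idx]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        xs = xs - xs.mean()
        ys = ys - ys.mean()
        rs[i] = (xs @ ys) / np.sqrt((xs @ xs) * (ys @ ys))
        i += 1
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(rs, [tail, 1.0 - tail])
    return float(lo), float(hi), n_redrawn


def validation_anova(expr, genotypes, coding: str):
    """One-way ANOVA of expression across coded genotype groups.

    ``coding`` selects the genotype -> group map: "cross" (LL 0, LS -1,
    SL 1, SS 0), "paternal_allele" (LL 0, LS 1, SL 0, SS 1), or
    "mitochondrial" (F2 cohort by maternal grandmother).  Alleles are
    ordered maternal | paternal.  Returns (p, status).
    """
    if coding not in CODINGS:
        raise ValueError(f"unknown coding {coding!r}")
    mapping = CODINGS[coding]
    codes = np.array([mapping[g] for g in genotypes])
    expr = np.asarray(expr, dtype=float)
    groups = [expr[codes == c] for c in np.unique(codes)]
    groups = [g[~np.isnan(g)] for g in groups if np.sum(~np.isnan(g)) > 0]
    if len(groups) < 2:
        return float("nan"), "untestable"
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        return 1.0, "degenerate"
    stat, p = stats.f_oneway(*groups)
    return float(p), "ok"


def product_predictor(expr_a, expr_b, phenotype):
    """Regression of a phenotype on the product of two genes' expression.

    Fits phenotype ~ a*b by least squares and returns (Wald p for the
    product term, R^2, status).  The product test is powered for
    interaction-only signals where neither gene is marginally predictive.
    """
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b) | np.isnan(y))
    if keep.sum() < 5:
        raise ValueError("at least 5 complete cases are required")
    prod = a[keep] * b[keep]
    y = y[keep]
    if np.ptp(prod) == 0:
        return float("nan"), float("nan"), "untestable"
    X = np.column_stack([np.ones(prod.size), prod])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = resid @ resid
    tss = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    dof = y.size - 2
    if rss <= 0 or dof <= 0:
        return 0.0, 1.0, "degenerate"
    sigma2 = rss / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    t = beta[1] / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return float(p), float(r2), "ok"
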