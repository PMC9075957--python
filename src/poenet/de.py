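"""Differential total expression between reciprocal crosses.

Counts are normalized by trimmed mean of M-values (TMM) scale factors, genes
are required to reach a minimum normalized count, and each gene is tested
under five negative-binomial log-linear models in which expression responds
to cross alone or to cross in interaction with sex and/or diet:

    1. Expression ~ Cross
    2. Expression ~ Cross:Sex
    3. Expression ~ Cross:Diet
    4. Expression ~ Cross:Sex:Diet
    5. Expression ~ Cross + Cross:Sex + Cross:Diet + Cross:Sex:Diet

Each model is a cell-means model over the factor partition it spans, fitted
with a library-size-and-factor offset and a single common NB dispersion
estimated by maximum (Cox-Reid) adjusted profile likelihood shared across
genes.  Significance comes from the likelihood-ratio test of the
cross-containing terms against the matched environmental null (the same
partition with the cross dimension removed), with (gene, model) pairs pooled
into one Storey q-value calculation.  A gene is called DE when its pooled
q-value is <= 0.1 and its largest-magnitude context fold change is >= 1.5.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .stats import qvalue_pi0

__all__ = [
    "tmm_factors",
    "filter_min_expression",
    "estimate_common_dispersion",
    "fit_cross_models",
    "de_scan",
    "qvalue_pi0",
]

# alternative partition -> null partition (cross dimension removed)
MODEL_SPECS = {
    "m1_cross": (("cross",), ()),
    "m2_cross_sex": (("cross", "sex"), ("sex",)),
    "m3_cross_diet": (("cross", "diet"), ("diet",)),
    "m4_cross_sex_diet": (("cross", "sex", "diet"), ("sex", "diet")),
    "m5_full": (("cross", "sex", "diet"), ("sex", "diet")),
}


def tmm_factors(counts: pd.DataFrame, logratio_trim: float = 0.30, abs_trim: float = 0.05):
    """Trimmed-mean-of-M-values scale factors (geometric mean 1).

    The reference library is the sample whose upper quartile of
    depth-scaled counts is closest to the mean upper quartile.  For each
    sample, genes positive in both sample and reference contribute a log2
    expression ratio M and average abundance A; the factor is the
    precision-weighted mean of M after rank-trimming the most extreme
    ``logratio_trim`` of M on each side and ``abs_trim`` of A on each side.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    X = counts.to_numpy(dtype=float)
    lib = X.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("every sample must have nonzero counts")
    f75 = np.array([np.quantile(X[:, j] / lib[j], 0.75) for j in range(X.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(X.shape[1])
    xr, nr = X[:, ref], lib[ref]
    for j in range(X.shape[1]):
        if j == ref:
            continue
        xo, no = X[:, j], lib[j]
        keep = (xo > 0) & (xr > 0)
        if keep.sum() == 0:
            continue
        o, r = xo[keep], xr[keep]
        m = np.log2((o / no) / (r / nr))
        a = 0.5 * np.log2((o / no) * (r / nr))
        # asymptotic variance of M; weights are its inverse
        v = (no - o) / (no * o) + (nr - r) / (nr * r)
        w = 1.0 / v
        finite = np.isfinite(m) & np.isfinite(a)
        m, a, w = m[finite], a[finite], w[finite]
        n = m.size
        lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
        lo_a, hi_a = np.floor(n * abs_trim) + 1, n - np.floor(n * abs_trim)
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        trimmed = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if trimmed.sum() == 0 or w[trimmed].sum() == 0:
            continue
        logf = np.sum(w[trimmed] * m[trimmed]) / np.sum(w[trimmed])
        if np.isfinite(logf) and abs(logf) > 1e-6:
            factors[j] = 2.0 ** logf
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def effective_offsets(counts: pd.DataFrame, factors: pd.Series) -> np.ndarray:
    """Effective library sizes (library size x TMM factor), mean-centered."""
    lib = counts.to_numpy(dtype=float).sum(axis=0)
    off = lib * factors.loc[counts.columns].to_numpy()
    return off / np.exp(np.mean(np.log(off)))


def normalized_counts(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Counts rescaled by effective library size, back on the count scale."""
    return counts / effective_offsets(counts, factors)


def filter_min_expression(
    counts: pd.DataFrame,
    factors: pd.Series,
    design: pd.DataFrame,
    min_normalized_count: float = 10.0,
):
    """Genes reaching the normalized-count floor in every sample of a context.

    The rule is applied within each (sex, diet) context; a gene is retained
    overall if it passes in at least one context (and enters testing only in
    contexts where it passes).  Returns (retained Series, per-context
    boolean DataFrame).
    """
    norm = normalized_counts(counts, factors)
    design = design.set_index("sample_id").loc[counts.columns]
    per_context = {}
    for (sex, diet), sub in design.groupby(["sex", "diet"]):
        cols = sub.index
        per_context[f"{sex}_{diet}"] = (norm[cols] >= min_normalized_count).all(axis=1)
    per_context = pd.DataFrame(per_context)
    return per_context.any(axis=1), per_context


def _nb_loglik(y, mu, alpha):
    if alpha <= 0:
        return np.sum(stats.poisson.logpmf(y, mu))
    r = 1.0 / alpha
    return np.sum(stats.nbinom.logpmf(y, r, r / (r + mu)))


def _fit_cell_means(Y: np.ndarray, offsets: np.ndarray, groups: np.ndarray, alpha: float):
    """Vectorized NB MLE of per-cell rates with offsets.

    Solves the 1-D score equation per (gene, cell) by Newton iterations in
    log mu; closed form at alpha = 0 (Poisson).  Returns the genes x samples
    fitted mean matrix and the per-gene log-likelihood.
    """
    n_genes, n_samples = Y.shape
    uniq, inv = np.unique(groups, return_inverse=True)
    mu_hat = np.empty((n_genes, n_samples))
    for g in range(uniq.size):
        cols = inv == g
        y, o = Y[:, cols], offsets[cols]
        start = y.sum(axis=1) / o.sum()
        if alpha <= 0:
            rate = start
        else:
            eta = np.log(np.maximum(start, 1e-8))
            for _ in range(50):
                m = np.exp(eta)[:, None] * o[None, :]
                resid = y.sum(axis=1) - np.sum((y + 1.0 / alpha) * (alpha * m) / (1.0 + alpha * m), axis=1)
                hess = -np.sum((y + 1.0 / alpha) * (alpha * m) / (1.0 + alpha * m) ** 2, axis=1)
                step = resid / np.where(np.abs(hess) < 1e-12, -1e-12, hess)
                step = np.clip(step, -3.0, 3.0)
                eta = eta - step
                if np.max(np.abs(step)) < 1e-10:
                    break
            rate = np.exp(eta)
        mu_hat[:, cols] = rate[:, None] * o[None, :]
    mu_hat = np.maximum(mu_hat, 1e-12)
    if alpha <= 0:
        ll = stats.poisson.logpmf(Y, mu_hat).sum(axis=1)
    else:
        r = 1.0 / alpha
        ll = stats.nbinom.logpmf(Y, r, r / (r + mu_hat)).sum(axis=1)
    return mu_hat, ll


def _cr_adjustment(mu_hat: np.ndarray, groups: np.ndarray, alpha: float) -> np.ndarray:
    """Cox-Reid adjustment -0.5 log det(X'WX) per gene for a cell-means fit."""
    w = mu_hat / (1.0 + alpha * mu_hat)
    uniq, inv = np.unique(groups, return_inverse=True)
    adj = np.zeros(mu_hat.shape[0])
    for g in range(uniq.size):
        adj -= 0.5 * np.log(np.maximum(w[:, inv == g].sum(axis=1), 1e-300))
    return adj


def estimate_common_dispersion(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    factors: pd.Series,
    partition=("cross", "sex", "diet"),
    max_genes: int = 500,
) -> float:
    """Common NB dispersion by maximum Cox-Reid adjusted profile likelihood.

    The full factorial partition is used as the fitted model; the shared
    dispersion maximizes the sum over genes of the profile log-likelihood
    plus the Cox-Reid adjustment.  Genes are capped at ``max_genes`` (taken
    evenly across the abundance range) for speed.
    """
    design = design.set_index("sample_id").loc[counts.columns]
    groups = design[list(partition)].astype(str).agg("|".join, axis=1).to_numpy()
    Y = counts.to_numpy(dtype=float)
    if Y.shape[0] > max_genes:
        order = np.argsort(Y.sum(axis=1))
        pick = order[np.linspace(0, Y.shape[0] - 1, max_genes).astype(int)]
        Y = Y[pick]
    offsets = effective_offsets(counts, factors)

    def neg_apl(log_alpha):
        alpha = float(np.exp(log_alpha))
        mu_hat, ll = _fit_cell_means(Y, offsets, groups, alpha)
        return -(ll + _cr_adjustment(mu_hat, groups, alpha)).sum()

    res = optimize.minimize_scalar(neg_apl, bounds=(-10.0, 3.0), method="bounded",
                                   options={"xatol": 1e-3})
    return float(np.exp(res.x))


def _context_log2fc(norm: pd.DataFrame, design: pd.DataFrame):
    """Per-(sex, diet) context log2 fold change SxL over LxS of normalized means."""
    out = {}
    for (sex, diet), sub in design.groupby(["sex", "diet"]):
        sxl = sub.index[sub["cross"] == "SxL"]
        lxs = sub.index[sub["cross"] == "LxS"]
        if len(sxl) == 0 or len(lxs) == 0:
            continue
        eps = 1e-8
        ratio = (norm[sxl].mean(axis=1) + eps) / (norm[lxs].mean(axis=1) + eps)
        out[f"{sex}_{diet}"] = np.log2(ratio)
    return pd.DataFrame(out)


def fit_cross_models(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    factors: pd.Series,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Likelihood-ratio p-values for the five cross models per gene.

    Each model's cross-containing terms are tested against the matched
    environmental null by LRT on chi-square with df = difference in cell
    counts.  Returns a genes x models DataFrame of p-values.
    """
    design_idx = design.set_index("sample_id").loc[counts.columns]
    if design_idx["cross"].nunique() < 2:
        raise ValueError("both crosses must be present")
    if dispersion is None:
        dispersion = estimate_common_dispersion(counts, design, factors)
    Y = counts.to_numpy(dtype=float)
    offsets = effective_offsets(counts, factors)

    ll_cache: dict = {}

    def loglik(partition):
        if partition not in ll_cache:
            if partition:
                groups = design_idx[list(partition)].astype(str).agg("|".join, axis=1).to_numpy()
            else:
                groups = np.zeros(len(design_idx), dtype=int)
            _, ll = _fit_cell_means(Y, offsets, groups, dispersion)
            k = np.unique(groups).size
            ll_cache[partition] = (ll, k)
        return ll_cache[partition]

    pvals = {}
    for name, (alt, null) in MODEL_SPECS.items():
        ll1, k1 = loglik(alt)
        ll0, k0 = loglik(null)
        lrt = np.maximum(2.0 * (ll1 - ll0), 0.0)
        pvals[name] = stats.chi2.sf(lrt, df=k1 - k0)
    return pd.DataFrame(pvals, index=counts.index)


def de_scan(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    min_normalized_count: float = 10.0,
    fdr_threshold: float = 0.1,
    min_fold_change: float = 1.5,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Full reciprocal-cross DE scan with pooled q-values and FC filter.

    (gene, model) p-values are pooled into a single Storey q-value
    calculation; a gene's q is the smallest q over its models, and the
    significance flag additionally requires the largest-magnitude context
    fold change to reach ``min_fold_change``.
    """
    factors = tmm_factors(counts)
    retained, _ = filter_min_expression(counts, factors, design, min_normalized_count)
    kept = counts.loc[retained[retained].index]
    if kept.empty:
        raise ValueError("no gene passes the minimum-expression filter")
    pmat = fit_cross_models(kept, design, factors, dispersion=dispersion)
    flat = pmat.to_numpy().ravel()
    ok = ~np.isnan(flat)
    pi0, q_flat = qvalue_pi0(np.clip(flat[ok], 0, 1))
    qmat = np.full(flat.shape, np.nan)
    qmat[ok] = q_flat
    qmat = pd.DataFrame(qmat.reshape(pmat.shape), index=pmat.index, columns=pmat.columns)

    norm = normalized_counts(kept, factors)
    design_idx = design.set_index("sample_id").loc[kept.columns]
    lfc = _context_log2fc(norm, design_idx)
    max_ctx = lfc.abs().idxmax(axis=1)
    max_lfc = lfc.to_numpy()[np.arange(len(lfc)), lfc.columns.get_indexer(max_ctx)]

    result = pmat.add_prefix("p_")
    result = result.join(qmat.add_prefix("q_"))
    result["q_value"] = qmat.min(axis=1)
    result["p_value"] = pmat.min(axis=1)
    result["log2fc_max"] = max_lfc
    result["max_fc_context"] = max_ctx
    result["pi0"] = pi0
    result["significant"] = (result["q_value"] <= fdr_threshold) & (
        np.abs(result["log2fc_max"]) >= np.log2(min_fold_change)
    )
    return result
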