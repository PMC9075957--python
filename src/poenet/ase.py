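"""Parent-of-origin-dependent allele-specific expression.

The allelic bias of a gene in a sample is L_bias = L / (L + S), the fraction
of its reads carrying the L haplotype.  In a reciprocal cross, an imprinted
gene shows L_bias near 1 in one cross and near 0 in the other, so
parent-of-origin dependence is tested as an ANOVA of L_bias on cross and its
interactions with sex and diet.  Because allelic bias is correlated within
imprinted domains, significance is controlled with a permutation-based
empirical FDR rather than an analytic correction, and effect size is
summarized as the POE score: mean L_bias(SxL) - mean L_bias(LxS), which runs
from -1 (fully maternal expression) through 0 (biallelic) to +1 (fully
paternal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simulate import AllelicCounts
from .stats import PermutationNull, empirical_fdr_flags, fdr_ratio, score_critical_value

__all__ = [
    "BetaBinomFit",
    "upper_quartile_normalize",
    "compute_lbias",
    "fit_beta_binomial",
    "select_ase_model",
    "test_poe_ase",
    "permute_context_null",
    "permute_score_null",
    "poe_score",
    "ase_scan",
    "fdr_ratio",
    "score_critical_value",
]

# Nested conditional ANOVA models, from a bare cross effect to the full
# cross-by-sex-by-diet interaction.  Each maps to the factor partition whose
# cell means the model spans; the omnibus F-test against the intercept is
# then a one-way ANOVA over that partition (every term contains cross, so
# the test is the parental-origin omnibus).
MODEL_PARTITIONS = {
    "cross": ("cross",),
    "cross_sex": ("cross", "sex"),
    "cross_diet": ("cross", "diet"),
    "full": ("cross", "sex", "diet"),
}

MODEL_FORMULAS = {
    "cross": "L_bias ~ Cross",
    "cross_sex": "L_bias ~ Cross + Cross:Sex",
    "cross_diet": "L_bias ~ Cross + Cross:Diet",
    "full": "L_bias ~ Cross + Cross:Sex + Cross:Diet + Cross:Sex:Diet",
    "untestable": "untestable",
}

RHO_COMPLEXITY_THRESHOLD = 0.05


@dataclass
class BetaBinomFit:
    """Maximum-likelihood beta-binomial shape parameters for a library.

    rho = 1 / (1 + alpha + beta) is the overdispersion of allelic bias; a
    library is called complex (not dominated by a few duplicated fragments)
    when rho < 0.05.
    """

    alpha: float
    beta: float
    boundary: bool = False

    @property
    def rho(self) -> float:
        return 1.0 / (1.0 + self.alpha + self.beta)

    @property
    def complex_library(self) -> bool:
        return self.rho < RHO_COMPLEXITY_THRESHOLD


def upper_quartile_normalize(counts: AllelicCounts, min_depth: float = 20.0):
    """Upper-quartile normalization of allelic totals with a depth mask.

    The per-sample scale is the 75th percentile of that sample's nonzero
    totals, rescaled so the scales have geometric mean 1.  A gene is
    retained only if its normalized total reaches ``min_depth`` in every
    sample, so each retained gene is informative in all analysis contexts.

    Returns (normalized totals DataFrame, boolean retained-gene Series).
    """
    totals = counts.totals.astype(float)
    scales = np.empty(totals.shape[1])
    for j, col in enumerate(totals.columns):
        nonzero = totals[col].to_numpy()
        nonzero = nonzero[nonzero > 0]
        if nonzero.size == 0:
            raise ValueError(f"sample {col!r} has no nonzero totals")
        scales[j] = np.percentile(nonzero, 75)
    scales = scales / np.exp(np.mean(np.log(scales)))
    normalized = totals / scales
    retained = (normalized >= min_depth).all(axis=1)
    return normalized, retained


def compute_lbias(counts: AllelicCounts) -> pd.DataFrame:
    """L_bias = L / (L + S), NaN where a gene has no reads in a sample."""
    totals = counts.totals.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        lbias = counts.L / totals.where(totals > 0)
    return lbias


def fit_beta_binomial(L, T) -> BetaBinomFit:
    """ML fit of a beta-binomial to allelic counts across genes.

    Maximizes the beta-binomial likelihood over (log alpha, log beta) with a
    method-of-moments start.  Degenerate data (all reads on one allele)
    cannot identify both shapes; the fit is returned at the boundary with
    ``boundary=True`` rather than failing.
    """
    L = np.asarray(L, dtype=float)
    T = np.asarray(T, dtype=float)
    keep = T > 0
    L, T = L[keep], T[keep]
    if L.size < 10:
        raise ValueError("at least 10 informative observations are required")
    if np.all(L == 0) or np.all(L == T):
        return BetaBinomFit(alpha=1e-6, beta=1e-6, boundary=True)

    ratio = L / T
    m, v = ratio.mean(), max(ratio.var(), 1e-8)
    # moment start: v ~ m(1-m) * (rho + (1-rho) E[1/T])
    inv_t = np.mean(1.0 / T)
    rho0 = np.clip((v / (m * (1 - m) + 1e-12) - inv_t) / (1 - inv_t), 1e-4, 0.99)
    a0 = m * (1 - rho0) / rho0
    b0 = (1 - m) * (1 - rho0) / rho0

    def nll(theta):
        a, b = np.exp(theta)
        return -np.sum(stats.betabinom.logpmf(L, T, a, b))

    res = optimize.minimize(nll, np.log([a0, b0]), method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    a, b = np.exp(res.x)
    return BetaBinomFit(alpha=float(a), beta=float(b))


def _cell_counts(design: pd.DataFrame, factors) -> np.ndarray:
    labels = design[list(factors)].astype(str).agg("|".join, axis=1)
    return labels.value_counts().to_numpy()


def select_ase_model(design: pd.DataFrame) -> str:
    """Pick the most complex testable conditional model for a gene.

    The cascade requires every conditioning cell to hold at least two
    informative samples: with >= 2 per cross the bare cross model is
    testable; >= 2 per cross:sex (resp. cross:diet) cell upgrades to the
    corresponding interaction model; >= 2 in all eight cross:sex:diet cells
    allows the full model.  Later conditions take priority, so a design
    satisfying both cross:sex and cross:diet (but not the full model) is
    tested under cross + cross:diet.  Returns "untestable" when either cross
    has fewer than two samples.
    """
    if design.empty:
        return "untestable"
    crosses = design["cross"].value_counts()
    if len(crosses) < 2 or crosses.min() < 2 or set(crosses.index) != {"LxS", "SxL"}:
        return "untestable"
    model = "cross"
    counts_cs = _cell_counts(design, ("cross", "sex"))
    if counts_cs.size == 4 and counts_cs.min() >= 2:
        model = "cross_sex"
    counts_cd = _cell_counts(design, ("cross", "diet"))
    if counts_cd.size == 4 and counts_cd.min() >= 2:
        model = "cross_diet"
    counts_full = _cell_counts(design, ("cross", "sex", "diet"))
    if counts_full.size == 8 and counts_full.min() >= 2:
        model = "full"
    return model


def _anova_f(y: np.ndarray, groups: np.ndarray):
    """One-way ANOVA F and p of group means vs a common mean."""
    n = y.size
    k = len(np.unique(groups))
    if k < 2 or n - k < 1:
        return np.nan, np.nan, True
    grand = y.mean()
    rss0 = np.sum((y - grand) ** 2)
    rss1 = 0.0
    for g in np.unique(groups):
        sub = y[groups == g]
        rss1 += np.sum((sub - sub.mean()) ** 2)
    if rss1 <= 1e-300:
        # zero residual variance: boundary p, flagged
        return np.inf, 0.0 if rss0 > rss1 else 1.0, True
    f = ((rss0 - rss1) / (k - 1)) / (rss1 / (n - k))
    return f, float(stats.f.sf(f, k - 1, n - k)), False


def test_poe_ase(lbias, design: pd.DataFrame, model: str):
    """Omnibus F-test of the selected conditional model against the intercept.

    All model terms contain cross, so this jointly tests parental-origin
    dependence of allelic bias.  Returns (p_value, boundary_flag).
    """
    if model == "untestable":
        raise ValueError("model is untestable for this design")
    y = np.asarray(lbias, dtype=float)
    keep = ~np.isnan(y)
    y = y[keep]
    sub = design.loc[keep] if keep.size == len(design) else design
    groups = sub[list(MODEL_PARTITIONS[model])].astype(str).agg("|".join, axis=1).to_numpy()
    _, p, flag = _anova_f(y, groups)
    return p, flag


def _scan_pvalues(lbias_df: pd.DataFrame, design: pd.DataFrame):
    """Per-gene model selection + omnibus test, dropping NaNs casewise."""
    pvals = np.full(lbias_df.shape[0], np.nan)
    models = []
    design = design.set_index("sample_id").loc[list(lbias_df.columns)].reset_index()
    values = lbias_df.to_numpy()
    # fast path: genes informative in every sample share the design
    complete = ~np.isnan(values).any(axis=1)
    shared_model = select_ase_model(design)
    if complete.any() and shared_model != "untestable":
        groups = design[list(MODEL_PARTITIONS[shared_model])].astype(str).agg(
            "|".join, axis=1
        ).to_numpy()
        pvals[complete] = _grouped_anova_p(values[complete], groups)
    for i in range(values.shape[0]):
        if complete[i]:
            models.append(shared_model if shared_model != "untestable" else "untestable")
            continue
        keep = ~np.isnan(values[i])
        sub = design.loc[keep]
        model = select_ase_model(sub)
        models.append(model)
        if model == "untestable":
            continue
        grp = sub[list(MODEL_PARTITIONS[model])].astype(str).agg("|".join, axis=1).to_numpy()
        _, p, _ = _anova_f(values[i][keep], grp)
        pvals[i] = p
    if shared_model == "untestable":
        models = ["untestable" if complete[i] else models[i] for i in range(len(models))]
    return pvals, models


def _grouped_anova_p(Y: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Vectorized one-way ANOVA over the rows of Y for a shared grouping."""
    n = Y.shape[1]
    uniq, inv = np.unique(groups, return_inverse=True)
    k = uniq.size
    grand = Y.mean(axis=1, keepdims=True)
    rss0 = np.sum((Y - grand) ** 2, axis=1)
    group_sums = np.zeros((Y.shape[0], k))
    group_ns = np.bincount(inv, minlength=k)
    for g in range(k):
        group_sums[:, g] = Y[:, inv == g].sum(axis=1)
    group_means = group_sums / group_ns
    between = np.sum(group_ns * (group_means - grand) ** 2, axis=1)
    rss1 = np.maximum(rss0 - between, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (between / (k - 1)) / (rss1 / (n - k))
    p = stats.f.sf(f, k - 1, n - k)
    p = np.where(rss1 <= 1e-300, np.where(between > 0, 0.0, 1.0), p)
    return p


def permute_context_null(
    lbias_df: pd.DataFrame,
    design: pd.DataFrame,
    n_iterations: int = 10,
    seed: int = 0,
) -> PermutationNull:
    """Null p-values from per-gene independent shuffles of context labels.

    Each iteration permutes the (cross, sex, diet) label tuple independently
    for every gene — equivalently, permutes that gene's L_bias values over
    samples — then reruns model selection and the omnibus test.  Pooled
    p-values across iterations form the empirical null.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    values = lbias_df.to_numpy()
    pooled, counts, crits = [], [], []
    for _ in range(n_iterations):
        order = np.argsort(rng.random(values.shape), axis=1)
        perm = np.take_along_axis(values, order, axis=1)
        p, _ = _scan_pvalues(pd.DataFrame(perm, index=lbias_df.index, columns=lbias_df.columns), design)
        p = p[~np.isnan(p)]
        pooled.append(p)
        counts.append(p.size)
        crits.append(float(np.quantile(p, 0.05)) if p.size else np.nan)
    return PermutationNull(
        statistic="p_value",
        values=np.concatenate(pooled) if pooled else np.array([]),
        iteration_counts=counts,
        critical_values=crits,
    )


def permute_score_null(
    lbias_df: pd.DataFrame,
    design: pd.DataFrame,
    n_iterations: int = 10,
    seed: int = 0,
) -> PermutationNull:
    """Null POE scores from per-gene independent shuffles of cross labels."""
    rng = np.random.default_rng(seed)
    design = design.set_index("sample_id").loc[list(lbias_df.columns)].reset_index()
    is_sxl = (design["cross"] == "SxL").to_numpy()
    values = lbias_df.to_numpy()
    pooled, counts, crits = [], [], []
    for _ in range(n_iterations):
        # permuting the row values against the fixed cross mask is the same
        # permutation test as shuffling the labels per gene
        order = np.argsort(rng.random(values.shape), axis=1)
        perm = np.take_along_axis(values, order, axis=1)
        with np.errstate(invalid="ignore"):
            scores = np.nanmean(perm[:, is_sxl], axis=1) - np.nanmean(perm[:, ~is_sxl], axis=1)
        scores = scores[~np.isnan(scores)]
        pooled.append(scores)
        counts.append(scores.size)
        crits.append(float(np.quantile(np.abs(scores), 0.95)) if scores.size else np.nan)
    return PermutationNull(
        statistic="poe_score",
        values=np.concatenate(pooled) if pooled else np.array([]),
        iteration_counts=counts,
        critical_values=crits,
    )


def poe_score(lbias_df: pd.DataFrame, design: pd.DataFrame, by_context: bool = False):
    """POE score per gene: mean L_bias of SxL samples minus LxS samples.

    +1 is complete paternal expression of the L allele's partner cross, -1
    complete maternal expression, 0 biallelic.  With ``by_context=True`` the
    score is computed within each (sex, diet) context, exposing bipolar
    cases where opposite context scores cancel in the pooled value.
    """
    design = design.set_index("sample_id").loc[list(lbias_df.columns)].reset_index()
    sxl = design.loc[design["cross"] == "SxL", "sample_id"]
    lxs = design.loc[design["cross"] == "LxS", "sample_id"]
    if sxl.empty or lxs.empty:
        return pd.Series(np.nan, index=lbias_df.index, name="poe_score")
    if not by_context:
        score = lbias_df[sxl].mean(axis=1, skipna=True) - lbias_df[lxs].mean(axis=1, skipna=True)
        return score.rename("poe_score")
    out = {}
    for (sex, diet), sub in design.groupby(["sex", "diet"]):
        s = sub.loc[sub["cross"] == "SxL", "sample_id"]
        l = sub.loc[sub["cross"] == "LxS", "sample_id"]
        if s.empty or l.empty:
            out[f"{sex}_{diet}"] = pd.Series(np.nan, index=lbias_df.index)
        else:
            out[f"{sex}_{diet}"] = lbias_df[s].mean(axis=1) - lbias_df[l].mean(axis=1)
    return pd.DataFrame(out)


def ase_scan(
    counts: AllelicCounts,
    min_depth: float = 20.0,
    n_iterations: int = 10,
    fdr_threshold: float = 0.1,
    alpha_score: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Full parent-of-origin ASE scan.

    Normalizes totals (upper quartile, minimum normalized depth), computes
    L_bias, selects and tests the conditional ANOVA per gene, estimates
    empirical FDR against a per-gene context-permutation null, and requires
    both FDR <= ``fdr_threshold`` and a POE score beyond the two-sided
    alpha = ``alpha_score`` critical values of the permuted score null.
    """
    _, retained = upper_quartile_normalize(counts, min_depth=min_depth)
    lbias = compute_lbias(counts).loc[retained[retained].index]
    design = counts.design
    pvals, models = _scan_pvalues(lbias, design)
    null = permute_context_null(lbias, design, n_iterations=n_iterations, seed=seed)
    fdrs, flags = empirical_fdr_flags(pvals, null, fdr_threshold=fdr_threshold)
    scores = poe_score(lbias, design)
    score_null = permute_score_null(lbias, design, n_iterations=n_iterations, seed=seed + 1)
    lo, hi = score_critical_value(score_null, alpha=alpha_score)
    beyond = (scores.to_numpy() <= lo) | (scores.to_numpy() >= hi)
    result = pd.DataFrame(
        {
            "model_formula": [MODEL_FORMULAS[m] for m in models],
            "p_value": pvals,
            "fdr": fdrs,
            "poe_score": scores.to_numpy(),
            "score_lo": lo,
            "score_hi": hi,
            "significant": flags & beyond,
        },
        index=lbias.index,
    )
    return result
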