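"""Imprinting-by-imprinting epistasis in an advanced intercross.

Each genotyped marker gets an imprinting score from the animal's ordered
maternal|paternal genotype (LL = 0, LS = +1, SL = -1, SS = 0): homozygotes
carry no parental-origin contrast, and the heterozygote sign records which
parent transmitted the L allele.  Candidate locus pairs are drawn from
markers within 1.5 Mb of the geometric center of the ASE and DE genes.
After a covariate screen removes sex, diet, and their interaction from each
phenotype, epistasis is tested with

    R_pheno ~ BDE_imp + ASE_imp + BDE_imp : ASE_imp

and called when the interaction term passes a permutation-based empirical
FDR of 0.1.  Permutations shuffle whole animals (rows of the score matrix),
preserving the linkage among proximal markers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .phenotype import normalize_phenotype, residualize
from .stats import PermutationNull, empirical_fdr_flags

__all__ = [
    "IMPRINTING_CODES",
    "imprinting_score",
    "score_matrix",
    "select_markers",
    "covariate_screen",
    "test_epistasis",
    "epistasis_permutation_fdr",
]

IMPRINTING_CODES = {"LL": 0, "LS": 1, "SL": -1, "SS": 0}


def imprinting_score(ordered_genotype: str) -> int:
    """Imprinting score of an ordered maternal|paternal genotype."""
    try:
        return IMPRINTING_CODES[ordered_genotype]
    except KeyError:
        raise ValueError(
            f"unknown ordered genotype {ordered_genotype!r}; expected LL/LS/SL/SS"
        ) from None


def score_matrix(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Apply the imprinting-score coding to an animal x marker genotype table."""
    values = genotypes.to_numpy()
    out = np.zeros(values.shape, dtype=int)
    for g, code in IMPRINTING_CODES.items():
        out[values == g] = code
    bad = ~np.isin(values, list(IMPRINTING_CODES))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"unknown ordered genotype {values[i, j]!r}")
    return pd.DataFrame(out, index=genotypes.index, columns=genotypes.columns)


def select_markers(gene, markers: pd.DataFrame, window: float = 1.5e6) -> list:
    """Markers within ``window`` of a gene's geometric center.

    ``gene`` is (chrom, tx_start, tx_stop); the center is the midpoint of
    the transcript, and only same-chromosome markers qualify.
    """
    chrom, tx_start, tx_stop = gene
    if tx_start > tx_stop:
        raise ValueError("tx_start must not exceed tx_stop")
    center = (tx_start + tx_stop) / 2.0
    same = markers["chrom"].astype(str) == str(chrom)
    near = (markers["pos"] - center).abs() <= window
    return markers.index[same & near].tolist()


def covariate_screen(phenotype, design: pd.DataFrame, alpha_sw: float = 0.05) -> np.ndarray:
    """Shapiro-Wilk-gated log10 transform, then residualize on sex/diet/sex:diet."""
    y, _ = normalize_phenotype(phenotype, alpha_sw=alpha_sw)
    return residualize(y, design)


def test_epistasis(r_pheno, score_a, score_b, min_cases: int = 30):
    """Partial test of the interaction in R_pheno ~ B + A + B:A.

    ``score_a`` is the ASE-locus imprinting score, ``score_b`` the DE-locus
    score.  Returns a dict with the OLS coefficients, the Wald p of the
    product term, and a status flag; a constant score vector (e.g. no
    heterozygotes at a locus) or a constant product makes the pair
    untestable.
    """
    y = np.asarray(r_pheno, dtype=float)
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(a) | np.isnan(b))
    y, a, b = y[keep], a[keep], b[keep]
    if y.size < min_cases:
        raise ValueError(f"at least {min_cases} complete cases are required")
    prod = a * b
    if np.ptp(a) == 0 or np.ptp(b) == 0 or np.ptp(prod) == 0:
        return {"p_interaction": np.nan, "status": "untestable"}
    X = np.column_stack([np.ones(y.size), b, a, prod])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return {"p_interaction": np.nan, "status": "untestable"}
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = resid @ resid
    dof = y.size - X.shape[1]
    if rss <= 0 or dof <= 0:
        return {
            "beta_de": beta[1], "beta_ase": beta[2], "beta_interaction": beta[3],
            "p_interaction": 0.0, "status": "degenerate",
        }
    sigma2 = rss / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[3, 3])
    t = beta[3] / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return {
        "beta_de": float(beta[1]),
        "beta_ase": float(beta[2]),
        "beta_interaction": float(beta[3]),
        "p_interaction": float(p),
        "status": "ok",
    }


def _test_pairs(pairs, scores: pd.DataFrame, r_pheno: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for ase_locus, de_locus, pheno in pairs:
        res = test_epistasis(
            r_pheno[pheno].to_numpy(),
            scores[ase_locus].to_numpy(),
            scores[de_locus].to_numpy(),
        )
        rows.append({"ase_locus": ase_locus, "de_locus": de_locus, "phenotype": pheno, **res})
    return pd.DataFrame(rows)


def epistasis_permutation_fdr(
    pairs,
    scores: pd.DataFrame,
    r_pheno: pd.DataFrame,
    n_iterations: int = 10,
    fdr_threshold: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, PermutationNull]:
    """Test all candidate pairs and control FDR with a whole-animal permutation.

    Each iteration permutes the animal rows of the score matrix — keeping
    every animal's markers together, so within-animal linkage and each
    marker's marginal score distribution are preserved exactly — and retests
    every pair.  Per-pair empirical FDR uses the ratio of null to real
    positive rates at that pair's p-value.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    scores = scores.loc[r_pheno.index]
    real = _test_pairs(pairs, scores, r_pheno)
    rng = np.random.default_rng(seed)
    pooled, counts, crits = [], [], []
    for _ in range(n_iterations):
        perm = rng.permutation(len(scores))
        perm_scores = pd.DataFrame(
            scores.to_numpy()[perm], index=scores.index, columns=scores.columns
        )
        null_res = _test_pairs(pairs, perm_scores, r_pheno)
        ps = null_res["p_interaction"].dropna().to_numpy()
        pooled.append(ps)
        counts.append(ps.size)
        crits.append(float(np.quantile(ps, 0.05)) if ps.size else np.nan)
    null = PermutationNull(
        statistic="p_interaction",
        values=np.concatenate(pooled) if pooled else np.array([]),
        iteration_counts=counts,
        critical_values=crits,
    )
    fdrs, flags = empirical_fdr_flags(
        real["p_interaction"].to_numpy(), null, fdr_threshold=fdr_threshold
    )
    real["fdr"] = fdrs
    real["significant"] = flags
    return real, null
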