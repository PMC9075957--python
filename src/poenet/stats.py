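"""Shared statistical machinery: permutation nulls, empirical FDR, Storey q-values.

The pipeline controls error rates almost everywhere with permutation-based
empirical FDR rather than analytic corrections, because allelic bias and
expression are correlated within and between imprinted domains, which breaks
the independence assumptions of standard procedures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import UnivariateSpline

__all__ = [
    "PermutationNull",
    "fdr_ratio",
    "empirical_fdr_flags",
    "qvalue_pi0",
    "score_critical_value",
]


@dataclass
class PermutationNull:
    """Pooled null statistics from genome-wide permutation.

    Attributes
    ----------
    statistic : str
        Name of the pooled statistic (e.g. ``"p_value"`` or ``"poe_score"``).
    values : np.ndarray
        All null statistics pooled across iterations.
    iteration_counts : list of int
        Number of tests contributed by each iteration; the pooled size is
        exactly the sum of these.
    critical_values : list of float
        Per-iteration critical value of the statistic at ``alpha``
        (lower-tail quantile, the convention for p-values).
    alpha : float
        Level at which the per-iteration critical values were taken.
    """

    statistic: str
    values: np.ndarray
    iteration_counts: list = field(default_factory=list)
    critical_values: list = field(default_factory=list)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.iteration_counts and int(np.sum(self.iteration_counts)) != self.values.size:
            raise ValueError(
                "pooled null size must equal the sum of per-iteration test counts"
            )

    @property
    def n_iterations(self) -> int:
        return len(self.iteration_counts)

    @property
    def pooled_size(self) -> int:
        """Exact bookkeeping: pooled count = sum of per-iteration test counts."""
        return int(np.sum(self.iteration_counts)) if self.iteration_counts else self.values.size

    @property
    def stability(self) -> float:
        """SD of the critical values over the last five iterations (>= 0)."""
        if len(self.critical_values) < 2:
            return float("nan")
        tail = np.asarray(self.critical_values[-5:], dtype=float)
        return float(np.std(tail, ddof=0))

    @staticmethod
    def schedule_size(n_iterations: int, tests_per_iteration) -> int:
        """Planned pooled size for a permutation schedule.

        ``tests_per_iteration`` may be a scalar (same count every iteration)
        or a sequence of per-iteration counts.
        """
        counts = np.broadcast_to(
            np.asarray(tests_per_iteration, dtype=int), (int(n_iterations),)
        ) if np.ndim(tests_per_iteration) == 0 else np.asarray(tests_per_iteration, dtype=int)
        if counts.size != int(n_iterations):
            raise ValueError("per-iteration counts must match n_iterations")
        return int(counts.sum())


def fdr_ratio(real_p, null, threshold: float) -> float:
    """Empirical FDR at a threshold: null positive rate over real positive rate.

    FDR(t) = [(#null <= t) / N_null] / [(#real <= t) / N_real], clamped to
    [0, 1].  A value of 1 means every test called at ``t`` is expected to be
    a false positive.  Returns NaN (flagged undefined) when no real test
    reaches the threshold.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    null_values = null.values if isinstance(null, PermutationNull) else np.asarray(null, float)
    null_values = null_values[~np.isnan(null_values)]
    if null_values.size == 0:
        raise ValueError("empty permutation null")
    real_p = np.asarray(real_p, dtype=float)
    real_p = real_p[~np.isnan(real_p)]
    n_real_hits = int(np.sum(real_p <= threshold))
    if n_real_hits == 0:
        return float("nan")
    null_rate = np.sum(null_values <= threshold) / null_values.size
    real_rate = n_real_hits / real_p.size
    return float(min(1.0, null_rate / real_rate))


def empirical_fdr_flags(real_p, null, fdr_threshold: float = 0.1):
    """Per-test empirical FDR (at t = each test's own p) and significance flags.

    Ties at the threshold count as significant (<=, not <).  Undefined FDRs
    (no real test at the threshold cannot occur here, since the test itself
    reaches its own p) never arise; NaN p-values yield NaN FDR and False.
    """
    real_p = np.asarray(real_p, dtype=float)
    null_values = null.values if isinstance(null, PermutationNull) else np.asarray(null, float)
    null_values = np.sort(null_values[~np.isnan(null_values)])
    if null_values.size == 0:
        raise ValueError("empty permutation null")
    finite = ~np.isnan(real_p)
    real_sorted = np.sort(real_p[finite])
    n_real = real_sorted.size
    fdrs = np.full(real_p.shape, np.nan)
    if n_real:
        null_hits = np.searchsorted(null_values, real_p[finite], side="right")
        real_hits = np.searchsorted(real_sorted, real_p[finite], side="right")
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (null_hits / null_values.size) / (real_hits / n_real)
        fdrs[finite] = np.minimum(1.0, ratio)
    flags = np.where(np.isnan(fdrs), False, fdrs <= fdr_threshold)
    return fdrs, flags.astype(bool)


def qvalue_pi0(p, lambdas=None):
    """Storey q-values with smoother-based pi0 estimation.

    pi0 is estimated on the grid lambda = 0.05, 0.10, ..., 0.95 as
    #{p > lambda} / (n (1 - lambda)), a cubic smoothing spline is fit to the
    grid, and the spline's value at the largest lambda is taken, clamped to
    (0, 1].  q(i) = min_{j >= i} pi0 * n * p(j) / j on the sorted p-values,
    which makes q monotone non-decreasing in p by construction.

    Returns ``(pi0, qvalues)`` with q-values in the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    lambdas = np.asarray(lambdas, dtype=float)
    pi0_grid = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
    if np.allclose(pi0_grid, pi0_grid[0]):
        pi0 = pi0_grid[-1]
    else:
        spline = UnivariateSpline(lambdas, pi0_grid, k=3)
        pi0 = float(spline(lambdas[-1]))
    pi0 = float(min(max(pi0, 1.0 / n), 1.0))

    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * n * ranked / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return pi0, q


def score_critical_value(null_scores, alpha: float = 0.01):
    """Two-sided critical values: the (alpha/2, 1 - alpha/2) null quantiles."""
    null_scores = np.asarray(
        null_scores.values if isinstance(null_scores, PermutationNull) else null_scores,
        dtype=float,
    )
    null_scores = null_scores[~np.isnan(null_scores)]
    if null_scores.size == 0:
        raise ValueError("empty score null")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    lo, hi = np.quantile(null_scores, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)
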