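"""Independent brute-force oracles used by the test suite.

These restate definitions gene-by-gene in plain loops, deliberately sharing
no code with the package implementations they check.
"""

import numpy as np
import pandas as pd
from scipy import stats


def brute_force_tmm_pair(counts: pd.DataFrame, sample: int, ref: int,
                         logratio_trim: float = 0.30, abs_trim: float = 0.05) -> float:
    """Trimmed weighted mean of gene-wise log ratios for one sample vs the reference."""
    lib = counts.sum(axis=0).to_numpy(float)
    m_list, a_list, v_list = [], [], []
    for g in range(counts.shape[0]):
        o, r = counts.iat[g, sample], counts.iat[g, ref]
        if o <= 0 or r <= 0:
            continue
        m_list.append(np.log2((o / lib[sample]) / (r / lib[ref])))
        a_list.append(0.5 * np.log2((o / lib[sample]) * (r / lib[ref])))
        v_list.append((lib[sample] - o) / (lib[sample] * o) + (lib[ref] - r) / (lib[ref] * r))
    m = np.array(m_list)
    a = np.array(a_list)
    v = np.array(v_list)
    n = m.size
    rank_m, rank_a = stats.rankdata(m), stats.rankdata(a)
    keep = (
        (rank_m >= np.floor(n * logratio_trim) + 1)
        & (rank_m <= n - np.floor(n * logratio_trim))
        & (rank_a >= np.floor(n * abs_trim) + 1)
        & (rank_a <= n - np.floor(n * abs_trim))
    )
    return 2.0 ** (np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep]))


def brute_force_tmm_factors(counts: pd.DataFrame) -> np.ndarray:
    """Full factor vector: reference selection, pairwise factors, geometric-mean rescale."""
    lib = counts.sum(axis=0).to_numpy(float)
    f75 = np.array(
        [np.quantile(counts.iloc[:, j] / lib[j], 0.75) for j in range(counts.shape[1])]
    )
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    raw = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j != ref:
            raw[j] = brute_force_tmm_pair(counts, j, ref)
    return raw / np.exp(np.mean(np.log(raw)))
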