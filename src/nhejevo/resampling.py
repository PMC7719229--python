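"""Permutation and resampling procedures.

Mantel test between patristic distance matrices (tree incongruence screen),
the gene-pool genome-size randomization null, and the Wilcoxon rank-sum
wrapper used throughout the comparative analyses.  All permutation p-values
use the (1 + exceedances) / (1 + permutations) estimator and are reproducible
given a seed.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["mantel_test", "GSRandomizationResult", "gs_randomization",
           "wilcoxon_compare"]


def _lower_triangle(m: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


def mantel_test(D1: pd.DataFrame, D2: pd.DataFrame, n_perm: int = 10000,
                seed: int | None = None, exact: bool | None = None):
    """One-tailed Mantel test between two distance matrices.

    r is the Pearson correlation of the lower-triangle entries over the
    shared label set; the null jointly permutes rows and columns of the
    second matrix.  With ``exact`` (the default whenever n! <= n_perm) all
    permutations are enumerated and p = #{r_perm >= r_obs} / n!; otherwise
    p = (1 + exceedances) / (1 + n_perm) over random permutations.

    Returns (r, p, n_shared).
    """
    shared = [lb for lb in D1.index if lb in set(D2.index)]
    if len(shared) < len(D1.index) or len(shared) < len(D2.index):
        logger.info("mantel_test: %d shared labels (of %d and %d)",
                    len(shared), len(D1.index), len(D2.index))
    n = len(shared)
    if n < 4:
        raise ValueError("Mantel test needs at least 4 shared labels")
    A = D1.loc[shared, shared].to_numpy(dtype=float)
    B = D2.loc[shared, shared].to_numpy(dtype=float)
    for M, name in ((A, "D1"), (B, "D2")):
        if not np.allclose(M, M.T):
            raise ValueError(f"{name} is not symmetric")
    a = _lower_triangle(A)

    def corr_with(perm):
        return float(np.corrcoef(a, _lower_triangle(B[np.ix_(perm, perm)]))[0, 1])

    r_obs = corr_with(np.arange(n))
    if exact is None:
        exact = math.factorial(n) <= n_perm
    if exact:
        total = 0
        exceed = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if corr_with(np.array(perm)) >= r_obs - 1e-12:
                exceed += 1
        p = exceed / total
    else:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            if corr_with(rng.permutation(n)) >= r_obs - 1e-12:
                exceed += 1
        p = (1 + exceed) / (1 + n_perm)
    return r_obs, float(p), n


@dataclass
class GSRandomizationResult:
    medians: np.ndarray
    n_pick: int
    n_iter: int
    statistic: float | None = None
    p_value: float | None = None


def gs_randomization(cds_counts, n_pick: int, n_iter: int = 100,
                     seed: int | None = None,
                     observed=None) -> GSRandomizationResult:
    """Gene-pool genome-size randomization null.

    Genes are drawn uniformly from the pooled gene set of all genomes, so a
    genome is sampled with probability proportional to its gene count; each
    draw records the source genome's gene count and each iteration keeps the
    median.  When ``observed`` (the genome sizes of the focal group, same
    units) is given, the null medians are compared against it with a
    two-sided Wilcoxon rank-sum test.
    """
    counts = pd.Series(cds_counts, dtype=float)
    if n_pick < 1:
        raise ValueError("n_pick must be >= 1")
    total = counts.sum()
    if len(counts) == 0 or total <= 0:
        raise ValueError("empty gene pool")
    probs = (counts / total).to_numpy()
    sizes = counts.to_numpy()
    rng = np.random.default_rng(seed)
    medians = np.empty(n_iter)
    for it in range(n_iter):
        picked = rng.choice(len(sizes), size=n_pick, p=probs)
        medians[it] = np.median(sizes[picked])
    stat = p = None
    if observed is not None:
        stat, p = wilcoxon_compare(medians, np.asarray(observed, dtype=float))
    return GSRandomizationResult(medians=medians, n_pick=n_pick, n_iter=n_iter,
                                 statistic=stat, p_value=p)


def wilcoxon_compare(a, b):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact distribution when the smaller sample has <= 10 observations and the
    pooled data are tie-free, otherwise the normal approximation with tie and
    continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 10 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
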