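"""Phylogenetic signal statistics and the simulation-based phylogenetic ANOVA.

All three operations share the Brownian-motion covariance implied by the
tree: C[i, j] is the root-to-LCA depth of tips i and j.  Pagel's lambda
rescales the off-diagonal of C; Blomberg's K compares the observed variance
ratio with its Brownian expectation; the phylogenetic ANOVA replaces the
F-distribution null with Brownian simulations on the tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from .trees import Phylogeny

__all__ = [
    "pagel_lambda",
    "blomberg_k",
    "phylo_anova",
    "PhyloAnovaResult",
]


def _aligned(tree: Phylogeny, x) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(x, dict):
        x = pd.Series(x)
    C = tree.shared_depth_matrix()
    vals = x.loc[C.index].to_numpy(dtype=float)
    return C.to_numpy(), vals


def _gls_profile_loglik(C: np.ndarray, x: np.ndarray) -> float:
    """BM log-likelihood with mean and rate profiled out analytically."""
    n = len(x)
    try:
        chol = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    one = np.ones(n)
    Ci_x = np.linalg.solve(C, x)
    Ci_1 = np.linalg.solve(C, one)
    mu = (one @ Ci_x) / (one @ Ci_1)
    r = x - mu
    q = r @ np.linalg.solve(C, r)
    if q <= 0:
        return -np.inf
    sigma2 = q / n
    return float(-0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n))


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    Cl = lam * C
    np.fill_diagonal(Cl, np.diag(C))
    return Cl


def pagel_lambda(tree: Phylogeny, x, lambda_max: float | None = None):
    """ML estimate of Pagel's lambda with a likelihood-ratio test against 0.

    Returns (lambda_hat, loglik, p).  Lambda scales the shared (off-diagonal)
    part of the Brownian covariance; 0 means no signal, 1 plain Brownian
    motion.  A flat likelihood (e.g. a star tree, where lambda is
    unidentifiable) triggers a warning.
    """
    C, vals = _aligned(tree, x)
    if np.allclose(vals, vals[0]):
        raise ValueError("constant trait: phylogenetic signal undefined")
    if lambda_max is None:
        diag = np.diag(C)
        off = C - np.diag(diag)
        m = off.max()
        lambda_max = float(min(diag.min() / m, 1.5)) if m > 0 else 1.0

    def negll(lam):
        return -_gls_profile_loglik(_lambda_cov(C, lam), vals)

    res = minimize_scalar(negll, bounds=(0.0, lambda_max), method="bounded",
                          options={"xatol": 1e-8})
    ll_hat = -res.fun
    ll0 = _gls_profile_loglik(_lambda_cov(C, 0.0), vals)
    if abs(ll_hat - ll0) < 1e-8 and abs(-negll(lambda_max) - ll0) < 1e-8:
        warnings.warn("likelihood is flat in lambda (no internal structure?); "
                      "lambda is unidentifiable", RuntimeWarning)
    lr = max(2.0 * (ll_hat - ll0), 0.0)
    p = float(stats.chi2.sf(lr, df=1))
    return float(res.x), float(ll_hat), p


def blomberg_k(tree: Phylogeny, x, n_perm: int = 1000, seed: int | None = None):
    """Blomberg's K with a tip-permutation significance test.

    K is the observed MSE0/MSE ratio divided by its Brownian expectation on
    the tree; the p-value permutes trait values across tips and counts
    variance ratios at least as large as observed, with the
    (1 + exceedances) / (1 + permutations) estimator.
    """
    C, vals = _aligned(tree, x)
    if np.allclose(vals, vals[0]):
        raise ValueError("constant trait: phylogenetic signal undefined")
    n = len(vals)
    Cinv = np.linalg.inv(C)
    one = np.ones(n)
    denom_expected = (np.trace(C) - n / (one @ Cinv @ one)) / (n - 1)

    def ratio(v: np.ndarray) -> float:
        a0 = (one @ Cinv @ v) / (one @ Cinv @ one)
        r = v - a0
        mse0 = (r @ r) / (n - 1)
        mse = (r @ Cinv @ r) / (n - 1)
        return mse0 / mse

    obs = ratio(vals)
    K = float(obs / denom_expected)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if ratio(rng.permutation(vals)) >= obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return K, float(p)


@dataclass
class PhyloAnovaResult:
    f_statistic: float
    p_phylo: float
    n_sim: int
    pairwise: pd.DataFrame  # group_a, group_b, t, p_raw, p_holm
    sigma2: float


def _anova_f(values: np.ndarray, design: np.ndarray, n_per_group: np.ndarray):
    """One-way ANOVA F; ``values`` may be (n,) or (n, n_sim)."""
    single = values.ndim == 1
    V = values[:, None] if single else values
    n, _ = V.shape
    g = design.shape[1]
    group_means = (design.T @ V) / n_per_group[:, None]
    grand = V.mean(axis=0)
    ssb = (n_per_group[:, None] * (group_means - grand) ** 2).sum(axis=0)
    fitted = design @ group_means
    ssw = ((V - fitted) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (g - 1)) / (ssw / (n - g))  # inf for zero within-group variance
    return F[0] if single else F


def phylo_anova(tree: Phylogeny, x, groups, n_sim: int = 1000,
                seed: int | None = None) -> PhyloAnovaResult:
    """Phylogenetic ANOVA: Brownian-simulation null for the ANOVA F statistic.

    The observed F comes from an ordinary one-way ANOVA; the null distribution
    simulates the trait under Brownian motion on the tree (rate = ML estimate
    from the data) ``n_sim`` times.  Pairwise post-hoc t statistics are tested
    against their own simulated nulls and Holm-Bonferroni corrected.
    """
    C, vals = _aligned(tree, x)
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    labels = tree.shared_depth_matrix().index
    grp = groups.loc[labels].to_numpy()
    uniq = np.unique(grp)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    counts = np.array([(grp == u).sum() for u in uniq])
    if counts.min() < 2:
        small = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise ValueError(f"groups with fewer than two members: {', '.join(small)}")
    design = (grp[:, None] == uniq[None, :]).astype(float)
    n = len(vals)
    g = len(uniq)

    F_obs = _anova_f(vals, design, counts)

    # Brownian rate from the data, then a simulated null for F
    one = np.ones(n)
    Cinv = np.linalg.inv(C)
    mu = (one @ Cinv @ vals) / (one @ Cinv @ one)
    r = vals - mu
    sigma2 = float(r @ Cinv @ r / n)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(C + 1e-12 * np.eye(n))
    sims = chol @ rng.standard_normal((n, n_sim)) * np.sqrt(sigma2)
    F_sim = _anova_f(sims, design, counts)
    p = (1 + int((F_sim >= F_obs).sum())) / (1 + n_sim)

    # pairwise t statistics vs their simulated nulls
    def pairwise_t(V):
        single = V.ndim == 1
        M = V[:, None] if single else V
        means = (design.T @ M) / counts[:, None]
        fitted = design @ means
        mse = ((M - fitted) ** 2).sum(axis=0) / (n - g)
        out = {}
        with np.errstate(divide="ignore", invalid="ignore"):
            for i in range(g):
                for j in range(i + 1, g):
                    se = np.sqrt(mse * (1.0 / counts[i] + 1.0 / counts[j]))
                    out[(i, j)] = (means[i] - means[j]) / se
        return {k: (v[0] if single else v) for k, v in out.items()}

    t_obs = pairwise_t(vals)
    t_sim = pairwise_t(sims)
    rows = []
    for (i, j), t in t_obs.items():
        exceed = int((np.abs(t_sim[(i, j)]) >= abs(t)).sum())
        rows.append({"group_a": uniq[i], "group_b": uniq[j], "t": float(t),
                     "p_raw": (1 + exceed) / (1 + n_sim)})
    pair = pd.DataFrame(rows)
    if len(pair):
        pair["p_holm"] = multipletests(pair["p_raw"], method="holm")[1]
    return PhyloAnovaResult(f_statistic=float(F_obs), p_phylo=float(p),
                            n_sim=n_sim, pairwise=pair, sigma2=sigma2)
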