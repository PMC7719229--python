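"""Phylogenetic logistic regression for a binary trait on a tree.

Model: y_i ~ Bernoulli(logit^{-1}(x_i' beta)) with phylogenetically
correlated responses.  The working correlation between two tips is that of a
stationary two-state Markov switching process run along the tree and
conditioned on the root, with switching intensity alpha:

    R_ij = (exp(-a d_ij) - exp(-a (t_i + t_j)))
           / sqrt((1 - exp(-2 a t_i)) (1 - exp(-2 a t_j)))

where d_ij is the patristic distance and t_i the root-to-tip depth.  Tips
that share no history (a star tree) are exactly uncorrelated for every
alpha, so the estimator reduces to ordinary logistic regression there.
Larger alpha means faster switching and hence less phylogenetic signal.

Coefficients solve the generalized estimating equations given alpha; alpha
maximizes a Gaussian working likelihood of the standardized residuals.  For
model comparison the reported log-likelihood is the independence
quasi-likelihood (the Bernoulli log-likelihood at the GEE estimates, the
quantity behind QIC-type criteria for estimating equations), and
AIC = -2*loglik + 2*(p + 1), counting alpha.  On a star tree both the
estimates and the AIC coincide with ordinary logistic regression (up to the
constant +2 for alpha, shared by all models being compared).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import Phylogeny

__all__ = ["vif", "PerfectSeparationError", "PhyloGLMResult",
           "phylo_logistic_regression", "phyloglm_model_choice"]


class PerfectSeparationError(RuntimeError):
    pass


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors, VIF_j = 1 / (1 - R^2_j).

    R^2_j regresses predictor j on the remaining predictors (with intercept).
    Zero-variance predictors raise; perfect collinearity yields inf.
    """
    X = pd.DataFrame(X)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two predictors")
    var = X.var(ddof=0)
    dead = var[var <= 0].index.tolist()
    if dead:
        raise ValueError(f"zero-variance predictors: {', '.join(map(str, dead))}")
    out = {}
    for col in X.columns:
        y = X[col].to_numpy(dtype=float)
        others = X.drop(columns=[col]).to_numpy(dtype=float)
        A = np.column_stack([np.ones(len(y)), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def _markov_correlation(dist: np.ndarray, depth: np.ndarray, alpha: float) -> np.ndarray:
    ti = depth[:, None]
    tj = depth[None, :]
    num = np.exp(-alpha * dist) - np.exp(-alpha * (ti + tj))
    den = np.sqrt(np.clip((1.0 - np.exp(-2.0 * alpha * ti))
                          * (1.0 - np.exp(-2.0 * alpha * tj)), 1e-300, None))
    R = num / den
    np.fill_diagonal(R, 1.0)
    return R


class _NoConvergence(RuntimeError):
    pass


def _gee_score(X, y, beta, Rinv_chol):
    eta = np.clip(X @ beta, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    A = np.clip(mu * (1.0 - mu), 1e-12, None)
    sqrtA = np.sqrt(A)
    # U = X' A^{1/2} R^{-1} A^{-1/2} (y - mu); H = X' A^{1/2} R^{-1} A^{1/2} X
    Za = sqrtA[:, None] * X
    U = Za.T @ Rinv_chol((y - mu) / sqrtA)
    H = Za.T @ Rinv_chol(Za)
    return U, H


def _gee_beta(X: np.ndarray, y: np.ndarray, Rinv_chol, max_iter=60, tol=1e-10,
              separation_check=False):
    """Solve the GEE score equations for logistic beta given a fixed R.

    Damped Fisher scoring: steps are halved until the score norm decreases.
    """
    n, p = X.shape
    beta = np.zeros(p)
    U, H = _gee_score(X, y, beta, Rinv_chol)
    for it in range(max_iter):
        norm0 = np.linalg.norm(U)
        if norm0 < tol * n:
            break
        try:
            step = np.linalg.solve(H, U)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, U, rcond=None)[0]
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            Uc, Hc = _gee_score(X, y, cand, Rinv_chol)
            if np.linalg.norm(Uc) < norm0:
                beta, U, H = cand, Uc, Hc
                break
            scale *= 0.5
        else:
            raise _NoConvergence("GEE scoring stalled")
        if separation_check and np.max(np.abs(X @ beta)) > 30 \
                and np.max(np.abs(step)) > 1.0:
            raise PerfectSeparationError(
                "linear predictor diverged (|eta| > 30): the data are likely "
                "perfectly separated by the predictors")
    else:
        raise _NoConvergence("GEE scoring did not converge")
    return beta


@dataclass
class PhyloGLMResult:
    coefficients: pd.Series
    alpha: float
    penloglik: float
    aic: float
    vif: pd.Series | None
    n: int
    converged: bool


def phylo_logistic_regression(tree: Phylogeny, y, X,
                              alpha_bounds: tuple | None = None,
                              check_collinearity: bool = True) -> PhyloGLMResult:
    """Fit the phylogenetic logistic regression described in the module docs.

    ``y`` is a binary series indexed by tip label, ``X`` a predictor frame on
    the same index (an intercept is added).  Returns coefficient estimates,
    the switching intensity alpha (higher = less signal), a penalized
    log-likelihood and its AIC.
    """
    X = pd.DataFrame(X)
    if isinstance(y, dict):
        y = pd.Series(y)
    labels = [lb for lb in tree.tip_labels]
    yv = y.loc[labels].to_numpy(dtype=float)
    Xv = X.loc[labels]
    if set(np.unique(yv)) - {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    if check_collinearity and Xv.shape[1] >= 2:
        v = vif(Xv)
        if np.isinf(v).any():
            bad = v.index[np.isinf(v)].tolist()
            raise ValueError(f"perfectly collinear predictors (VIF=inf): {bad}")
    else:
        v = None
    design = np.column_stack([np.ones(len(yv)), Xv.to_numpy(dtype=float)])
    names = ["intercept"] + list(Xv.columns)

    dist = tree.patristic_matrix().loc[labels, labels].to_numpy()
    all_depths = tree.depths()
    depth = np.array([all_depths[t] for t in tree.tip_indices()])
    height = max(depth.max(), 1e-9)
    if alpha_bounds is None:
        alpha_bounds = (0.01 / height, 50.0 / height)

    def chol_solver(R):
        jitter = 1e-10
        while True:
            try:
                c = np.linalg.cholesky(R + jitter * np.eye(R.shape[0]))
                break
            except np.linalg.LinAlgError:
                jitter *= 10
                if jitter > 1e-2:
                    raise
        logdet = 2.0 * np.log(np.diag(c)).sum()

        def solve(b):
            return np.linalg.solve(c.T, np.linalg.solve(c, b))

        return solve, logdet

    # perfect-separation screen at the independence limit (R = I)
    _gee_beta(design, yv, lambda b: b, separation_check=True)

    def profile(alpha):
        R = _markov_correlation(dist, depth, alpha)
        solve, logdet = chol_solver(R)
        beta = _gee_beta(design, yv, solve)
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        bern = float(yv @ np.log(np.clip(mu, 1e-12, 1)) +
                     (1 - yv) @ np.log(np.clip(1 - mu, 1e-12, 1)))
        A = np.clip(mu * (1 - mu), 1e-12, None)
        e = (yv - mu) / np.sqrt(A)
        quad = float(e @ solve(e))
        # Gaussian working likelihood in the residuals: used only to pick alpha
        gauss = -0.5 * logdet - 0.5 * (quad - float(e @ e))
        return gauss, bern, beta

    # profile alpha on a log grid, then refine around the best point
    lo, hi = np.log(alpha_bounds[0]), np.log(alpha_bounds[1])
    grid = np.exp(np.linspace(lo, hi, 25))
    vals = []
    for a in grid:
        try:
            vals.append(profile(a)[0])
        except _NoConvergence:
            vals.append(-np.inf)
    if not np.any(np.isfinite(vals)):
        raise _NoConvergence("GEE scoring failed at every alpha on the grid")
    best_i = int(np.argmax(vals))
    a_lo = grid[max(best_i - 1, 0)]
    a_hi = grid[min(best_i + 1, len(grid) - 1)]
    from scipy.optimize import minimize_scalar

    def neg(la):
        try:
            return -profile(np.exp(la))[0]
        except _NoConvergence:
            return np.inf  # alpha values where scoring fails are never selected

    res = minimize_scalar(neg, bounds=(np.log(a_lo), np.log(a_hi)),
                          method="bounded", options={"xatol": 1e-6})
    alpha = float(np.exp(res.x))
    if neg(res.x) > -vals[best_i]:
        alpha = float(grid[best_i])
    _, pll, beta = profile(alpha)
    p = design.shape[1]
    aic = -2.0 * pll + 2.0 * (p + 1)
    return PhyloGLMResult(
        coefficients=pd.Series(beta, index=names),
        alpha=alpha,
        penloglik=float(pll),
        aic=float(aic),
        vif=v,
        n=len(yv),
        converged=True,
    )


def phyloglm_model_choice(tree: Phylogeny, y, X: pd.DataFrame,
                          models: list[list[str]]) -> pd.DataFrame:
    """Fit several predictor subsets and rank them by AIC."""
    rows = []
    for cols in models:
        fit = phylo_logistic_regression(tree, y, X[cols],
                                        check_collinearity=len(cols) >= 2)
        rows.append({"model": " + ".join(cols), "aic": fit.aic,
                     "penloglik": fit.penloglik, "alpha": fit.alpha,
                     **{f"coef_{c}": fit.coefficients[c] for c in cols}})
    return pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
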