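"""Continuous-time Markov (Mk) machinery for discrete characters on trees.

Implements the pruning likelihood, maximum-likelihood fitting of ER/SYM/ARD
(or arbitrary constrained) rate matrices, AIC weights, and a Metropolis
sampler for the posterior of the rate matrix.  The rate structure is encoded
as a k x k integer matrix mapping each off-diagonal cell to a free-parameter
index (-1 on the diagonal, -2 for transitions fixed to rate zero), which also
expresses the correlated-evolution (Pagel) model structures downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .trees import Phylogeny

__all__ = [
    "rate_index_matrix",
    "build_generator",
    "n_free_rates",
    "transition_matrices",
    "MkData",
    "MkFit",
    "mk_loglik",
    "fit_mk",
    "aic_weights",
    "QPosterior",
    "sample_q_posterior",
    "marginal_node_posteriors",
]

RATE_MIN = 1e-8
RATE_MAX = 1e3

# ----------------------------------------------------------------- structures


def rate_index_matrix(k: int, structure: str) -> np.ndarray:
    """Map off-diagonal cells of a k-state generator to free-parameter indices.

    ER shares one rate, SYM shares rates across (i,j)/(j,i) pairs, ARD gives
    every ordered pair its own rate.  -1 marks the diagonal.
    """
    idx = np.full((k, k), -1, dtype=np.int64)
    if structure == "ER":
        for i in range(k):
            for j in range(k):
                if i != j:
                    idx[i, j] = 0
    elif structure == "SYM":
        c = 0
        for i in range(k):
            for j in range(i + 1, k):
                idx[i, j] = c
                idx[j, i] = c
                c += 1
    elif structure == "ARD":
        c = 0
        for i in range(k):
            for j in range(k):
                if i != j:
                    idx[i, j] = c
                    c += 1
    else:
        raise ValueError(f"unknown rate structure {structure!r}")
    return idx


def n_free_rates(rate_index: np.ndarray) -> int:
    m = rate_index[rate_index >= 0]
    return int(m.max()) + 1 if m.size else 0


def build_generator(rate_index: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """Assemble the generator Q from the structure map and free rates."""
    k = rate_index.shape[0]
    Q = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            r = rate_index[i, j]
            if r >= 0:
                Q[i, j] = rates[r]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _check_generator(Q: np.ndarray) -> None:
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("Q must be square")
    off = Q.copy()
    np.fill_diagonal(off, 0.0)
    if np.any(off < -1e-12):
        raise ValueError("Q has negative off-diagonal rates")
    if np.any(np.abs(Q.sum(axis=1)) > 1e-9 * max(1.0, np.abs(Q).max())):
        raise ValueError("Q rows must sum to zero")


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    k = Q.shape[0]
    A = np.vstack([Q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


# -------------------------------------------------------- transition matrices


def transition_matrices(Q: np.ndarray, t: np.ndarray) -> np.ndarray:
    """exp(Q * t_e) for a vector of branch lengths, shape (m, k, k).

    Uses the eigendecomposition when Q is well conditioned, falling back to
    scaling-and-squaring per unique length otherwise.  Small negative entries
    from round-off are clipped at zero.
    """
    t = np.asarray(t, dtype=float)
    k = Q.shape[0]
    P = None
    try:
        w, U = np.linalg.eig(Q)
        Uinv = np.linalg.inv(U)
        # cheap condition estimate; eig is unreliable for defective Q
        if np.abs(U).max() * np.abs(Uinv).max() * k < 1e8:
            E = np.exp(t[:, None] * w[None, :])  # (m, k)
            P = (U[None, :, :] * E[:, None, :]) @ Uinv
            if np.iscomplexobj(P):
                P = P.real
            P = np.ascontiguousarray(P)
    except np.linalg.LinAlgError:
        P = None
    if P is None or not np.all(np.isfinite(P)):
        P = np.empty((t.shape[0], k, k))
        cache: dict[float, np.ndarray] = {}
        for i, ti in enumerate(t):
            if ti not in cache:
                cache[ti] = expm(Q * ti)
            P[i] = cache[ti]
    np.clip(P, 0.0, None, out=P)
    return P


# ------------------------------------------------------------- pruning kernel


def _prune_python(post_internal, child1, child2, P, L, logscale):
    for idx in range(post_internal.shape[0]):
        node = post_internal[idx]
        c1 = child1[idx]
        c2 = child2[idx]
        v = (P[c1] @ L[c1]) * (P[c2] @ L[c2])
        m = v.max()
        if m <= 0.0 or not np.isfinite(m):
            return -1
        L[node] = v / m
        logscale[node] = np.log(m) + logscale[c1] + logscale[c2]
    return 0


try:  # numba speeds the per-node loop up by ~2 orders of magnitude
    from numba import njit

    @njit(cache=False)
    def _prune_numba(post_internal, child1, child2, P, L, logscale):  # pragma: no cover
        n_int = post_internal.shape[0]
        k = L.shape[1]
        for idx in range(n_int):
            node = post_internal[idx]
            c1 = child1[idx]
            c2 = child2[idx]
            m = 0.0
            for i in range(k):
                s1 = 0.0
                s2 = 0.0
                for j in range(k):
                    s1 += P[c1, i, j] * L[c1, j]
                    s2 += P[c2, i, j] * L[c2, j]
                v = s1 * s2
                L[node, i] = v
                if v > m:
                    m = v
            if m <= 0.0:
                return -1
            for i in range(k):
                L[node, i] /= m
            logscale[node] = np.log(m) + logscale[c1] + logscale[c2]
        return 0

    _prune = _prune_numba
except Exception:  # pragma: no cover
    _prune = _prune_python


def _as_state_series(tip_states, tip_labels) -> pd.Series:
    if isinstance(tip_states, dict):
        tip_states = pd.Series(tip_states)
    if not isinstance(tip_states, pd.Series):
        raise TypeError("tip_states must be a mapping or pandas Series")
    missing = [t for t in tip_labels if t not in tip_states.index]
    if missing:
        raise ValueError(f"tips without an assigned state: {', '.join(missing[:5])}")
    return tip_states.loc[tip_labels].astype(int)


class MkData:
    """Tree + tip data prepared for repeated likelihood evaluation."""

    def __init__(self, tree: Phylogeny, tip_states, k: int):
        if not tree.is_bifurcating():
            raise ValueError("Mk likelihood requires a strictly bifurcating tree "
                             "(resolve polytomies first)")
        self.tree = tree
        self.k = int(k)
        tips = tree.tip_indices()
        states = _as_state_series(tip_states, [tree.labels[t] for t in tips])
        if states.min() < 0 or states.max() >= k:
            raise ValueError("tip state codes must lie in [0, k)")
        n = tree.n_nodes
        self.blen = np.maximum(tree.blen.astype(float), 1e-12)
        self.blen[tree.root] = 0.0
        post = [int(x) for x in tree.postorder() if not tree.is_tip(int(x))]
        self.post_internal = np.array(post, dtype=np.int64)
        self.child1 = np.array([tree.children(nd)[0] for nd in post], dtype=np.int64)
        self.child2 = np.array([tree.children(nd)[1] for nd in post], dtype=np.int64)
        self.tipL = np.zeros((n, self.k))
        for t, s in zip(tips, states.to_numpy()):
            self.tipL[t, s] = 1.0
        self.tip_state_array = states.to_numpy()
        self.tip_node_ids = np.array(tips, dtype=np.int64)

    # -- core computations -------------------------------------------------

    def downpass(self, Q: np.ndarray):
        """Conditional likelihoods; returns (L, logscale, P) or None on underflow."""
        P = transition_matrices(Q, self.blen)
        L = self.tipL.copy()
        logscale = np.zeros(self.tree.n_nodes)
        status = _prune(self.post_internal, self.child1, self.child2, P, L, logscale)
        if status != 0:
            return None
        return L, logscale, P

    def root_prior_vector(self, root_prior, Q: np.ndarray, L_root: np.ndarray) -> np.ndarray:
        if isinstance(root_prior, str):
            if root_prior == "flat":
                return np.full(self.k, 1.0 / self.k)
            if root_prior == "stationary":
                return stationary_distribution(Q)
            if root_prior == "fitzjohn":
                s = L_root.sum()
                if s <= 0:
                    return np.full(self.k, 1.0 / self.k)
                return L_root / s
            raise ValueError(f"unknown root prior {root_prior!r}")
        pi = np.asarray(root_prior, dtype=float)
        if pi.shape != (self.k,) or np.any(pi < 0):
            raise ValueError("root prior must be a nonnegative length-k vector")
        return pi / pi.sum()

    def loglik(self, Q: np.ndarray, root_prior="flat") -> float:
        res = self.downpass(Q)
        if res is None:
            return -np.inf
        L, logscale, _ = res
        root = self.tree.root
        pi = self.root_prior_vector(root_prior, Q, L[root])
        lik = float(pi @ L[root])
        if lik <= 0:
            return -np.inf
        return np.log(lik) + logscale[root]


def mk_loglik(tree: Phylogeny, tip_states, Q: np.ndarray, root_prior="flat") -> float:
    """Pruning log-likelihood of a discrete character on a tree.

    ``root_prior`` may be a probability vector or one of "flat", "stationary",
    "fitzjohn" (root conditional likelihoods, normalized).
    """
    _check_generator(Q)
    data = MkData(tree, tip_states, Q.shape[0])
    return data.loglik(Q, root_prior)


# ------------------------------------------------------------------ ML fitting


@dataclass
class MkFit:
    structure: str
    rate_index: np.ndarray
    rates: np.ndarray
    Q: np.ndarray
    loglik: float
    n_params: int
    aic: float
    root_prior_mode: object
    root_prior: np.ndarray
    converged: bool = True
    state_names: list | None = None

    def rates_frame(self) -> pd.DataFrame:
        names = self.state_names or list(range(self.rate_index.shape[0]))
        return pd.DataFrame(self.Q, index=names, columns=names)


def fit_mk(
    tree: Phylogeny,
    tip_states,
    structure="ARD",
    k: int | None = None,
    root_prior="fitzjohn",
    n_starts: int = 5,
    seed: int = 0,
    extra_starts=None,
    state_names=None,
) -> MkFit:
    """Maximum-likelihood Mk fit under an ER/SYM/ARD (or custom) structure.

    ``structure`` may be a string or an explicit rate-index matrix (see
    :func:`rate_index_matrix`; -2 forbids a transition).  Optimization is a
    seeded multistart L-BFGS-B on log rates bounded in [1e-8, 1e3].
    ``extra_starts`` adds user-supplied rate vectors as starting points.
    """
    if isinstance(structure, str):
        if k is None:
            k = int(pd.Series(dict(tip_states) if isinstance(tip_states, dict)
                              else tip_states).max()) + 1
        rate_index = rate_index_matrix(k, structure)
        structure_name = structure
    else:
        rate_index = np.asarray(structure, dtype=np.int64)
        k = rate_index.shape[0]
        structure_name = "custom"
    npar = n_free_rates(rate_index)
    data = MkData(tree, tip_states, k)

    def objective(log_rates):
        Q = build_generator(rate_index, np.exp(log_rates))
        ll = data.loglik(Q, root_prior)
        return -ll if np.isfinite(ll) else 1e10  # finite penalty keeps FD gradients clean

    # empirical rate scale: observed state changes per unit tree length, then
    # a 1-D scan over a common rate multiplier.  The scan both seeds the
    # multistart near the likelihood ridge and guards against the line search
    # overshooting onto the saturated-rate plateau (where the likelihood is
    # exactly flat and box-constrained quasi-Newton steps stall).
    total_len = max(data.tree.total_length(), 1e-9)
    base_rate = max(len(set(data.tip_state_array)) - 1, 1) / total_len * 2.0
    scan = base_rate * np.geomspace(1e-2, 3e2, 16)
    scan_obj = [objective(np.full(npar, np.log(c))) for c in scan]
    best_scan = float(scan[int(np.argmin(scan_obj))])
    rng = np.random.default_rng(seed)
    starts = [np.full(npar, np.log(best_scan))]
    for _ in range(max(0, n_starts - 1)):
        starts.append(np.log(best_scan) + rng.normal(0.0, 1.2, size=npar))
    if extra_starts is not None:
        for r in extra_starts:
            starts.append(np.log(np.clip(np.asarray(r, dtype=float),
                                         RATE_MIN, RATE_MAX)))
    bounds = [(np.log(RATE_MIN), np.log(RATE_MAX))] * npar

    best = None
    any_converged = False
    for x0 in starts:
        res = minimize(objective, np.clip(x0, np.log(RATE_MIN), np.log(RATE_MAX)),
                       method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
        any_converged = any_converged or bool(res.success)
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("Mk optimization failed from every start")
    if not any_converged:
        warnings.warn("Mk optimizer did not report convergence; returning best found",
                      RuntimeWarning)
    rates = np.exp(best.x)
    Q = build_generator(rate_index, rates)
    ll = -best.fun
    res_down = data.downpass(Q)
    L_root = res_down[0][tree.root] if res_down is not None else np.full(k, 1.0 / k)
    pi = data.root_prior_vector(root_prior, Q, L_root)
    return MkFit(
        structure=structure_name,
        rate_index=rate_index,
        rates=rates,
        Q=Q,
        loglik=ll,
        n_params=npar,
        aic=2.0 * npar - 2.0 * ll,
        root_prior_mode=root_prior,
        root_prior=pi,
        converged=any_converged,
        state_names=list(state_names) if state_names is not None else None,
    )


def fit_mk_models(tree: Phylogeny, tip_states, k: int, root_prior="fitzjohn",
                  n_starts: int = 5, seed: int = 0, state_names=None) -> dict:
    """Fit ER, SYM and ARD on the same data with nested warm starts.

    The SYM fit is additionally started from the ER MLE and the ARD fit from
    the SYM MLE (each mapped into the larger parameterization), so the nested
    log-likelihood ordering ER <= SYM <= ARD holds at the optima.
    """
    fits: dict[str, MkFit] = {}
    fits["ER"] = fit_mk(tree, tip_states, "ER", k=k, root_prior=root_prior,
                        n_starts=n_starts, seed=seed, state_names=state_names)
    idx_sym = rate_index_matrix(k, "SYM")
    er_in_sym = np.full(n_free_rates(idx_sym), fits["ER"].rates[0])
    fits["SYM"] = fit_mk(tree, tip_states, "SYM", k=k, root_prior=root_prior,
                         n_starts=n_starts, seed=seed + 1,
                         extra_starts=[er_in_sym], state_names=state_names)
    idx_ard = rate_index_matrix(k, "ARD")
    Q_sym = fits["SYM"].Q
    sym_in_ard = np.array([Q_sym[i, j] for i in range(k) for j in range(k) if i != j])
    fits["ARD"] = fit_mk(tree, tip_states, "ARD", k=k, root_prior=root_prior,
                         n_starts=n_starts, seed=seed + 2,
                         extra_starts=[sym_in_ard], state_names=state_names)
    return fits


def aic_weights(fits) -> np.ndarray:
    """Akaike weights w_i = exp(-dAIC_i/2) / sum_j exp(-dAIC_j/2)."""
    aics = np.array([f.aic if hasattr(f, "aic") else float(f) for f in fits])
    if aics.size < 2:
        raise ValueError("AIC weights need at least two fitted models")
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


# ----------------------------------------------------------- posterior over Q


@dataclass
class QPosterior:
    structure: str
    rate_index: np.ndarray
    rates: np.ndarray            # (n_samples, n_params)
    acceptance_rate: float
    mle: MkFit
    root_prior_mode: object

    def generator(self, i: int) -> np.ndarray:
        return build_generator(self.rate_index, self.rates[i])

    @property
    def n_samples(self) -> int:
        return self.rates.shape[0]


def sample_q_posterior(
    tree: Phylogeny,
    tip_states,
    structure="ARD",
    n_samples: int = 1000,
    seed: int = 0,
    k: int | None = None,
    root_prior="fitzjohn",
    thin: int = 2,
    prior_mean: np.ndarray | None = None,
    step: float = 0.4,
    mle: MkFit | None = None,
) -> QPosterior:
    """Metropolis sampling of the rate-matrix posterior.

    Log-rate random-walk proposals; independent exponential priors on rates
    with mean equal to the MLE (or ``prior_mean``); burn-in is 10% of the
    chain with step-size adaptation toward ~30% acceptance; the post-burn-in
    chain is thinned by ``thin`` to yield ``n_samples`` draws.  Reproducible
    given ``seed``.
    """
    if mle is None:
        mle = fit_mk(tree, tip_states, structure=structure, k=k,
                     root_prior=root_prior, seed=seed)
    rate_index = mle.rate_index
    kk = rate_index.shape[0]
    npar = mle.n_params
    data = MkData(tree, tip_states, kk)
    if prior_mean is None:
        prior_mean = np.clip(mle.rates, 1e-4, None)
    prior_rate = 1.0 / np.asarray(prior_mean, dtype=float)

    def logpost(log_r):
        r = np.exp(log_r)
        Q = build_generator(rate_index, r)
        ll = data.loglik(Q, root_prior)
        if not np.isfinite(ll):
            return -np.inf
        # exponential prior on rates + log-scale Jacobian
        return ll + np.sum(-prior_rate * r) + np.sum(log_r)

    rng = np.random.default_rng(seed)
    keep_iters = n_samples * thin
    burn = max(int(np.ceil(keep_iters / 9.0)), 50)  # burn-in = 10% of chain
    x = np.log(np.clip(mle.rates, RATE_MIN, RATE_MAX))
    lp = logpost(x)
    out = np.empty((n_samples, npar))
    accepted = 0
    proposed = 0
    kept = 0
    s = step
    for it in range(burn + keep_iters):
        prop = x + rng.normal(0.0, s, size=npar)
        lp_prop = logpost(prop)
        proposed += 1
        if np.log(rng.uniform()) < lp_prop - lp:
            x, lp = prop, lp_prop
            accepted += 1
        if it < burn and (it + 1) % 50 == 0:  # adapt during burn-in only
            rate = accepted / proposed
            if rate < 0.2:
                s *= 0.7
            elif rate > 0.45:
                s *= 1.4
            accepted = 0
            proposed = 0
        if it >= burn and (it - burn) % thin == thin - 1:
            out[kept] = np.exp(x)
            kept += 1
    acc = accepted / max(proposed, 1)
    if not 0.05 <= acc <= 0.8:
        warnings.warn(f"MCMC acceptance rate {acc:.3f} outside [0.05, 0.8]",
                      RuntimeWarning)
    return QPosterior(
        structure=mle.structure,
        rate_index=rate_index,
        rates=out[:kept],
        acceptance_rate=acc,
        mle=mle,
        root_prior_mode=root_prior,
    )


# ----------------------------------------------------- marginal node posteriors


def marginal_node_posteriors(tree: Phylogeny, tip_states, Q: np.ndarray,
                             root_prior="fitzjohn") -> pd.DataFrame:
    """Marginal posterior state probabilities for every node (tips included).

    Standard down-pass/up-pass computation; rows sum to one and are indexed by
    node id in the tree's own numbering.
    """
    _check_generator(Q)
    k = Q.shape[0]
    data = MkData(tree, tip_states, k)
    res = data.downpass(Q)
    if res is None:
        raise FloatingPointError("likelihood underflow in downpass")
    L, logscale, P = res
    root = tree.root
    pi = data.root_prior_vector(root_prior, Q, L[root])
    n = tree.n_nodes
    G = np.zeros((n, k))  # up-pass partials (prior-to-node messages)
    G[root] = pi
    for node in tree.preorder():
        kids = tree.children(int(node))
        if len(kids) != 2:
            continue
        a, b = kids
        Ma = P[a] @ L[a]
        Mb = P[b] @ L[b]
        G[a] = (G[int(node)] * Mb) @ P[a]
        G[b] = (G[int(node)] * Ma) @ P[b]
    post = G * L
    norm = post.sum(axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return pd.DataFrame(post / norm, index=range(n))
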