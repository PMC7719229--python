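"""Correlated evolution of two binary traits (Pagel's discrete test).

Both traits are placed on the product state space {00, 01, 10, 11} (state
code = 2*a + b).  The independent model gives each trait its own gain and
loss rate (4 free rates, shared across the other trait's background); the
dependent model frees all 8 single-step transitions.  Simultaneous double
transitions (00<->11, 01<->10) are disallowed in both models, so the
dependent model nests the independent one with 4 extra degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mk import MkFit, build_generator, fit_mk, n_free_rates
from .trees import Phylogeny

__all__ = [
    "independent_rate_index",
    "dependent_rate_index",
    "combine_binary_traits",
    "CorrelatedEvolutionResult",
    "correlated_evolution",
    "binarize",
]

PAIR_STATES = ("00", "01", "10", "11")


def independent_rate_index() -> np.ndarray:
    """4-state structure where trait A and trait B evolve independently.

    Free rates: 0 = A gain (0->1), 1 = A loss, 2 = B gain, 3 = B loss.
    """
    idx = np.full((4, 4), -2, dtype=np.int64)
    np.fill_diagonal(idx, -1)
    a_gain, a_loss, b_gain, b_loss = 0, 1, 2, 3
    idx[0, 2] = a_gain   # 00 -> 10
    idx[1, 3] = a_gain   # 01 -> 11
    idx[2, 0] = a_loss   # 10 -> 00
    idx[3, 1] = a_loss   # 11 -> 01
    idx[0, 1] = b_gain   # 00 -> 01
    idx[2, 3] = b_gain   # 10 -> 11
    idx[1, 0] = b_loss   # 01 -> 00
    idx[3, 2] = b_loss   # 11 -> 10
    return idx


def dependent_rate_index() -> np.ndarray:
    """4-state structure with all 8 single-step transitions free."""
    idx = np.full((4, 4), -2, dtype=np.int64)
    np.fill_diagonal(idx, -1)
    c = 0
    for i, j in [(0, 1), (0, 2), (1, 0), (1, 3), (2, 0), (2, 3), (3, 1), (3, 2)]:
        idx[i, j] = c
        c += 1
    return idx


def combine_binary_traits(a: pd.Series, b: pd.Series) -> pd.Series:
    """Combine two aligned binary traits into product-state codes 2*a + b."""
    a = a.astype(int)
    b = b.loc[a.index].astype(int)
    if not set(a.unique()) <= {0, 1} or not set(b.unique()) <= {0, 1}:
        raise ValueError("traits must be binary (0/1)")
    return (2 * a + b).rename("pair_state")


@dataclass
class CorrelatedEvolutionResult:
    fit_independent: MkFit
    fit_dependent: MkFit
    loglik_independent: float
    loglik_dependent: float
    lr: float
    df: int
    p_value: float


def correlated_evolution(tree: Phylogeny, trait_a, trait_b,
                         root_prior="fitzjohn", n_starts: int = 5,
                         seed: int = 0) -> CorrelatedEvolutionResult:
    """ML likelihood-ratio test of dependent vs independent binary evolution.

    The dependent fit is also started from the independent MLE (mapped into
    the 8-rate parameterization), which guarantees the nesting inequality
    loglik_dependent >= loglik_independent at the optimum.
    """
    if isinstance(trait_a, dict):
        trait_a = pd.Series(trait_a)
    if isinstance(trait_b, dict):
        trait_b = pd.Series(trait_b)
    for name, tr in (("a", trait_a), ("b", trait_b)):
        vals = set(pd.Series(tr).unique())
        if len(vals) < 2:
            raise ValueError(f"trait {name} is constant; rates unidentifiable")
    pair = combine_binary_traits(trait_a, trait_b)
    idx_ind = independent_rate_index()
    idx_dep = dependent_rate_index()

    fit_ind = fit_mk(tree, pair, structure=idx_ind, root_prior=root_prior,
                     n_starts=n_starts, seed=seed, state_names=list(PAIR_STATES))
    # map independent MLE onto the dependent parameterization as a warm start
    Q_ind = build_generator(idx_ind, fit_ind.rates)
    warm = np.array([Q_ind[i, j] for i, j in
                     [(0, 1), (0, 2), (1, 0), (1, 3), (2, 0), (2, 3), (3, 1), (3, 2)]])
    fit_dep = fit_mk(tree, pair, structure=idx_dep, root_prior=root_prior,
                     n_starts=n_starts, seed=seed + 1, extra_starts=[warm],
                     state_names=list(PAIR_STATES))
    lli, lld = fit_ind.loglik, fit_dep.loglik
    df = n_free_rates(idx_dep) - n_free_rates(idx_ind)
    lr = max(2.0 * (lld - lli), 0.0)
    return CorrelatedEvolutionResult(
        fit_independent=fit_ind,
        fit_dependent=fit_dep,
        loglik_independent=lli,
        loglik_dependent=lld,
        lr=lr,
        df=df,
        p_value=float(stats.chi2.sf(lr, df)),
    )


def binarize(values, rule: str = "mean"):
    """Binarize a continuous trait; returns (codes, threshold).

    ``mean``: 0 iff value < mean (values at the mean go to 1).
    ``median_le``: 0 ("slow") iff value <= median -- the growth-rate
    convention for rRNA copy numbers.
    """
    s = pd.Series(values, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least two values")
    if rule == "mean":
        thr = float(s.mean())
        codes = (s >= thr).astype(int)
    elif rule == "median_le":
        thr = float(s.median())
        codes = (s > thr).astype(int)
    else:
        raise ValueError("rule must be 'mean' or 'median_le'")
    return codes, thr
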