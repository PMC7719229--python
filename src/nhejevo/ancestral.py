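"""Ancestral reconstruction of continuous traits under Brownian motion.

The joint ML (equivalently GLS) estimates of ancestral values solve a sparse
linear system: each internal node's value is the branch-length-weighted
harmonic average of its neighbors.  The root estimate coincides with the GLS
mean of the tip data under the Brownian covariance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trees import Phylogeny

__all__ = ["brownian_ancestral", "brownian_sigma2_ml"]


def _align_tip_values(tree: Phylogeny, x) -> np.ndarray:
    if isinstance(x, dict):
        x = pd.Series(x)
    tips = tree.tip_indices()
    labels = [tree.labels[t] for t in tips]
    missing = [lb for lb in labels if lb not in x.index]
    if missing:
        raise ValueError(f"tips without a value: {', '.join(missing[:5])}")
    return x.loc[labels].to_numpy(dtype=float)


def brownian_sigma2_ml(tree: Phylogeny, x) -> float:
    """ML estimate of the Brownian rate from tip data (GLS residual variance)."""
    vals = _align_tip_values(tree, x)
    C = tree.shared_depth_matrix().to_numpy()
    n = len(vals)
    Cinv = np.linalg.inv(C)
    one = np.ones(n)
    mu = float(one @ Cinv @ vals / (one @ Cinv @ one))
    r = vals - mu
    return float(r @ Cinv @ r / n)


def brownian_ancestral(tree: Phylogeny, x) -> pd.DataFrame:
    """ML ancestral state estimates and variances under single-rate BM.

    Returns a frame indexed by internal node id with columns ``estimate`` and
    ``variance``; the root row equals the GLS mean of the tips.  Variances are
    conditional variances given the tip data, scaled by the ML Brownian rate.
    """
    vals_by_tip: dict[int, float] = {}
    if isinstance(x, dict):
        x = pd.Series(x)
    for t in tree.tip_indices():
        lb = tree.labels[t]
        if lb not in x.index:
            raise ValueError(f"tip {lb!r} has no value")
        vals_by_tip[t] = float(x[lb])

    internal = [i for i in range(tree.n_nodes) if not tree.is_tip(i)]
    pos = {node: i for i, node in enumerate(internal)}
    m = len(internal)
    A = np.zeros((m, m))
    b = np.zeros(m)
    for node in range(tree.n_nodes):
        p = tree.parent[node]
        if p < 0:
            continue
        t = max(float(tree.blen[node]), 1e-12)
        w = 1.0 / t
        i = pos[int(p)]
        A[i, i] += w
        if tree.is_tip(node):
            b[i] += w * vals_by_tip[node]
        else:
            j = pos[node]
            A[i, j] -= w
            A[j, i] -= w
            A[j, j] += w
    est = np.linalg.solve(A, b)
    sigma2 = brownian_sigma2_ml(tree, x)
    var = sigma2 * np.diag(np.linalg.inv(A))
    return pd.DataFrame({"estimate": est, "variance": var}, index=internal)
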