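"""Independent oracles used by the test suite.

These deliberately avoid the package's own computational paths: likelihoods
by exhaustive enumeration over internal-node states, distances by undirected
path sums, expected CTMC jump counts by numerical integration, Fisher tails
by hypergeometric enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.stats import hypergeom


def loglik_by_enumeration(tree, tip_states, Q, prior) -> float:
    """Sum over all internal-node state combinations (small trees only)."""
    k = Q.shape[0]
    P = {n: expm(Q * tree.blen[n]) for n in range(tree.n_nodes)}
    internals = [i for i in range(tree.n_nodes) if not tree.is_tip(i)]
    state = {t: int(tip_states[tree.labels[t]]) for t in tree.tip_indices()}
    total = 0.0
    for combo in itertools.product(range(k), repeat=len(internals)):
        for nd, s in zip(internals, combo):
            state[nd] = s
        p = prior[state[tree.root]]
        for nd in range(tree.n_nodes):
            if nd == tree.root:
                continue
            p *= P[nd][state[tree.parent[nd]], state[nd]]
        total += p
    return float(np.log(total))


def patristic_by_path_sum(tree) -> dict:
    """Tip-to-tip distances by BFS over the undirected edge graph."""
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(tree.n_nodes)}
    for i in range(tree.n_nodes):
        p = tree.parent[i]
        if p >= 0:
            adj[i].append((int(p), float(tree.blen[i])))
            adj[int(p)].append((i, float(tree.blen[i])))
    out = {}
    tips = tree.tip_indices()
    for src in tips:
        dist = {src: 0.0}
        queue = [src]
        while queue:
            u = queue.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    queue.append(v)
        for dst in tips:
            out[(tree.labels[src], tree.labels[dst])] = dist[dst]
    return out


def expected_jumps_conditioned(Q, t, a, b, i, j) -> float:
    """E[# of i->j transitions | X_0 = a, X_t = b] by numerical integration.

    Uses E[N_ij | a, b] = q_ij * Int_0^t p_ai(s) p_jb(t-s) ds / p_ab(t).
    """
    def integrand(s):
        return expm(Q * s)[a, i] * expm(Q * (t - s))[j, b]

    val, _ = quad(integrand, 0.0, t, limit=200)
    p_ab = expm(Q * t)[a, b]
    return float(Q[i, j] * val / p_ab)


def fisher_p_by_enumeration(a, b, c, d) -> float:
    """Two-sided Fisher exact p by enumerating tables with fixed margins."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    rv = hypergeom(n, row1, col1)
    p_obs = rv.pmf(a)
    total = 0.0
    for x in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        px = rv.pmf(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return float(min(total, 1.0))


def mantel_p_by_enumeration(D1: np.ndarray, D2: np.ndarray) -> tuple[float, float]:
    """Exhaustive one-tailed Mantel p over all label permutations."""
    n = D1.shape[0]
    il = np.tril_indices(n, k=-1)
    a = D1[il]
    r_obs = np.corrcoef(a, D2[il])[0, 1]
    exceed = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        perm = np.array(perm)
        r = np.corrcoef(a, D2[np.ix_(perm, perm)][il])[0, 1]
        total += 1
        if r >= r_obs - 1e-12:
            exceed += 1
    return float(r_obs), exceed / total


def ranksum_p_by_enumeration(x, y) -> float:
    """Two-sided rank-sum p by enumerating all group assignments (no ties)."""
    x = list(x)
    y = list(y)
    pooled = np.array(x + y, dtype=float)
    n1 = len(x)
    ranks = {v: r for r, v in enumerate(np.sort(pooled), start=1)}
    obs = sum(ranks[v] for v in x)
    center = n1 * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = sum(ranks[pooled[i]] for i in combo)
        total += 1
        if abs(w - center) >= abs(obs - center) - 1e-12:
            count += 1
    return count / total
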