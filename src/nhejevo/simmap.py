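"""Stochastic character mapping and its summaries.

A stochastic map is one full character history drawn from the posterior:
states at every node plus, on every branch, the ordered (state, dwell-time)
segments of an endpoint-conditioned CTMC path.  Node states are drawn from
their joint posterior by a pre-order sweep over conditional likelihoods;
branch paths are drawn exactly by uniformization, which remains robust on the
1e-6 branches introduced by polytomy resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mk import MkData, _check_generator, transition_matrices
from .trees import Phylogeny

__all__ = [
    "StochasticMap",
    "MapSummary",
    "stochastic_map",
    "summarize_maps",
    "call_node_states",
    "PrimaryGainCall",
    "find_primary_gains",
]


@dataclass
class StochasticMap:
    """One sampled character history on a tree."""

    tree: Phylogeny
    node_states: np.ndarray               # state index per node id
    segments: dict                        # node id -> [(state, dwell), ...] on the branch above
    k: int

    def transition_counts(self) -> np.ndarray:
        counts = np.zeros((self.k, self.k))
        for segs in self.segments.values():
            for (s0, _), (s1, _) in zip(segs, segs[1:]):
                counts[s0, s1] += 1
        return counts

    def time_in_state(self) -> np.ndarray:
        t = np.zeros(self.k)
        for segs in self.segments.values():
            for s, dwell in segs:
                t[s] += dwell
        return t


def _sample_path(Q, R, Rpows, omega, t, a, b, rng):
    """Endpoint-conditioned CTMC path on one branch by uniformization.

    Returns the ordered (state, dwell) segments from state ``a`` (branch top)
    to state ``b`` over duration ``t``.
    """
    k = Q.shape[0]
    if omega <= 0.0:  # Q == 0: no movement possible
        return [(a, t)]

    mu = omega * t
    # P(N = n | a, b) proportional to Poisson(n; mu) * R^n[a, b]; the series
    # is summed to numerical convergence and used as its own normalizer so the
    # draw is exact regardless of how the endpoint probability was computed.
    max_n = int(mu + 12.0 * np.sqrt(mu) + 60)
    log_pois = -mu
    terms = []
    acc = 0.0
    for n in range(max_n + 1):
        while len(Rpows) <= n:
            Rpows.append(Rpows[-1] @ R)
        term = np.exp(log_pois) * Rpows[n][a, b]
        terms.append(term)
        acc += term
        if n > mu + 6.0 * np.sqrt(mu) + 5 and term < 1e-14 * max(acc, 1e-300):
            break
        log_pois += np.log(mu) - np.log(n + 1)
    if acc <= 0.0:  # endpoint pair unreachable under Q; keep parent state
        return [(a, t)]
    target = rng.uniform() * acc
    cum = 0.0
    n_jumps = len(terms) - 1
    for n, term in enumerate(terms):
        cum += term
        if cum >= target:
            n_jumps = n
            break

    if n_jumps == 0:
        return [(a, t)]
    # uniformized jump chain states, bridged between a and b
    states = [a]
    for j in range(1, n_jumps):
        prev = states[-1]
        w = R[prev, :] * Rpows[n_jumps - j][:, b]
        total = w.sum()
        if total <= 0:
            w = np.full(k, 1.0 / k)
            total = 1.0
        states.append(int(rng.choice(k, p=w / total)))
    states.append(b)
    times = np.sort(rng.uniform(0.0, t, size=n_jumps))
    # build segments, collapsing virtual (self) jumps
    segs: list[tuple[int, float]] = []
    cur = a
    last = 0.0
    for s, tm in zip(states[1:], times):
        if s != cur:
            segs.append((cur, tm - last))
            cur = s
            last = tm
    segs.append((cur, t - last))
    return segs


def stochastic_map(tree: Phylogeny, tip_states, Q: np.ndarray,
                   root_prior="fitzjohn", seed=None, rng=None,
                   _data: MkData | None = None, _down=None) -> StochasticMap:
    """Draw one stochastic map conditioned on tip data and Q."""
    _check_generator(Q)
    k = Q.shape[0]
    if rng is None:
        rng = np.random.default_rng(seed)
    data = _data if _data is not None else MkData(tree, tip_states, k)
    down = _down if _down is not None else data.downpass(Q)
    if down is None:
        raise FloatingPointError("likelihood underflow; cannot map")
    L, _, P = down
    root = tree.root

    node_states = np.full(tree.n_nodes, -1, dtype=np.int64)
    pi = data.root_prior_vector(root_prior, Q, L[root])
    w = pi * L[root]
    node_states[root] = int(rng.choice(k, p=w / w.sum()))
    for node in tree.preorder():
        node = int(node)
        for c in tree.children(node):
            wv = P[c][node_states[node], :] * L[c]
            total = wv.sum()
            if total <= 0:
                wv = np.full(k, 1.0 / k)
                total = 1.0
            node_states[c] = int(rng.choice(k, p=wv / total))

    omega = float(max(-np.diag(Q).min(), 0.0))
    if omega > 0:
        R = np.eye(k) + Q / omega
    else:
        R = np.eye(k)
    Rpows = [np.eye(k)]
    segments: dict[int, list[tuple[int, float]]] = {}
    for node in range(tree.n_nodes):
        if node == root:
            continue
        a = node_states[tree.parent[node]]
        b = node_states[node]
        t = float(data.blen[node])
        segments[node] = _sample_path(Q, R, Rpows, omega, t, int(a), int(b), rng)
    return StochasticMap(tree=tree, node_states=node_states, segments=segments, k=k)


@dataclass
class MapSummary:
    """Averages over a set of stochastic maps on one tree."""

    tree: Phylogeny
    k: int
    n_maps: int
    mean_transition_counts: np.ndarray    # k x k, mean over maps
    transition_rel_freq: np.ndarray       # off-diagonal cells, sums to 1
    time_in_state: np.ndarray             # mean total dwell per state
    node_posteriors: pd.DataFrame         # node id x state frequency
    state_names: list | None = None

    def transition_frame(self) -> pd.DataFrame:
        names = self.state_names or list(range(self.k))
        return pd.DataFrame(self.mean_transition_counts, index=names, columns=names)


def summarize_maps(maps: list[StochasticMap], state_names=None) -> MapSummary:
    """Mean transition counts, time in state and per-node state frequencies."""
    if not maps:
        raise ValueError("need at least one map")
    tree = maps[0].tree
    k = maps[0].k
    ref_tips = tuple(tree.tip_labels)
    counts = np.zeros((k, k))
    times = np.zeros(k)
    node_freq = np.zeros((tree.n_nodes, k))
    for m in maps:
        if m.k != k or tuple(m.tree.tip_labels) != ref_tips \
                or m.tree.n_nodes != tree.n_nodes:
            raise ValueError("all maps must live on the same tree")
        counts += m.transition_counts()
        times += m.time_in_state()
        node_freq[np.arange(tree.n_nodes), m.node_states] += 1.0
    n = len(maps)
    counts /= n
    times /= n
    node_freq /= n
    off = counts.copy()
    np.fill_diagonal(off, 0.0)
    total = off.sum()
    rel = off / total if total > 0 else off
    return MapSummary(
        tree=tree, k=k, n_maps=n,
        mean_transition_counts=counts,
        transition_rel_freq=rel,
        time_in_state=times,
        node_posteriors=pd.DataFrame(node_freq, index=range(tree.n_nodes)),
        state_names=list(state_names) if state_names is not None else None,
    )


def call_node_states(summary: MapSummary, threshold: float = 0.7) -> pd.Series:
    """Argmax state per node when its posterior probability exceeds ``threshold``.

    The threshold is exclusive (a node at exactly the threshold stays
    uncalled); uncalled nodes carry -1.
    """
    post = summary.node_posteriors.to_numpy()
    best = post.argmax(axis=1)
    pp = post[np.arange(post.shape[0]), best]
    calls = np.where(pp > threshold, best, -1)
    return pd.Series(calls, index=summary.node_posteriors.index, name="state")


@dataclass
class PrimaryGainCall:
    node_id: int
    gained_state: int
    n_descendant_tips: int
    pp_at_node: float


def find_primary_gains(
    tree: Phylogeny,
    calls: pd.Series,
    posteriors: pd.DataFrame,
    absent_state: int,
    gain_states: tuple,
    full_state: int,
    tip_states=None,
    min_desc: int = 3,
    pp_threshold: float = 0.7,
) -> list[PrimaryGainCall]:
    """Primary acquisitions of the trait on a rooted tree.

    A node is reported when (1) every node on the path from the root down to
    its parent is called ``absent_state``; (2) the posterior probability of
    one of ``gain_states`` or ``full_state`` at the node is >= ``pp_threshold``;
    (3) a gain of a partial state (``gain_states``) is later completed -- some
    descendant node (or tip, when tip states are given) carries
    ``full_state``; and (4) the node subtends at least ``min_desc`` tips.
    """
    if not tree.rooted:
        raise ValueError("primary-gain calling requires a rooted tree")
    below = tree.tips_below()
    post = posteriors.to_numpy()
    candidate_states = tuple(gain_states) + (full_state,)
    tip_state_by_node = {}
    if tip_states is not None:
        ts = tip_states if isinstance(tip_states, pd.Series) else pd.Series(tip_states)
        for t in tree.tip_indices():
            tip_state_by_node[t] = int(ts[tree.labels[t]])

    def descendant_has_full(node: int) -> bool:
        stack = list(tree.children(node))
        while stack:
            x = stack.pop()
            if tree.is_tip(x):
                if tip_state_by_node.get(x, -1) == full_state:
                    return True
            else:
                if calls.get(x, -1) == full_state:
                    return True
                stack.extend(tree.children(x))
        return False

    out: list[PrimaryGainCall] = []
    for node in range(tree.n_nodes):
        if tree.is_tip(node) or node == tree.root:
            continue
        anc = tree.ancestors(node)
        if any(calls.get(a, -1) != absent_state for a in anc):
            continue
        pps = {s: post[node, s] for s in candidate_states}
        gained = max(pps, key=pps.get)
        if pps[gained] < pp_threshold:
            continue
        if gained in gain_states and not descendant_has_full(node):
            continue
        n_tips = len(below[node])
        if n_tips < min_desc:
            continue
        out.append(PrimaryGainCall(node_id=node, gained_state=int(gained),
                                   n_descendant_tips=n_tips,
                                   pp_at_node=float(pps[gained])))
    return out
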