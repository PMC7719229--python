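"""Phylogeny container and tree operations.

Everything downstream (Mk likelihoods, stochastic mapping, comparative tests)
works on an array-backed rooted tree: integer node ids, a parent array, a
branch-length array and per-node labels.  Newick reading/writing is delegated
to dendropy; rooting, polytomy resolution, pruning and patristic distances are
implemented here so that their tie-breaking rules are deterministic.
"""

from __future__ import annotations

import io
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "NewickParseError",
    "read_newick",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


def _needs_quoting(label: str) -> bool:
    special = set("()[]{}/\\,;:=*'\"`<> \t\n")
    return any(c in special for c in label)


def _format_label(label: str) -> str:
    if _needs_quoting(label):
        return "'" + label.replace("'", "''") + "'"
    return label


class Phylogeny:
    """Rooted phylogenetic tree with branch lengths.

    Parameters
    ----------
    parent:
        Integer array, ``parent[i]`` is the parent node id of node ``i`` and
        ``-1`` for the root (exactly one root).
    blen:
        Branch length of the edge above each node (ignored for the root,
        stored as 0).  All lengths must be >= 0.
    labels:
        Per-node label or ``None``.  Tip labels must be unique and non-empty;
        internal labels (e.g. support values read from Newick) are carried as
        plain strings and never interpreted.
    """

    def __init__(
        self,
        parent: Sequence[int],
        blen: Sequence[float],
        labels: Sequence[str | None],
        rooted: bool = True,
        validate: bool = True,
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.blen = np.asarray(blen, dtype=float).copy()
        self.labels = list(labels)
        self.rooted = rooted
        n = self.parent.shape[0]
        if self.blen.shape[0] != n or len(self.labels) != n:
            raise ValueError("parent, blen and labels must have equal length")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        self.blen[self.root] = 0.0
        self._children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            p = self.parent[i]
            if p >= 0:
                self._children[p].append(i)
        if validate:
            self._validate()
        self._postorder_cache: np.ndarray | None = None

    # ------------------------------------------------------------------ basics

    def _validate(self) -> None:
        if np.any(self.blen < 0):
            raise ValueError("negative branch lengths")
        tips = [self.labels[i] for i in self.tip_indices()]
        if any(t is None or t == "" for t in tips):
            raise ValueError("all tips must carry non-empty labels")
        if len(set(tips)) != len(tips):
            raise ValueError("tip labels must be unique")

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    def children(self, node: int) -> list[int]:
        return self._children[node]

    def is_tip(self, node: int) -> bool:
        return not self._children[node]

    def tip_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.is_tip(i)]

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices())

    def postorder(self) -> np.ndarray:
        """Node ids in postorder (children before parents)."""
        if self._postorder_cache is None:
            order: list[int] = []
            stack = [self.root]
            while stack:
                node = stack.pop()
                order.append(node)
                stack.extend(self._children[node])
            self._postorder_cache = np.array(order[::-1], dtype=np.int64)
        return self._postorder_cache

    def preorder(self) -> np.ndarray:
        return self.postorder()[::-1]

    def is_bifurcating(self) -> bool:
        return all(
            len(self._children[i]) in (0, 2)
            for i in range(self.n_nodes)
        )

    def total_length(self) -> float:
        mask = np.ones(self.n_nodes, dtype=bool)
        mask[self.root] = False
        return float(self.blen[mask].sum())

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths."""
        d = np.zeros(self.n_nodes)
        for node in self.preorder():
            p = self.parent[node]
            if p >= 0:
                d[node] = d[p] + self.blen[node]
        return d

    def height(self) -> float:
        d = self.depths()
        return float(max(d[i] for i in self.tip_indices()))

    def copy(self) -> "Phylogeny":
        return Phylogeny(
            self.parent.copy(), self.blen.copy(), list(self.labels),
            rooted=self.rooted, validate=False,
        )

    def scale(self, factor: float) -> "Phylogeny":
        """Return a copy with all branch lengths multiplied by ``factor``."""
        out = self.copy()
        out.blen = out.blen * factor
        out.blen[out.root] = 0.0
        return out

    def tips_below(self) -> list[set[int]]:
        """Per node, the set of descendant tip ids (a tip contains itself)."""
        below: list[set[int]] = [set() for _ in range(self.n_nodes)]
        for node in self.postorder():
            if self.is_tip(node):
                below[node].add(node)
            else:
                for c in self._children[node]:
                    below[node] |= below[c]
        return below

    def ancestors(self, node: int) -> list[int]:
        """Ancestor node ids from the parent of ``node`` up to the root."""
        out = []
        p = self.parent[node]
        while p >= 0:
            out.append(int(p))
            p = self.parent[p]
        return out

    # ------------------------------------------------------------------ newick

    @classmethod
    def from_newick(cls, text: str, rooted: bool = True) -> "Phylogeny":
        import dendropy
        from dendropy.utility import error as dperror

        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except (dperror.DataParseError, dperror.TaxonNamespaceReconstructionError) as exc:
            col = getattr(exc, "col_num", None)
            offset = f" near character offset {col}" if col is not None else ""
            raise NewickParseError(f"malformed Newick{offset}: {exc}") from exc
        except Exception as exc:  # dendropy raises plain exceptions for some defects
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        return cls.from_dendropy(dtree, rooted=rooted)

    @classmethod
    def from_dendropy(cls, dtree, rooted: bool = True) -> "Phylogeny":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        blen = np.zeros(len(nodes))
        labels: list[str | None] = [None] * len(nodes)
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                blen[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.label is not None:
                labels[i] = str(nd.label)
        return cls(parent, blen, labels, rooted=rooted)

    def to_newick(self, precision: int = 10) -> str:
        """Serialize to Newick; branch lengths use ``precision`` significant digits."""
        fmt = f"%.{precision}g"
        out = io.StringIO()

        def write_node(node: int) -> None:
            kids = self._children[node]
            if kids:
                out.write("(")
                for i, c in enumerate(kids):
                    if i:
                        out.write(",")
                    write_node(c)
                out.write(")")
            if self.labels[node] is not None:
                out.write(_format_label(self.labels[node]))
            if self.parent[node] >= 0:
                out.write(":" + fmt % self.blen[node])

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10 * self.n_nodes + 100))
        try:
            write_node(self.root)
        finally:
            sys.setrecursionlimit(old)
        out.write(";")
        return out.getvalue()

    # --------------------------------------------------------------- distances

    def patristic_matrix(self) -> pd.DataFrame:
        """Symmetric tip-to-tip path-length matrix (zero diagonal)."""
        tips = self.tip_indices()
        tip_pos = {t: i for i, t in enumerate(tips)}
        labels = [self.labels[t] for t in tips]
        d = self.depths()
        n = len(tips)
        mat = np.zeros((n, n))
        below = self.tips_below()
        for node in self.postorder():
            kids = self._children[node]
            if len(kids) < 2:
                continue
            # tips in different child subtrees have this node as their LCA
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for ti in below[kids[a]]:
                        i = tip_pos[ti]
                        di = d[ti]
                        for tj in below[kids[b]]:
                            j = tip_pos[tj]
                            val = di + d[tj] - 2.0 * d[node]
                            mat[i, j] = val
                            mat[j, i] = val
        return pd.DataFrame(mat, index=labels, columns=labels)

    def shared_depth_matrix(self) -> pd.DataFrame:
        """Brownian-motion covariance structure: depth of the LCA per tip pair."""
        tips = self.tip_indices()
        tip_pos = {t: i for i, t in enumerate(tips)}
        labels = [self.labels[t] for t in tips]
        d = self.depths()
        n = len(tips)
        mat = np.zeros((n, n))
        for t in tips:
            mat[tip_pos[t], tip_pos[t]] = d[t]
        below = self.tips_below()
        for node in self.postorder():
            kids = self._children[node]
            if len(kids) < 2:
                continue
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for ti in below[kids[a]]:
                        i = tip_pos[ti]
                        for tj in below[kids[b]]:
                            j = tip_pos[tj]
                            mat[i, j] = d[node]
                            mat[j, i] = d[node]
        return pd.DataFrame(mat, index=labels, columns=labels)

    # ----------------------------------------------------------------- rooting

    def _undirected_edges(self) -> tuple[dict[int, list[tuple[int, float]]], list[str | None]]:
        """Adjacency of the unrooted version (old degree-2 root suppressed)."""
        adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(self.n_nodes)}
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                adj[i].append((int(p), float(self.blen[i])))
                adj[int(p)].append((i, float(self.blen[i])))
        kids = self._children[self.root]
        if len(kids) == 2:
            a, b = kids
            la, lb = float(self.blen[a]), float(self.blen[b])
            adj[a] = [(x, w) for x, w in adj[a] if x != self.root]
            adj[b] = [(x, w) for x, w in adj[b] if x != self.root]
            adj[a].append((b, la + lb))
            adj[b].append((a, la + lb))
            del adj[self.root]
        return adj, list(self.labels)

    def midpoint_root(self) -> "Phylogeny":
        """Root at the midpoint of the longest tip-to-tip path.

        Ties between equally long paths are broken by the lexicographically
        smallest (sorted) tip-label pair, so the result is deterministic.
        """
        if self.n_tips < 2:
            raise ValueError("midpoint rooting requires at least two tips")
        pm = self.patristic_matrix()
        arr = pm.values
        diameter = arr.max()
        if diameter <= 0:
            raise ValueError("zero-diameter tree cannot be midpoint rooted")
        pairs = [
            tuple(sorted((pm.index[i], pm.columns[j])))
            for i, j in zip(*np.nonzero(np.isclose(arr, diameter, rtol=0, atol=1e-12)))
            if i < j
        ]
        tip_a, tip_b = min(pairs)
        label_to_node = {self.labels[t]: t for t in self.tip_indices()}
        na, nb = label_to_node[tip_a], label_to_node[tip_b]

        adj, labels = self._undirected_edges()
        # BFS path na -> nb
        prev: dict[int, tuple[int, float]] = {na: (-1, 0.0)}
        queue = [na]
        while queue:
            u = queue.pop()
            if u == nb:
                break
            for v, w in adj[u]:
                if v not in prev:
                    prev[v] = (u, w)
                    queue.append(v)
        path = [nb]
        while path[-1] != na:
            path.append(prev[path[-1]][0])
        path.reverse()  # na ... nb
        # walk from na until half the diameter
        half = diameter / 2.0
        acc = 0.0
        for u, v in zip(path, path[1:]):
            w = next(wt for x, wt in adj[u] if x == v)
            if acc + w >= half - 1e-15:
                offset = half - acc  # distance from u along edge (u, v)
                return self._reroot_on_edge(adj, labels, u, v, w, offset)
            acc += w
        raise AssertionError("midpoint not found on diameter path")

    def _reroot_on_edge(self, adj, labels, u, v, w, offset) -> "Phylogeny":
        """Build a rooted tree with the root ``offset`` from ``u`` on edge (u, v)."""
        tol = 1e-12
        if offset <= tol or offset >= w - tol:
            anchor = u if offset <= tol else v
            return self._orient(adj, labels, root_old=anchor, new_root_edge=None)
        return self._orient(adj, labels, root_old=None, new_root_edge=(u, v, w, offset))

    def _orient(self, adj, labels, root_old, new_root_edge) -> "Phylogeny":
        old_n = self.n_nodes
        keep = sorted(adj.keys())
        remap = {old: i for i, old in enumerate(keep)}
        n_new = len(keep) + (1 if new_root_edge is not None else 0)
        parent = np.full(n_new, -1, dtype=np.int64)
        blen = np.zeros(n_new)
        new_labels: list[str | None] = [labels[old] for old in keep]
        if new_root_edge is not None:
            u, v, w, offset = new_root_edge
            root = n_new - 1
            new_labels.append(None)
            # detach edge (u, v), attach both to root
            visited = {u: (root, offset), v: (root, w - offset)}
            order = [u, v]
            queue = [u, v]
            banned = {(u, v), (v, u)}
        else:
            root = remap[root_old]
            visited = {root_old: (-1, 0.0)}
            order = [root_old]
            queue = [root_old]
            banned = set()
        while queue:
            x = queue.pop()
            for y, wt in adj[x]:
                if (x, y) in banned or y in visited:
                    continue
                visited[y] = (remap[x], wt)
                order.append(y)
                queue.append(y)
        for old in keep:
            p, wt = visited[old]
            parent[remap[old]] = p
            blen[remap[old]] = wt
        if new_root_edge is not None:
            parent[root] = -1
        return Phylogeny(parent, blen, new_labels, rooted=True, validate=False)

    # ------------------------------------------------------------- polytomies

    def resolve_polytomies(self, eps: float = 1e-6) -> "Phylogeny":
        """Return a strictly bifurcating copy.

        Multifurcations are resolved deterministically by repeatedly grouping
        the first two children (input order) under a new zero-length node;
        afterwards every zero-length branch (old or newly introduced) is set
        to ``eps``.
        """
        if not self.rooted:
            raise ValueError("polytomy resolution requires a rooted tree")
        parent = list(self.parent)
        blen = list(self.blen)
        labels = list(self.labels)
        children = [list(c) for c in self._children]
        stack = [i for i, c in enumerate(children) if len(c) > 2]
        while stack:
            node = stack.pop()
            while len(children[node]) > 2:
                a, b = children[node][0], children[node][1]
                new = len(parent)
                parent.append(node)
                blen.append(0.0)
                labels.append(None)
                children.append([a, b])
                parent[a] = new
                parent[b] = new
                children[node] = [new] + children[node][2:]
        root = parent.index(-1)
        blen = [
            (eps if (bl == 0.0 and i != root) else bl)
            for i, bl in enumerate(blen)
        ]
        out = Phylogeny(parent, blen, labels, rooted=True, validate=False)
        assert out.is_bifurcating()
        return out

    # ----------------------------------------------------------------- pruning

    def prune_to_taxa(self, keep: Iterable[str]) -> "Phylogeny":
        """Induced subtree on ``keep``; tip-to-tip path lengths are preserved."""
        keep = set(keep)
        known = set(self.tip_labels)
        unknown = sorted(keep - known)
        if unknown:
            raise KeyError(f"unknown tip labels: {', '.join(unknown)}")
        if len(keep) < 2:
            raise ValueError("need at least two tips to prune to")

        # (new-subtree, pendant-length) per node, bottom-up
        results: dict[int, tuple[dict, float]] = {}
        for node in self.postorder():
            if self.is_tip(node):
                if self.labels[node] in keep:
                    results[node] = ({"label": self.labels[node], "children": []},
                                     float(self.blen[node]))
                continue
            sub = [results[c] for c in self._children[node] if c in results]
            if not sub:
                continue
            if len(sub) == 1:
                child, pend = sub[0]
                results[node] = (child, pend + float(self.blen[node]))
            else:
                results[node] = (
                    {"label": self.labels[node], "children": sub},
                    float(self.blen[node]),
                )
        top, _ = results[self.root]
        while len(top["children"]) == 1:
            top = top["children"][0][0]

        parent: list[int] = []
        blen: list[float] = []
        labels: list[str | None] = []

        def build(rec: dict, parent_id: int, length: float) -> None:
            me = len(parent)
            parent.append(parent_id)
            blen.append(length)
            labels.append(rec["label"])
            for child, pend in rec["children"]:
                build(child, me, pend)

        build(top, -1, 0.0)
        return Phylogeny(parent, blen, labels, rooted=True, validate=False)


def read_newick(source: str) -> Phylogeny:
    """Read a tree from a Newick string or a ``.nwk`` file path."""
    text = source
    if "(" not in source and source.strip().endswith((".nwk", ".tre", ".newick", ".txt")):
        with open(source) as fh:
            text = fh.read()
    return Phylogeny.from_newick(text)
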