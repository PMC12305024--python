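"""Lightweight rooted phylogeny with branch lengths.

Array-backed node representation with Newick I/O (via dendropy), pruning,
shared-path (MRCA-time) matrices and ultrametricity checks — the substrate
for the regression and trait-evolution machinery.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


class TreeError(ValueError):
    pass


class Phylogeny:
    """Rooted tree; nodes indexed 0..n_nodes-1, root edge length 0."""

    def __init__(
        self,
        parent: list[int],
        edge_len: list[float],
        labels: list[str | None],
    ):
        self.parent = np.asarray(parent, dtype=int)
        self.edge_len = np.asarray(edge_len, dtype=float)
        self.labels = list(labels)
        n = len(self.parent)
        if not (len(self.edge_len) == len(self.labels) == n):
            raise TreeError("parent/edge_len/labels length mismatch")
        roots = np.where(self.parent < 0)[0]
        if len(roots) != 1:
            raise TreeError(f"expected exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            if i != self.root:
                self.children[self.parent[i]].append(i)
        if np.any(self.edge_len < 0):
            raise TreeError("negative branch length")
        tips = [i for i in range(n) if not self.children[i]]
        names = [self.labels[i] for i in tips]
        if any(nm is None for nm in names):
            raise TreeError("unlabeled tip")
        if len(set(names)) != len(names):
            raise TreeError("duplicate tip labels")
        self.tips = tips
        self._tip_of = {self.labels[i]: i for i in tips}
        # trees are immutable in practice; cache the expensive pairwise pieces
        self._cache: dict = {}

    # -- basic structure -------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tips]

    def tip_index(self, label: str) -> int:
        return self._tip_of[label]

    def preorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        return order

    def postorder(self) -> list[int]:
        return self.preorder()[::-1]

    def node_times(self) -> np.ndarray:
        """Time from the root to each node."""
        if "node_times" not in self._cache:
            t = np.zeros(self.n_nodes)
            for v in self.preorder():
                if v != self.root:
                    t[v] = t[self.parent[v]] + self.edge_len[v]
            self._cache["node_times"] = t
        return self._cache["node_times"]

    @property
    def depth(self) -> float:
        return float(self.node_times()[self.tips].max())

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        tt = self.node_times()[self.tips]
        return float(tt.max() - tt.min()) <= rtol * float(tt.max())

    # -- pairwise quantities --------------------------------------------

    def _ancestor_paths(self) -> dict[int, dict[int, float]]:
        """tip -> {ancestor node: time of that node}."""
        if "ancestor_paths" not in self._cache:
            times = self.node_times()
            out = {}
            for tip in self.tips:
                anc, v = {}, tip
                while v >= 0:
                    anc[v] = times[v]
                    v = self.parent[v] if v != self.root else -1
                out[tip] = anc
            self._cache["ancestor_paths"] = out
        return self._cache["ancestor_paths"]

    def mrca_nodes(self) -> np.ndarray:
        """Tip x tip matrix of MRCA node indices (tip order)."""
        if "mrca_nodes" not in self._cache:
            paths = self._ancestor_paths()
            times = self.node_times()
            n = self.n_tips
            M = np.zeros((n, n), dtype=int)
            for a in range(n):
                ta = self.tips[a]
                M[a, a] = ta
                for b in range(a + 1, n):
                    tb = self.tips[b]
                    shared = paths[ta].keys() & paths[tb].keys()
                    M[a, b] = M[b, a] = max(shared, key=lambda v: times[v])
            self._cache["mrca_nodes"] = M
        return self._cache["mrca_nodes"]

    def mrca_times(self, order: list[str] | None = None) -> np.ndarray:
        """Matrix of MRCA times from the root (diagonal = tip times)."""
        if "mrca_times" not in self._cache:
            times = self.node_times()
            self._cache["mrca_times"] = times[self.mrca_nodes()]
        M = self._cache["mrca_times"]
        if order is None or list(order) == self.tip_labels:
            return M
        pos = {lb: i for i, lb in enumerate(self.tip_labels)}
        idx = [pos[lb] for lb in order]
        return M[np.ix_(idx, idx)]

    def patristic(self, order: list[str] | None = None) -> np.ndarray:
        labels = order if order is not None else self.tip_labels
        M = self.mrca_times(labels)
        tt = np.diag(M)
        return tt[:, None] + tt[None, :] - 2.0 * M

    # -- editing ---------------------------------------------------------

    def prune(self, keep: list[str]) -> "Phylogeny":
        """Induced subtree on ``keep``; unary nodes collapsed, lengths summed."""
        unknown = sorted(set(keep) - set(self.tip_labels))
        if unknown:
            raise TreeError(f"unknown species: {unknown}")
        if len(set(keep)) < 2:
            raise TreeError("cannot prune to fewer than two tips")
        keep_set = {self.tip_index(lb) for lb in keep}
        retained = set(keep_set)
        n_desc = np.zeros(self.n_nodes, dtype=int)
        for v in self.postorder():
            if v in keep_set:
                n_desc[v] = 1
            else:
                n_desc[v] = sum(n_desc[c] for c in self.children[v])
            if n_desc[v] > 0:
                retained.add(v)
        # rebuild, collapsing nodes with one retained child
        parent, edge, labels = [], [], []
        index = {}

        def build(v: int, plen: float, pidx: int):
            kids = [c for c in self.children[v] if n_desc[c] > 0]
            if v not in keep_set and len(kids) == 1:
                build(kids[0], plen + self.edge_len[kids[0]], pidx)
                return
            idx = len(parent)
            index[v] = idx
            parent.append(pidx)
            edge.append(plen)
            labels.append(self.labels[v] if v in keep_set else None)
            for c in kids:
                build(c, self.edge_len[c], idx)

        # find the new root: deepest node ancestral to all kept tips
        v = self.root
        while True:
            kids = [c for c in self.children[v] if n_desc[c] > 0]
            if v in keep_set or len(kids) != 1:
                break
            v = kids[0]
        build(v, 0.0, -1)
        return Phylogeny(parent, edge, labels)

    def rescale(self, new_depth: float = 1.0) -> "Phylogeny":
        f = new_depth / self.depth
        return Phylogeny(self.parent.tolist(), (self.edge_len * f).tolist(), self.labels)

    # -- Newick ----------------------------------------------------------

    def to_newick(self) -> str:
        def rec(v: int) -> str:
            if not self.children[v]:
                body = self.labels[v]
            else:
                body = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
                if self.labels[v]:
                    body += self.labels[v]
            if v == self.root:
                return body
            return f"{body}:{float(self.edge_len[v])!r}"

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        import dendropy

        try:
            dt = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
        except Exception as exc:
            raise TreeError(f"Newick parse failure: {exc}") from exc
        parent, edge, labels = [], [], []
        index = {}
        for nd in dt.preorder_node_iter():
            idx = len(parent)
            index[nd] = idx
            if nd.parent_node is None:
                parent.append(-1)
                edge.append(0.0)
            else:
                if nd.edge.length is None:
                    raise TreeError("missing branch length")
                parent.append(index[nd.parent_node])
                edge.append(float(nd.edge.length))
            lbl = None
            if nd.taxon is not None:
                lbl = nd.taxon.label
            elif nd.label:
                lbl = nd.label
            labels.append(lbl)
        return cls(parent, edge, labels)


def read_newick(path: str | Path) -> Phylogeny:
    return Phylogeny.from_newick(Path(path).read_text())


def write_newick(tree: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
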