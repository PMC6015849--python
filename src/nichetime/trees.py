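"""Rooted phylogenies: Newick IO and an array-based container for fast numerics.

Newick parsing/writing is delegated to dendropy; all likelihood and simulation
code works on flat parent/child arrays in post-order, which is much faster than
object traversal for the repeated pruning passes the analyses need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["Phylogeny", "read_trees", "write_trees"]


class DuplicateTipError(ValueError):
    """Raised when a tree contains two tips with the same label."""


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths.

    Nodes are integers; tips are ``0 .. n_tips-1`` in the order of
    ``tip_labels``, internal nodes follow, the root is ``root``.
    ``parent[i]`` is the parent of node ``i`` (root has parent ``-1``) and
    ``edge_length[i]`` the length of the branch above node ``i``.
    """

    tip_labels: list[str]
    parent: np.ndarray
    edge_length: np.ndarray
    children: list[list[int]] = field(repr=False)
    root: int = 0

    # -- construction -----------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        leaves = [nd for nd in nodes if nd.is_leaf()]
        labels = [lf.taxon.label if lf.taxon is not None else str(id(lf)) for lf in leaves]
        if len(set(labels)) != len(labels):
            raise DuplicateTipError("duplicate tip labels in tree")
        n_tips = len(leaves)
        index = {}
        for i, lf in enumerate(leaves):
            index[id(lf)] = i
        k = n_tips
        for nd in nodes:
            if not nd.is_leaf():
                index[id(nd)] = k
                k += 1
        n = k
        parent = np.full(n, -1, dtype=np.int64)
        elen = np.zeros(n, dtype=float)
        children: list[list[int]] = [[] for _ in range(n)]
        for nd in nodes:
            i = index[id(nd)]
            if nd.edge.length is not None:
                if nd.edge.length < 0 or not np.isfinite(nd.edge.length):
                    raise ValueError("branch lengths must be finite and non-negative")
                elen[i] = float(nd.edge.length)
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                parent[i] = p
                children[p].append(i)
        root = index[id(tree.seed_node)]
        return cls(tip_labels=labels, parent=parent, edge_length=elen,
                   children=children, root=root)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick")
        except Exception as e:
            if "Multiple occurrences" in str(e) or "uplicate" in str(e):
                raise DuplicateTipError(str(e)) from e
            raise
        return cls.from_dendropy(tree)

    @classmethod
    def from_arrays(cls, tip_labels, parent, edge_length) -> "Phylogeny":
        parent = np.asarray(parent, dtype=np.int64)
        edge_length = np.asarray(edge_length, dtype=float)
        n = len(parent)
        children: list[list[int]] = [[] for _ in range(n)]
        root = -1
        for i, p in enumerate(parent):
            if p < 0:
                root = i
            else:
                children[p].append(i)
        if root < 0:
            raise ValueError("no root (node with parent -1) found")
        return cls(tip_labels=list(tip_labels), parent=parent,
                   edge_length=edge_length, children=children, root=root)

    # -- basic properties --------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def postorder(self) -> np.ndarray:
        """Node indices in post-order (children before parents)."""
        order = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            order.append(nd)
            stack.extend(self.children[nd])
        return np.asarray(order[::-1], dtype=np.int64)

    def node_depths(self) -> np.ndarray:
        """Distance from the root to each node."""
        depth = np.zeros(self.n_nodes)
        for nd in reversed(self.postorder()):  # preorder
            p = self.parent[nd]
            if p >= 0:
                depth[nd] = depth[p] + self.edge_length[nd]
        return depth

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        d = self.node_depths()[: self.n_tips]
        return bool(np.allclose(d, d.mean(), rtol=rtol, atol=rtol * max(d.mean(), 1.0)))

    def vcv(self) -> np.ndarray:
        """Brownian-motion covariance: shared root-to-MRCA path length per tip pair."""
        n = self.n_tips
        depth = self.node_depths()
        # tips under each node, accumulated post-order
        C = np.zeros((n, n))
        tipsets: dict[int, np.ndarray] = {}
        for nd in self.postorder():
            if nd < n:
                tipsets[nd] = np.array([nd])
            else:
                kids = [tipsets.pop(c) for c in self.children[nd]]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        C[np.ix_(kids[a], kids[b])] = depth[nd]
                        C[np.ix_(kids[b], kids[a])] = depth[nd]
                tipsets[nd] = np.concatenate(kids)
        C[np.diag_indices(n)] = depth[:n]
        return C

    def prune_to(self, keep: list[str]) -> "Phylogeny":
        """Subtree induced by the tip labels in ``keep`` (suppressing unifurcations)."""
        keep_set = set(keep)
        missing = keep_set - set(self.tip_labels)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        # count retained tips under each node
        n = self.n_nodes
        cnt = np.zeros(n, dtype=np.int64)
        po = self.postorder()
        for nd in po:
            if nd < self.n_tips:
                cnt[nd] = 1 if self.tip_labels[nd] in keep_set else 0
            else:
                cnt[nd] = sum(cnt[c] for c in self.children[nd])
        # rebuild: walk from root, skipping nodes with no retained tip and
        # collapsing unifurcating chains; remap so tips come first
        records: list[dict] = []

        def build2(nd: int, new_parent: int, acc_len: float) -> int:
            if nd < self.n_tips:
                records.append({"parent": new_parent, "len": acc_len,
                                "label": self.tip_labels[nd]})
                return len(records) - 1
            live = [c for c in self.children[nd] if cnt[c] > 0]
            if len(live) == 1:
                c = live[0]
                return build2(c, new_parent, acc_len + self.edge_length[c])
            records.append({"parent": new_parent, "len": acc_len, "label": None})
            me = len(records) - 1
            for c in live:
                build2(c, me, self.edge_length[c])
            return me

        build2(self.root, -1, 0.0)
        tip_idx = [i for i, r in enumerate(records) if r["label"] is not None]
        int_idx = [i for i, r in enumerate(records) if r["label"] is None]
        remap = {old: new for new, old in enumerate(tip_idx + int_idx)}
        labels = [records[i]["label"] for i in tip_idx]
        parent = np.array([remap[records[i]["parent"]] if records[i]["parent"] >= 0 else -1
                           for i in tip_idx + int_idx], dtype=np.int64)
        elen = np.array([records[i]["len"] for i in tip_idx + int_idx])
        return Phylogeny.from_arrays(labels, parent, elen)

    # -- IO ----------------------------------------------------------------
    def to_newick(self) -> str:
        def rec(nd: int) -> str:
            if nd < self.n_tips:
                core = self.tip_labels[nd].replace(" ", "_")
            else:
                core = "(" + ",".join(rec(c) for c in self.children[nd]) + ")"
            if self.parent[nd] >= 0:
                return f"{core}:{self.edge_length[nd]:.10g}"
            return core

        return rec(self.root) + ";"


def read_trees(path, species: list[str] | None = None) -> list[Phylogeny]:
    """Read one or more Newick trees from ``path``.

    When ``species`` is given, every tree's tip set must contain all of them.
    Raises on malformed Newick or duplicate tips.
    """
    try:
        tl = dendropy.TreeList.get(path=str(path), schema="newick")
    except Exception as e:
        if "Multiple occurrences" in str(e) or "uplicate" in str(e):
            raise DuplicateTipError(str(e)) from e
        raise
    trees = [Phylogeny.from_dendropy(t) for t in tl]
    if species is not None:
        want = set(species)
        for i, t in enumerate(trees):
            missing = want - set(t.tip_labels)
            if missing:
                raise KeyError(f"tree {i} lacks species: {sorted(missing)[:5]}")
    return trees


def write_trees(trees: list[Phylogeny], path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick() + "\n")
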