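"""Rooted phylogenies with branch durations in Ma and absolute node ages.

The central container is :class:`Phylogeny`, an array-backed rooted tree.
Edges carry durations in millions of years (Ma); absolute ages are "Ma
before present", so larger ages are older and every parent is at least as
old as its children.  Trees are parsed from and written to Newick via
dendropy, but all numerical work runs on flat arrays (parent pointers,
postorder index lists) so likelihood code never touches node objects.
"""

from __future__ import annotations

import io
from typing import Iterable

import dendropy
import numpy as np

__all__ = ["Phylogeny", "PhylogenyError", "read_newick", "write_newick"]


class PhylogenyError(ValueError):
    """Raised for structurally invalid trees or invalid tree operations."""


class Phylogeny:
    """Array-backed rooted tree.

    Nodes are indexed ``0 .. n_nodes-1`` in preorder with the root at 0.
    ``parent[i]`` is the parent index (-1 for the root) and
    ``edge_length[i]`` is the duration of the edge *above* node ``i``
    (``nan`` if absent, 0.0 convention for the root).

    Attributes
    ----------
    root_age:
        Absolute age of the root node in Ma before present, or ``None``
        for trees without a temporal anchor (e.g. bare cladograms).
    root_length:
        Duration of the stem edge hanging above the root (Ma). Used by
        time-scaling, never by likelihoods (no variance accrues above the
        root state).
    clades:
        Registry mapping clade labels (from internal node labels in the
        Newick, or registered programmatically) to node indices.
    """

    def __init__(
        self,
        parent: np.ndarray,
        edge_length: np.ndarray,
        tip_labels: dict[int, str],
        root_age: float | None = None,
        root_length: float = 0.0,
        clades: dict[str, int] | None = None,
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.edge_length = np.asarray(edge_length, dtype=float)
        self.n_nodes = len(self.parent)
        if self.parent[0] != -1 or np.any(self.parent[1:] >= np.arange(1, self.n_nodes)):
            raise PhylogenyError("nodes must be in preorder with root at index 0")
        self._children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(1, self.n_nodes):
            self._children[self.parent[i]].append(i)
        self.tip_labels = dict(tip_labels)
        labels = list(self.tip_labels.values())
        if len(set(labels)) != len(labels):
            raise PhylogenyError("duplicate tip labels")
        for i in range(self.n_nodes):
            if not self._children[i] and i not in self.tip_labels:
                raise PhylogenyError(f"leaf node {i} has no label")
        self.root_age = root_age
        self.root_length = float(root_length)
        self.clades = dict(clades or {})
        self._postorder: np.ndarray | None = None
        self._tips: np.ndarray | None = None

    # ------------------------------------------------------------------ basics

    def children(self, node: int) -> list[int]:
        return self._children[node]

    @property
    def tips(self) -> np.ndarray:
        """Tip node indices in preorder (the canonical trait-row order)."""
        if self._tips is None:
            self._tips = np.array(
                [i for i in range(self.n_nodes) if not self._children[i]], dtype=np.int64
            )
        return self._tips

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def tip_label_list(self) -> list[str]:
        return [self.tip_labels[i] for i in self.tips]

    @property
    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self._children)

    def postorder(self) -> np.ndarray:
        if self._postorder is None:
            order: list[int] = []
            stack = [0]
            while stack:
                node = stack.pop()
                order.append(node)
                stack.extend(self._children[node])
            self._postorder = np.array(order[::-1], dtype=np.int64)
        return self._postorder

    def copy(self) -> "Phylogeny":
        return Phylogeny(
            self.parent.copy(),
            self.edge_length.copy(),
            dict(self.tip_labels),
            self.root_age,
            self.root_length,
            dict(self.clades),
        )

    def tip_index(self, label: str) -> int:
        for i, lab in self.tip_labels.items():
            if lab == label:
                return i
        raise PhylogenyError(f"unknown taxon {label!r}")

    def subtree_nodes(self, node: int) -> np.ndarray:
        """All nodes in the subtree rooted at ``node`` (inclusive), preorder."""
        out = []
        stack = [node]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self._children[v])
        return np.array(sorted(out), dtype=np.int64)

    def subtree_tips(self, node: int) -> np.ndarray:
        sub = self.subtree_nodes(node)
        return sub[[len(self._children[v]) == 0 for v in sub]]

    def mrca(self, labels: Iterable[str]) -> int:
        nodes = {self.tip_index(lab) for lab in labels}
        if not nodes:
            raise PhylogenyError("mrca of empty taxon set")
        paths = []
        for v in nodes:
            path = [v]
            while self.parent[path[-1]] != -1:
                path.append(int(self.parent[path[-1]]))
            paths.append(set(path))
        common = set.intersection(*paths)
        return max(common, key=lambda v: self.depth_in_edges(v))

    def depth_in_edges(self, node: int) -> int:
        d = 0
        while self.parent[node] != -1:
            node = int(self.parent[node])
            d += 1
        return d

    # ------------------------------------------------------------ ages & depths

    @property
    def has_lengths(self) -> bool:
        return not np.any(np.isnan(self.edge_length[1:]))

    def node_depths(self) -> np.ndarray:
        """Root-to-node path durations (Ma)."""
        if not self.has_lengths:
            raise PhylogenyError("tree has no branch lengths")
        depth = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            depth[i] = depth[self.parent[i]] + self.edge_length[i]
        return depth

    def node_ages(self) -> np.ndarray:
        """Absolute ages (Ma before present); requires ``root_age``."""
        if self.root_age is None:
            raise PhylogenyError("tree has no root age anchor")
        return self.root_age - self.node_depths()

    def tip_dates(self) -> dict[str, float]:
        ages = self.node_ages()
        return {self.tip_labels[i]: float(ages[i]) for i in self.tips}

    # ------------------------------------------------------------ manipulation

    def set_edge_length(self, node: int, length: float) -> "Phylogeny":
        """Return a tree with the edge above ``node`` set to ``length`` (Ma).

        The edge grows (or shrinks) rootward: the focal node and its whole
        subtree keep their absolute ages, every node outside the subtree
        shifts older (younger) by the difference, and no other edge
        duration changes.  The root age therefore moves by the difference.
        """
        if node <= 0 or node >= self.n_nodes:
            raise PhylogenyError(f"edge above node {node} not found")
        if length < 0:
            raise PhylogenyError("edge duration must be >= 0")
        new = self.copy()
        delta = length - new.edge_length[node]
        new.edge_length[node] = length
        if new.root_age is not None:
            new.root_age += delta
        return new

    def register_clade(self, label: str, node: int) -> None:
        if len(self._children[node]) == 0:
            raise PhylogenyError("clade label must point at an internal node")
        self.clades[label] = node

    def prune_to_taxa(self, keep: Iterable[str]) -> "Phylogeny":
        """Induced subtree on ``keep``; suppressed degree-2 nodes have their
        edge durations summed, so retained root-to-tip paths (and node ages)
        are preserved. The new root is the MRCA of the retained taxa."""
        keep = list(keep)
        if len(set(keep)) < 2:
            raise PhylogenyError("prune requires at least two taxa")
        keep_idx = {self.tip_index(lab) for lab in keep}
        # count retained tips below every node
        counts = np.zeros(self.n_nodes, dtype=int)
        for i in self.postorder():
            if not self._children[i]:
                counts[i] = 1 if i in keep_idx else 0
            else:
                counts[i] = sum(counts[c] for c in self._children[i])
        # new root: deepest node containing all retained tips
        new_root = 0
        while True:
            cand = [c for c in self._children[new_root] if counts[c] == len(keep_idx)]
            if not cand:
                break
            new_root = cand[0]

        node_map: dict[int, int] = {}
        parent_list: list[int] = []
        elen_list: list[float] = []
        labels: dict[int, str] = {}

        def visit(old: int, new_parent: int, carried: float) -> None:
            kids = [c for c in self._children[old] if counts[c] > 0]
            is_tip = not self._children[old]
            edge = 0.0 if old == new_root else (self.edge_length[old] if not np.isnan(self.edge_length[old]) else np.nan)
            if old != new_root and len(kids) == 1 and not is_tip:
                # suppress degree-2 node: carry its duration downward
                visit(kids[0], new_parent, carried + edge)
                return
            idx = len(parent_list)
            parent_list.append(new_parent)
            elen_list.append(np.nan if old == new_root else carried + edge)
            node_map[old] = idx
            if is_tip:
                labels[idx] = self.tip_labels[old]
            for c in kids:
                visit(c, idx, 0.0)

        visit(new_root, -1, 0.0)
        elen = np.array(elen_list)
        elen[0] = np.nan
        root_age = None
        if self.root_age is not None and self.has_lengths:
            root_age = float(self.node_ages()[new_root])
        clades = {}
        for lab, nd in self.clades.items():
            if nd in node_map and len(self._children[nd]) > 0:
                clades[lab] = node_map[nd]
        return Phylogeny(np.array(parent_list), elen, labels, root_age, 0.0, clades)

    # ------------------------------------------------------------------ newick

    def to_newick(self, decimals: int = 8) -> str:
        def fmt(x: float) -> str:
            return f"{x:.{decimals}f}".rstrip("0").rstrip(".")

        def rec(node: int) -> str:
            if not self._children[node]:
                s = _quote(self.tip_labels[node])
            else:
                inner = ",".join(rec(c) for c in self._children[node])
                lab = ""
                for name, nd in self.clades.items():
                    if nd == node:
                        lab = _quote(name)
                        break
                s = f"({inner}){lab}"
            if node != 0 and not np.isnan(self.edge_length[node]):
                s += f":{fmt(self.edge_length[node])}"
            if node == 0 and self.root_length:
                s += f":{fmt(self.root_length)}"
            return s

        return rec(0) + ";"


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def read_newick(text: str, root_age: float | None = None) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Internal node labels populate the clade registry; a branch length on
    the root is kept as the root stem length. ``root_age`` optionally
    anchors absolute ages (Ma before present).
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise PhylogenyError(f"Newick parse failure: {exc}") from exc

    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.empty(len(nodes), dtype=np.int64)
    elen = np.full(len(nodes), np.nan)
    labels: dict[int, str] = {}
    clades: dict[str, int] = {}
    root_length = 0.0
    for i, nd in enumerate(nodes):
        parent[i] = -1 if nd.parent_node is None else index[id(nd.parent_node)]
        if nd.edge.length is not None:
            if parent[i] == -1:
                root_length = float(nd.edge.length)
            else:
                elen[i] = float(nd.edge.length)
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise PhylogenyError("unlabeled tip")
            labels[i] = nd.taxon.label
        elif nd.label:
            clades[nd.label] = i
    n_lab = len(labels)
    if len({v for v in labels.values()}) != n_lab:
        raise PhylogenyError("duplicate tip labels")
    have = ~np.isnan(elen[1:])
    if have.any() and not have.all():
        raise PhylogenyError("branch lengths must be present on all edges or none")
    return Phylogeny(parent, elen, labels, root_age, root_length, clades)


def write_newick(tree: Phylogeny, path: str | io.TextIOBase | None = None) -> str:
    text = tree.to_newick()
    if path is not None:
        if hasattr(path, "write"):
            path.write(text + "\n")
        else:
            with open(path, "w") as fh:
                fh.write(text + "\n")
    return text
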