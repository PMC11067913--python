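"""Rooted, dated, binary phylogenies in a flat post-order layout.

Likelihood pruning, ancestral-state passes and forward simulation all walk
the tree in post- or pre-order over contiguous node ids, so the tree is
stored as parallel arrays indexed by a stable post-order id (children
always precede parents; the root is the last id).  Parsing and Newick
serialisation are delegated to dendropy.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import dendropy

__all__ = ["Phylogeny", "PolytomyError"]


class PolytomyError(ValueError):
    """Raised when a tree is not strictly binary."""


class Phylogeny:
    """A rooted binary tree with branch lengths in Myr.

    Attributes
    ----------
    children : list of (int, int) or None
        Child ids per node; None for tips.
    lengths : list of float
        Branch length above each node (0.0 for the root).
    labels : list of str or None
        Tip labels; None for unlabelled internal nodes.
    """

    def __init__(
        self,
        children: Sequence[Optional[Tuple[int, int]]],
        lengths: Sequence[float],
        labels: Sequence[Optional[str]],
    ):
        n = len(children)
        if not (len(lengths) == len(labels) == n):
            raise ValueError("children, lengths and labels must have equal length")
        for i, ch in enumerate(children):
            if ch is not None:
                if len(ch) != 2:
                    raise PolytomyError(
                        f"node {i} has {len(ch)} children; the tree must be binary"
                    )
                if not all(0 <= c < i for c in ch):
                    raise ValueError("children must precede parents in post-order")
        for i, t in enumerate(lengths):
            if t is None or t < 0:
                raise ValueError(f"node {i} has invalid branch length {t!r}")
        self.children: List[Optional[Tuple[int, int]]] = list(children)
        self.lengths: List[float] = [float(t) for t in lengths]
        self.labels: List[Optional[str]] = list(labels)
        tip_labels = [l for l, ch in zip(labels, children) if ch is None]
        if any(l is None for l in tip_labels):
            raise ValueError("every tip must be labelled")
        if len(set(tip_labels)) != len(tip_labels):
            dupes = sorted({l for l in tip_labels if tip_labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        self.tip_ids: Dict[str, int] = {
            l: i for i, (l, ch) in enumerate(zip(labels, children)) if ch is None
        }
        self.parent: List[Optional[int]] = [None] * n
        for i, ch in enumerate(self.children):
            if ch is not None:
                for c in ch:
                    self.parent[c] = i

    # -- basic queries ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def is_tip(self, node: int) -> bool:
        return self.children[node] is None

    def internal_ids(self) -> List[int]:
        return [i for i in range(self.n_nodes) if self.children[i] is not None]

    def tip_labels(self) -> List[str]:
        return [self.labels[i] for i in range(self.n_nodes) if self.is_tip(i)]

    def subtree_tips(self, node: int) -> List[str]:
        """Labels of all tips descending from (and including) *node*."""
        out: List[str] = []
        stack = [node]
        while stack:
            v = stack.pop()
            ch = self.children[v]
            if ch is None:
                out.append(self.labels[v])
            else:
                stack.extend(ch)
        return out

    def mrca(self, taxa: Sequence[str]) -> int:
        """Post-order id of the most recent common ancestor of the tips."""
        if len(taxa) < 2:
            raise ValueError("an MRCA needs at least two tip names")
        missing = [t for t in taxa if t not in self.tip_ids]
        if missing:
            raise KeyError(f"taxa not in tree: {missing}")
        n_marked = [0] * self.n_nodes
        for t in taxa:
            n_marked[self.tip_ids[t]] = 1
        target = len(set(taxa))
        for i in range(self.n_nodes):
            ch = self.children[i]
            if ch is not None:
                n_marked[i] = n_marked[ch[0]] + n_marked[ch[1]]
            if n_marked[i] == target:
                return i
        raise RuntimeError("unreachable: root contains all tips")

    def mrca_signature(self, node: int) -> Tuple[str, ...]:
        """A portable node address: two tips whose MRCA is this node
        (or the single tip label for a tip)."""
        ch = self.children[node]
        if ch is None:
            return (self.labels[node],)
        return (self.subtree_tips(ch[0])[0], self.subtree_tips(ch[1])[0])

    def node_depths(self) -> List[float]:
        """Time from the root to each node (root at 0)."""
        depth = [0.0] * self.n_nodes
        for i in range(self.n_nodes - 1, -1, -1):
            ch = self.children[i]
            if ch is not None:
                for c in ch:
                    depth[c] = depth[i] + self.lengths[c]
        return depth

    # -- Newick interop ---------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        children: List[Optional[Tuple[int, int]]] = []
        lengths: List[float] = []
        labels: List[Optional[str]] = []
        ids: Dict[dendropy.Node, int] = {}
        for node in tree.postorder_node_iter():
            kids = node.child_nodes()
            if kids:
                if len(kids) != 2:
                    raise PolytomyError(
                        f"internal node with {len(kids)} children; "
                        "only strictly binary trees are supported"
                    )
                children.append((ids[kids[0]], ids[kids[1]]))
                labels.append(node.taxon.label if node.taxon else None)
            else:
                children.append(None)
                if node.taxon is None or not node.taxon.label:
                    raise ValueError("unlabelled tip in tree")
                labels.append(node.taxon.label)
            if node.parent_node is None:
                lengths.append(node.edge.length or 0.0)
            else:
                if node.edge.length is None:
                    raise ValueError(
                        f"missing branch length above "
                        f"{labels[-1] or 'an internal node'}"
                    )
                lengths.append(float(node.edge.length))
            ids[node] = len(children) - 1
        return cls(children, lengths, labels)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except dendropy.utility.error.DataParseError as exc:
            if "duplicate" in str(exc).lower() or "same taxa" in str(exc).lower():
                raise ValueError(f"duplicate tip labels in Newick: {exc}") from exc
            raise ValueError(f"malformed Newick: {exc}") from exc
        return cls.from_dendropy(tree)

    def to_newick(self) -> str:
        parts: List[str] = [""] * self.n_nodes
        for i in range(self.n_nodes):
            ch = self.children[i]
            if ch is None:
                parts[i] = f"{self.labels[i]}:{self.lengths[i]:.10g}"
            else:
                inner = f"({parts[ch[0]]},{parts[ch[1]]})"
                if i == self.root:
                    parts[i] = inner
                else:
                    parts[i] = f"{inner}:{self.lengths[i]:.10g}"
        return parts[self.root] + ";"
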