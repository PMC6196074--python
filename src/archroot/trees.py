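"""Rooted phylogenetic trees: a light mutable structure with Newick I/O.

The MCMC kernels re-root and rescale trees millions of times, so the tree is
kept as a plain linked structure of ``Node`` objects rather than a heavier
library object.  Newick parsing is delegated to :mod:`dendropy`; only the
(trivial) writer is local.
"""

from __future__ import annotations

from typing import Iterator, Optional

import dendropy

__all__ = ["Node", "PhyloTree", "parse_newick", "write_newick"]


class Node:
    """A tree node; leaves carry a ``label``, edges a ``length`` to the parent."""

    __slots__ = ("parent", "children", "length", "label", "index")

    def __init__(self, label: Optional[str] = None, length: float = 0.0):
        self.parent: Optional[Node] = None
        self.children: list[Node] = []
        self.length: float = length
        self.label: Optional[str] = label
        self.index: int = -1  # assigned by PhyloTree.reindex()

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, len={self.length:g}, deg={len(self.children)})"


class PhyloTree:
    """A rooted tree over uniquely labelled leaves.

    ``rooted=False`` marks trees whose root is a basal multifurcation used
    only as a traversal anchor (the usual unrooted convention).
    """

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        self.reindex()
        labels = [lf.label for lf in self.leaves()]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels in tree")
        if any(lb is None for lb in labels):
            raise ValueError("unlabelled leaf in tree")

    # ------------------------------------------------------------------ basics
    def reindex(self) -> None:
        """Assign postorder indices (leaves and internals interleaved)."""
        for i, nd in enumerate(self.postorder()):
            nd.index = i

    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            nd, done = stack.pop()
            if done:
                yield nd
            else:
                stack.append((nd, True))
                for ch in reversed(nd.children):
                    stack.append((ch, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def leaves(self) -> list[Node]:
        return [nd for nd in self.postorder() if nd.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.label for lf in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    def edges(self) -> list[Node]:
        """Every non-root node stands for the edge to its parent."""
        return [nd for nd in self.postorder() if nd.parent is not None]

    def copy(self) -> "PhyloTree":
        def clone(nd: Node) -> Node:
            c = Node(nd.label, nd.length)
            for ch in nd.children:
                c.add_child(clone(ch))
            return c

        return PhyloTree(clone(self.root), rooted=self.rooted)

    # ------------------------------------------------------------- tree shape
    def validate_lengths(self) -> None:
        for nd in self.edges():
            if nd.length < 0:
                raise ValueError(f"negative branch length on edge above {nd.label or nd.index}")

    def node_depths(self) -> dict[Node, float]:
        depth: dict[Node, float] = {self.root: 0.0}
        for nd in self.preorder():
            if nd.parent is not None:
                depth[nd] = depth[nd.parent] + nd.length
        return depth

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        depth = self.node_depths()
        tips = [depth[lf] for lf in self.leaves()]
        return max(tips) - min(tips) <= tol * max(1.0, max(tips))

    def clade_leafsets(self, nontrivial: bool = True) -> list[frozenset[str]]:
        """Leaf-label set below every node (rooted clades)."""
        below: dict[Node, frozenset[str]] = {}
        out = []
        for nd in self.postorder():
            if nd.is_leaf:
                below[nd] = frozenset([nd.label])
            else:
                below[nd] = frozenset().union(*(below[c] for c in nd.children))
            if not nontrivial or (len(below[nd]) > 1 and nd.parent is not None):
                out.append(below[nd])
        return out

    def bipartitions(self, nontrivial: bool = True) -> set[frozenset[str]]:
        """Unrooted splits, each encoded as the side not containing the first taxon."""
        all_taxa = frozenset(self.leaf_labels)
        anchor = min(all_taxa)
        splits: set[frozenset[str]] = set()
        for cl in self.clade_leafsets(nontrivial=False):
            side = all_taxa - cl if anchor in cl else cl
            if nontrivial and not (1 < len(side) < len(all_taxa) - 1):
                continue
            if 0 < len(side) < len(all_taxa):
                splits.add(side)
        return splits

    def root_split(self) -> frozenset[str]:
        """The split induced by the root edge, encoded as in :meth:`bipartitions`."""
        if len(self.root.children) != 2:
            raise ValueError("root_split requires a bifurcating root")
        all_taxa = frozenset(self.leaf_labels)
        anchor = min(all_taxa)
        side = frozenset(lf.label for lf in _subtree_leaves(self.root.children[0]))
        return all_taxa - side if anchor in side else side

    def find_edge_by_clade(self, taxa: frozenset[str]) -> Optional[Node]:
        """The edge whose below-set is exactly ``taxa`` (or its complement)."""
        all_taxa = frozenset(self.leaf_labels)
        comp = all_taxa - taxa
        below: dict[Node, frozenset[str]] = {}
        for nd in self.postorder():
            if nd.is_leaf:
                below[nd] = frozenset([nd.label])
            else:
                below[nd] = frozenset().union(*(below[c] for c in nd.children))
            if nd.parent is not None and (below[nd] == taxa or below[nd] == comp):
                return nd
        return None

    # -------------------------------------------------------------- rerooting
    def rerooted(self, edge_child: Node, frac: float = 0.5) -> "PhyloTree":
        """A new tree rooted on the edge above ``edge_child``.

        ``frac`` is the fraction of the edge length between the child
        (frac=0) and its old parent (frac=1).  The old (degree-2) root is
        suppressed.  ``edge_child`` must belong to *this* tree.
        """
        if edge_child.parent is None:
            raise ValueError("cannot root on the root itself")
        if not 0.0 <= frac <= 1.0:
            raise ValueError("frac must lie in [0, 1]")

        # Work on a copy so the original tree is untouched.
        cp = self.copy()
        target = _matching_node(self, cp, edge_child)

        old_parent = target.parent
        old_parent.children.remove(target)
        target.parent = None

        new_root = Node()
        lo = target.length * frac
        hi = target.length * (1.0 - frac)
        new_root.add_child(target)
        target.length = lo

        # Reverse parent pointers from old_parent up to the old root.
        prev = new_root
        prev_len = hi
        nd = old_parent
        while nd is not None:
            parent = nd.parent
            up_len = nd.length
            if parent is not None:
                parent.children.remove(nd)
            nd.parent = None
            prev.add_child(nd)
            nd.length = prev_len
            prev, prev_len, nd = nd, up_len, parent

        _suppress_unifurcations(new_root)
        return PhyloTree(new_root, rooted=True)


def _subtree_leaves(nd: Node) -> list[Node]:
    out, stack = [], [nd]
    while stack:
        x = stack.pop()
        if x.is_leaf:
            out.append(x)
        else:
            stack.extend(x.children)
    return out


def _matching_node(src: PhyloTree, dst: PhyloTree, node: Node) -> Node:
    """Find the node in ``dst`` (a copy of ``src``) corresponding to ``node``."""
    src_order = list(src.postorder())
    dst_order = list(dst.postorder())
    return dst_order[src_order.index(node)]


def _suppress_unifurcations(root: Node) -> None:
    """Splice out internal degree-2 nodes (other than the root) in place."""
    stack = [root]
    while stack:
        nd = stack.pop()
        while len(nd.children) == 1 and nd.parent is not None:
            (only,) = nd.children
            only.length += nd.length
            only.parent = nd.parent
            i = nd.parent.children.index(nd)
            nd.parent.children[i] = only
            nd = only
        stack.extend(nd.children)


# ------------------------------------------------------------------- Newick IO
def parse_newick(source: str, rooted: Optional[bool] = None) -> PhyloTree:
    """Parse a Newick string (or the contents of a file) into a PhyloTree."""
    try:
        dt = dendropy.Tree.get(data=source, schema="newick", preserve_underscores=True)
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
        raise ValueError(f"duplicate leaf labels in tree: {e}") from None
    root = _from_dendropy(dt.seed_node)
    if rooted is None:
        rooted = len(root.children) == 2
    return PhyloTree(root, rooted=rooted)


def _from_dendropy(dnode) -> Node:
    nd = Node(
        label=dnode.taxon.label if dnode.taxon is not None else None,
        length=dnode.edge.length if dnode.edge.length is not None else 0.0,
    )
    for ch in dnode.child_nodes():
        nd.add_child(_from_dendropy(ch))
    return nd


def write_newick(tree: PhyloTree, lengths: bool = True, fmt: str = "%.10g") -> str:
    def rec(nd: Node) -> str:
        if nd.is_leaf:
            s = nd.label
        else:
            s = "(" + ",".join(rec(c) for c in nd.children) + ")"
        if lengths and nd.parent is not None:
            s += ":" + (fmt % nd.length)
        return s

    return rec(tree.root) + ";"
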