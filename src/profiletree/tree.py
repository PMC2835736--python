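"""Unrooted phylogenetic trees stored with a trifurcation at the top.

The tree is kept in a rooted data structure whose top node has exactly three
children and carries no branch length; every other node has a branch length
to its parent.  The placement of the trifurcation is arbitrary and does not
affect any likelihood or distance computed from the tree.  A fully resolved
tree on N leaves stored this way has N-2 internal nodes (including the top)
and N-3 nontrivial splits.
"""

from __future__ import annotations

import itertools
from typing import Iterator, Optional

_node_counter = itertools.count()


class Node:
    """A tree node.  Leaves have a name and no children."""

    __slots__ = (
        "id", "name", "children", "parent", "length",
        "profile", "partial", "support",
    )

    def __init__(self, name: Optional[str] = None, length: Optional[float] = None):
        self.id = next(_node_counter)
        self.name = name
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.length = length
        self.profile = None   # Profile of the subtree below (ME phase)
        self.partial = None   # PartialLikelihood below (ML phase)
        self.support = None   # SH-like local support of the parent edge

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def sibling(self) -> "Node":
        """The other child of a bifurcating parent (parent must have 2 children)."""
        sibs = [c for c in self.parent.children if c is not self]
        if len(sibs) != 1:
            raise ValueError("sibling() requires a bifurcating parent")
        return sibs[0]

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.id} {self.name or 'internal'}>"


class Tree:
    """Unrooted tree with a top trifurcation (or a plain top node for N<3)."""

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------ walks

    def postorder(self) -> Iterator[Node]:
        """Children before parents; iterative to spare the recursion limit."""
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def internal_edge_nodes(self) -> list[Node]:
        """Child endpoints of internal edges: non-top internal nodes, postorder."""
        return [n for n in self.postorder()
                if not n.is_leaf and n.parent is not None]

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self.postorder() if n.is_leaf)

    # ------------------------------------------------------------------ splits

    def splits(self) -> set[frozenset]:
        """Nontrivial splits as canonical frozensets of leaf names.

        Each internal edge induces a bipartition; the side not containing a
        fixed reference leaf (the lexicographic minimum) is the canonical
        representative, so rooting and rotation do not matter.
        """
        all_names = frozenset(self.leaf_names())
        ref = min(all_names)
        below: dict[int, frozenset] = {}
        out: set[frozenset] = set()
        for node in self.postorder():
            if node.is_leaf:
                below[node.id] = frozenset((node.name,))
                continue
            side = frozenset().union(*(below[c.id] for c in node.children))
            below[node.id] = side
            if node.parent is None:
                continue
            if len(side) < 2 or len(all_names) - len(side) < 2:
                continue  # trivial
            out.add(side if ref not in side else all_names - side)
        return out

    # ------------------------------------------------------------------ edits

    def copy(self) -> "Tree":
        """Structural copy (topology, names, lengths); caches are not copied."""
        def rec(node: Node) -> Node:
            n = Node(node.name, node.length)
            for c in node.children:
                n.add(rec(c))
            return n
        return Tree(rec(self.root))

    @staticmethod
    def swap_subtrees(b: Node, c: Node) -> None:
        """Exchange two subtrees (used for NNIs).  Lengths travel with them."""
        pb, pc = b.parent, c.parent
        ib, ic = pb.children.index(b), pc.children.index(c)
        pb.children[ib], pc.children[ic] = c, b
        b.parent, c.parent = pc, pb

    def reroot_at(self, new_top: Node) -> None:
        """Move the top trifurcation to another internal node."""
        if new_top.is_leaf:
            raise ValueError("cannot place the trifurcation at a leaf")
        if new_top is self.root:
            return
        path = [new_top]
        while path[-1].parent is not None:
            path.append(path[-1].parent)
        # Reverse parent/child links along the path; each edge keeps its
        # length (captured up front because the loop overwrites them).
        edge_lens = [n.length for n in path[:-1]]
        for (lower, upper), edge_len in zip(zip(path, path[1:]), edge_lens):
            upper.children.remove(lower)
            lower.children.append(upper)
            upper.parent = lower
            upper.length = edge_len
        new_top.parent = None
        new_top.length = None
        self.root = new_top

    def detach(self, node: Node) -> Node:
        """Prune `node` (with its subtree); its parent is spliced out.

        The parent must not be the top node (re-hang the tree first if so).
        """
        parent = node.parent
        if parent is None or parent.parent is None:
            raise ValueError("detach requires a grandparent; reroot first")
        other = node.sibling()
        grand = parent.parent
        other.length += parent.length
        grand.children[grand.children.index(parent)] = other
        other.parent = grand
        node.parent = None
        return node

    def regraft(self, node: Node, edge_child: Node) -> Node:
        """Attach `node` to the middle of the edge above `edge_child`."""
        upper = edge_child.parent
        mid = Node(length=edge_child.length / 2.0)
        edge_child.length /= 2.0
        upper.children[upper.children.index(edge_child)] = mid
        mid.parent = upper
        mid.add(edge_child)
        mid.add(node)
        return mid

    def check(self) -> None:
        """Structural sanity: arity, parent pointers, lengths present."""
        assert self.root.parent is None and self.root.length is None
        for n in self.postorder():
            for c in n.children:
                assert c.parent is n
            if n is self.root:
                assert len(n.children) == 3 or self.n_leaves < 3
            elif not n.is_leaf:
                assert len(n.children) == 2, "internal nodes are bifurcating"
            if n is not self.root:
                assert n.length is not None and n.length >= 0.0


def collapse_root_bifurcation(root: Node) -> Node:
    """Turn a degree-2 rooted tree into the trifurcation convention.

    The two root edges are merged into one; the trifurcation lands on
    whichever root child is internal.
    """
    if len(root.children) != 2:
        return root
    c1, c2 = root.children
    keep, move = (c1, c2) if not c1.is_leaf else (c2, c1)
    if keep.is_leaf:
        raise ValueError("cannot unroot a two-leaf tree")
    move.length = (move.length or 0.0) + (keep.length or 0.0)
    keep.add(move)
    keep.parent = None
    keep.length = None
    return keep
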