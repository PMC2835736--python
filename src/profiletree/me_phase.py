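"""Minimum-evolution phase: profile neighbor joining, NNIs, "linear" SPRs.

The starting tree comes from a profile-based variant of neighbor joining:
join selection uses the classical Q criterion on *uncorrected* profile
dissimilarities, and a joined pair is replaced by the unweighted average of
its profiles rather than by reduced distances.  The topology is then
improved by sweeps of nearest-neighbor interchanges and two rounds of
restricted ("linear") subtree-pruning-regrafting moves, both scored by an
estimated change in total tree length computed from log-corrected profile
distances.

For an NNI around an internal edge with the four adjacent subtrees A, B
(together) and C, D (together), the length change of switching to (A,C|B,D)
is estimated as ``(d(A,C) + d(B,D) - d(A,B) - d(C,D)) / 2`` with
log-corrected profile distances; an SPR move is treated as a chain of such
NNIs and scored by the sum of the per-step estimates.
"""

from __future__ import annotations

import math
from typing import Callable, Optional

import numpy as np

from . import profile_core as pc
from .msa_io import Alignment
from .tree import Node, Tree


class MeEngine:
    """Profile-distance context for one alignment."""

    def __init__(self, aln: Alignment):
        self.aln = aln
        self.alphabet = aln.alphabet
        self.letters = aln.letters
        self.D = pc.dissimilarity_matrix(aln.alphabet)
        self._up_cache: dict[int, pc.Profile] = {}

    # distances ------------------------------------------------------------
    def raw(self, p1: pc.Profile, p2: pc.Profile) -> float:
        return pc.profile_dissimilarity(p1, p2, self.D)

    def corrected(self, p1: pc.Profile, p2: pc.Profile) -> float:
        return pc.log_correct(self.raw(p1, p2), self.alphabet)

    # profiles -------------------------------------------------------------
    def assign_leaf_profiles(self, tree: Tree) -> None:
        rows = dict(zip(self.aln.names, self.aln.rows))
        for leaf in tree.leaves():
            leaf.profile = pc.leaf_profile(rows[leaf.name], self.letters)

    def recompute_profiles(self, tree: Tree) -> None:
        for node in tree.postorder():
            if not node.is_leaf:
                node.profile = pc.average_profiles(*(c.profile for c in node.children[:2]))
                for extra in node.children[2:]:
                    node.profile = pc.average_profiles(node.profile, extra.profile)
        self._up_cache.clear()

    def refresh_path_to_root(self, node: Node) -> None:
        """Recompute profiles on the path node -> root after a local change."""
        while node is not None:
            if not node.is_leaf:
                node.profile = pc.average_profiles(*(c.profile for c in node.children[:2]))
                for extra in node.children[2:]:
                    node.profile = pc.average_profiles(node.profile, extra.profile)
            node = node.parent
        self._up_cache.clear()

    def up_profile(self, node: Node) -> pc.Profile:
        """Profile of everything outside `node`'s subtree."""
        cached = self._up_cache.get(node.id)
        if cached is not None:
            return cached
        parent = node.parent
        others = [c for c in parent.children if c is not node]
        if parent.parent is None:
            prof = pc.average_profiles(others[0].profile, others[1].profile)
            for extra in others[2:]:
                prof = pc.average_profiles(prof, extra.profile)
        else:
            prof = pc.average_profiles(self.up_profile(parent), others[0].profile)
        self._up_cache[node.id] = prof
        return prof

    def away_profile(self, node: Node, toward: Node) -> pc.Profile:
        """Profile of the component containing `toward` when the edge
        between `node` and `toward` is removed."""
        if toward.parent is node:
            return toward.profile
        if node.parent is toward:
            return self.up_profile(node)
        raise ValueError("nodes are not adjacent")


# --------------------------------------------------------------------------
# Neighbor joining

def _nj_loop(nodes: list[Node], dmat: np.ndarray,
             new_distance: Callable[[Node, Node, Node, list[Node], np.ndarray, int, int], np.ndarray],
             ) -> Tree:
    """Classical NJ selection/length machinery on an explicit matrix.

    `new_distance(joined, i_node, j_node, nodes, dmat, i, j)` returns the
    distance row from the freshly joined node to every remaining node.
    """
    nodes = list(nodes)
    D = np.array(dmat, float)
    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        joined = Node()
        a, b = nodes[i], nodes[j]
        a.length = max(li, 0.0)
        b.length = max(lj, 0.0)
        joined.add(a)
        joined.add(b)
        row = new_distance(joined, a, b, nodes, D, i, j)
        # replace slot i by the joined node, drop slot j
        nodes[i] = joined
        D[i, :] = row
        D[:, i] = row
        D[i, i] = 0.0
        nodes.pop(j)
        D = np.delete(np.delete(D, j, axis=0), j, axis=1)
    root = Node()
    if len(nodes) == 3:
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        lens = [(d01 + d02 - d12) / 2.0, (d01 + d12 - d02) / 2.0,
                (d02 + d12 - d01) / 2.0]
        for node, ln in zip(nodes, lens):
            node.length = max(ln, 0.0)
            root.add(node)
    else:  # pragma: no cover - guarded by callers
        raise ValueError("neighbor joining needs at least 3 taxa")
    return Tree(root)


def nj_tree_from_distances(D, names: list[str]) -> Tree:
    """Classical neighbor joining on a plain distance matrix.

    Distance reduction follows Studier-Keppler:
    d(u,k) = (d(i,k) + d(j,k) - d(i,j)) / 2.
    """
    if len(names) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    leaves = [Node(name) for name in names]

    def reduce_row(joined, a, b, nodes, dm, i, j):
        return 0.5 * (dm[i, :] + dm[j, :] - dm[i, j])

    return _nj_loop(leaves, np.asarray(D, float), reduce_row)


def nj_start_tree(aln: Alignment, engine: Optional[MeEngine] = None) -> Tree:
    """Profile neighbor joining: Q on uncorrected dissimilarities,
    joined pairs replaced by their unweighted average profile."""
    if aln.n < 3:
        raise ValueError("tree inference needs at least 3 sequences")
    engine = engine or MeEngine(aln)
    leaves = [Node(name) for name in aln.names]
    for leaf, row in zip(leaves, aln.rows):
        leaf.profile = pc.leaf_profile(row, engine.letters)
    n = len(leaves)
    D0 = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D0[i, j] = D0[j, i] = engine.raw(leaves[i].profile, leaves[j].profile)

    def profile_row(joined, a, b, nodes, dm, i, j):
        joined.profile = pc.average_profiles(a.profile, b.profile)
        row = np.empty(len(nodes))
        for k, other in enumerate(nodes):
            row[k] = 0.0 if k == i else engine.raw(joined.profile, other.profile)
        return row

    tree = _nj_loop(leaves, D0, profile_row)
    engine.recompute_profiles(tree)
    return tree


# --------------------------------------------------------------------------
# NNIs

ARRANGEMENTS = ("current", "AC|BD", "AD|BC")


def nni_delta_me(pA: pc.Profile, pB: pc.Profile, pC: pc.Profile, pD: pc.Profile,
                 engine: MeEngine) -> tuple[str, float]:
    """Best arrangement of the quartet and its estimated length change.

    Ties keep the current arrangement (stability)."""
    d = engine.corrected
    s_cur = d(pA, pB) + d(pC, pD)
    s1 = d(pA, pC) + d(pB, pD)
    s2 = d(pA, pD) + d(pB, pC)
    best = min(s1, s2)
    if best >= s_cur:
        return "current", 0.0
    if s1 <= s2:
        return "AC|BD", (s1 - s_cur) / 2.0
    return "AD|BC", (s2 - s_cur) / 2.0


def _quartet_nodes(node: Node) -> tuple[Node, Node, Node, Optional[Node]]:
    """(A, B, C, D-node-or-None) around the internal edge above `node`.

    A, B are the node's children.  If the parent is the top trifurcation,
    C and D are its other two children; otherwise C is the sibling and D is
    the "rest of the tree" (returned as None; use the up profile)."""
    A, B = node.children
    parent = node.parent
    others = [c for c in parent.children if c is not node]
    if parent.parent is None:
        return A, B, others[0], others[1]
    return A, B, others[0], None


def me_nni_rounds(tree: Tree, engine: MeEngine,
                  max_sweeps: Optional[int] = None) -> int:
    """Sweeps of minimum-evolution NNIs; returns the number of swaps made.

    Strictly length-reducing swaps are applied immediately and the affected
    profiles refreshed; sweeps stop at the first sweep with no change or
    after ceil(log2 N) + 1 sweeps.
    """
    n = tree.n_leaves
    if max_sweeps is None:
        max_sweeps = math.ceil(math.log2(max(n, 2))) + 1
    total = 0
    for _ in range(max_sweeps):
        changed = 0
        for node in tree.internal_edge_nodes():
            A, B, C, Dnode = _quartet_nodes(node)
            pD = Dnode.profile if Dnode is not None else engine.up_profile(node.parent)
            arr, delta = nni_delta_me(A.profile, B.profile, C.profile, pD, engine)
            if delta < 0.0:
                if arr == "AC|BD":
                    tree.swap_subtrees(B, C)
                else:  # AD|BC: group A with D by swapping A and C
                    tree.swap_subtrees(A, C)
                engine.refresh_path_to_root(node)
                changed += 1
        total += changed
        if changed == 0:
            break
    return total


# --------------------------------------------------------------------------
# Linear SPRs

def _unrooted_neighbors(node: Node) -> list[Node]:
    out = list(node.children)
    if node.parent is not None:
        out.append(node.parent)
    return out


def _edge_child(f: Node, w: Node) -> Node:
    """Canonical child endpoint of the edge between adjacent nodes f, w."""
    return w if w.parent is f else f


def _spr_best_move(tree: Tree, S: Node, engine: MeEngine,
                   max_len: int = 10) -> tuple[float, Optional[Node]]:
    """Best regraft for pruning S, scored as a chain of NNI length changes.

    Exhaustive over chains of length <= 2; each length-2 state is then
    extended greedily along its single best next step up to `max_len`.
    Returns (cumulative delta, target edge child) or (0, None).
    """
    P = S.parent
    d = engine.corrected
    pS = S.profile
    start_dirs = [c for c in _unrooted_neighbors(P) if c is not S]
    if len(start_dirs) != 2:  # pragma: no cover - P is always degree 3
        return 0.0, None

    def step(F: Node, back: Node, behind: pc.Profile, w: Node):
        """Cross F toward w; returns (delta, new_behind, edge_child)."""
        others = [x for x in _unrooted_neighbors(F) if x is not back]
        v = next(x for x in others if x is not w)
        Tw = engine.away_profile(F, w)
        Tv = engine.away_profile(F, v)
        delta = (d(pS, Tw) + d(behind, Tv) - d(pS, behind) - d(Tw, Tv)) / 2.0
        return delta, pc.average_profiles(behind, Tv), _edge_child(F, w)

    best_delta, best_edge = 0.0, None
    frontier = []  # states after exactly `depth` steps

    def consider(cum, edge):
        nonlocal best_delta, best_edge
        if cum < best_delta - 1e-12:
            best_delta, best_edge = cum, edge

    # depth 1 and 2: exhaustive
    states = []
    for F in start_dirs:
        if F.is_leaf:
            continue
        back = P
        behind = engine.away_profile(P, next(x for x in start_dirs if x is not F))
        for w in [x for x in _unrooted_neighbors(F) if x is not back]:
            delta, nb, edge = step(F, back, behind, w)
            consider(delta, edge)
            states.append((w, F, nb, delta, edge))
    frontier = []
    for (F, back, behind, cum, _edge) in states:
        if F.is_leaf:
            continue
        for w in [x for x in _unrooted_neighbors(F) if x is not back]:
            delta, nb, edge = step(F, back, behind, w)
            consider(cum + delta, edge)
            frontier.append((w, F, nb, cum + delta, edge))
    # greedy extension of each length-2 state
    for (F, back, behind, cum, _edge) in frontier:
        depth = 2
        while depth < max_len and not F.is_leaf:
            options = [step(F, back, behind, w) + (w,)
                       for w in _unrooted_neighbors(F) if w is not back]
            delta, nb, edge, w = min(options, key=lambda o: o[0])
            cum += delta
            depth += 1
            consider(cum, edge)
            F, back, behind = w, F, nb
    return best_delta, best_edge


def linear_spr_rounds(tree: Tree, engine: MeEngine, rounds: int = 2,
                      max_len: int = 10) -> int:
    """Two rounds of restricted SPR moves; returns the number applied."""
    applied = 0
    for _ in range(rounds):
        moved = 0
        candidates = [n for n in tree.postorder() if n.parent is not None]
        for S in candidates:
            # the node may have been detached/replaced by an earlier move
            top = S
            while top.parent is not None:
                top = top.parent
            if top is not tree.root or S.parent is None:
                continue
            if S.parent.parent is None:
                # re-hang so the pruned node's parent is not the top
                anchor = next((x for x in tree.root.children
                               if x is not S and not x.is_leaf), None)
                if anchor is None:
                    continue
                tree.reroot_at(anchor)
                engine.recompute_profiles(tree)
            delta, edge_child = _spr_best_move(tree, S, engine, max_len)
            if edge_child is None or delta >= 0.0:
                continue
            tree.detach(S)
            tree.regraft(S, edge_child)
            engine.recompute_profiles(tree)
            moved += 1
        applied += moved
        if moved == 0:
            break
    return applied


# --------------------------------------------------------------------------
# Branch lengths

def me_branch_lengths(tree: Tree, engine: MeEngine) -> Tree:
    """Set every branch length from log-corrected profile distances.

    Internal edge (A,B | C,D):
        len = (d(A,C)+d(A,D)+d(B,C)+d(B,D))/4 - (d(A,B)+d(C,D))/2
    Leaf edge (A | B, C):
        len = (d(A,B)+d(A,C)-d(B,C))/2
    floored at zero.
    """
    d = engine.corrected
    for node in tree.postorder():
        if node.parent is None:
            continue
        parent = node.parent
        others = [c for c in parent.children if c is not node]
        if parent.parent is None:
            pC, pD = others[0].profile, others[1].profile
        else:
            pC, pD = others[0].profile, engine.up_profile(parent)
        if node.is_leaf:
            pA = node.profile
            length = (d(pA, pC) + d(pA, pD) - d(pC, pD)) / 2.0
        else:
            pA, pB = (c.profile for c in node.children)
            length = ((d(pA, pC) + d(pA, pD) + d(pB, pC) + d(pB, pD)) / 4.0
                      - (d(pA, pB) + d(pC, pD)) / 2.0)
        node.length = max(length, 0.0)
    return tree


def total_length(tree: Tree) -> float:
    return sum(n.length for n in tree.postorder() if n.parent is not None)


# --------------------------------------------------------------------------
# Entry point

def minimum_evolution_tree(aln: Alignment, nni: bool = True,
                           spr_rounds: int = 2) -> Tree:
    """Full ME phase: NJ start tree, NNI sweeps, linear SPRs, branch lengths."""
    engine = MeEngine(aln)
    tree = nj_start_tree(aln, engine)
    if nni:
        me_nni_rounds(tree, engine)
    if spr_rounds:
        linear_spr_rounds(tree, engine, rounds=spr_rounds)
        if nni:
            me_nni_rounds(tree, engine)
    me_branch_lengths(tree, engine)
    return tree
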