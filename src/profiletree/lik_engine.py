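"""Felsenstein-pruning likelihood with normalized per-site vectors.

Partial likelihoods ("posteriors") are stored row-normalized: each site's
vector sums to 1, and the log of every normalization constant is
accumulated in a per-site ``log_scale`` counter, so the exact site
log-likelihood is always recoverable as ``log(row sum before
normalization) + accumulated log_scale``.  Stationary frequencies are
applied exactly once, inside :func:`edge_loglik`, keeping the stored
vectors model-convention free.

Per-site rate multipliers (the CAT approximation) enter only through the
branch length: a site in category k evolves along ``t * r_k``.  Sites are
grouped by category so each combine costs one small matrix product per
category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .msa_io import Alignment
from .subst_models import SubstitutionModel, transition_matrix
from .tree import Node, Tree

MIN_BRANCH_LENGTH = 1e-4
MAX_BRANCH_LENGTH = 10.0
BRANCH_TOL_ABS = 1e-4
BRANCH_TOL_REL = 1e-3


@dataclass
class PartialLikelihood:
    """Row-normalized conditional likelihoods with per-site log scales."""

    vec: np.ndarray        # (L, a); each row sums to 1
    log_scale: np.ndarray  # (L,)

    @property
    def length(self) -> int:
        return self.vec.shape[0]


@dataclass
class SiteRates:
    """Per-site relative rates as a category ladder plus assignments."""

    rates: np.ndarray     # (K,) strictly increasing
    site_cat: np.ndarray  # (L,) indices into rates
    _groups: Optional[list] = field(default=None, repr=False)

    @classmethod
    def uniform(cls, L: int) -> "SiteRates":
        return cls(rates=np.ones(1), site_cat=np.zeros(L, dtype=np.intp))

    @property
    def per_site(self) -> np.ndarray:
        return self.rates[self.site_cat]

    @property
    def groups(self) -> list:
        if self._groups is None:
            self._groups = [np.nonzero(self.site_cat == k)[0]
                            for k in range(len(self.rates))]
        return self._groups

    def scaled(self, factor: float) -> "SiteRates":
        return SiteRates(rates=self.rates * factor, site_cat=self.site_cat,
                         _groups=self._groups)


# --------------------------------------------------------------------------
# Primitives

def leaf_partial(row: str, letters: str) -> PartialLikelihood:
    """Indicator rows at characters; gaps become uniform rows whose
    compensating log_scale keeps the per-state likelihood factor at 1."""
    L, a = len(row), len(letters)
    vec = np.zeros((L, a))
    log_scale = np.zeros(L)
    index = {c: i for i, c in enumerate(letters)}
    for pos, ch in enumerate(row):
        i = index.get(ch)
        if i is None:
            vec[pos, :] = 1.0 / a
            log_scale[pos] = math.log(a)
        else:
            vec[pos, i] = 1.0
    return PartialLikelihood(vec=vec, log_scale=log_scale)


def _propagate(p: PartialLikelihood, t: float, model: SubstitutionModel,
               site_rates: SiteRates) -> np.ndarray:
    """v[i,x] = sum_y P(x->y | t*r_i) p[i,y], unnormalized."""
    if len(site_rates.rates) == 1:
        P = transition_matrix(model, t * site_rates.rates[0])
        return p.vec @ P.T
    out = np.empty_like(p.vec)
    for k, idx in enumerate(site_rates.groups):
        if idx.size == 0:
            continue
        P = transition_matrix(model, t * site_rates.rates[k])
        out[idx] = p.vec[idx] @ P.T
    return out


def combine_children(p1: PartialLikelihood, p2: PartialLikelihood,
                     t1: float, t2: float, model: SubstitutionModel,
                     site_rates: SiteRates) -> PartialLikelihood:
    """Posterior of a parent from its two children and their branch lengths."""
    v = _propagate(p1, t1, model, site_rates) * _propagate(p2, t2, model, site_rates)
    norm = v.sum(axis=1)
    v /= norm[:, None]
    return PartialLikelihood(vec=v,
                             log_scale=np.log(norm) + p1.log_scale + p2.log_scale)


def combine_many(partials, lengths, model: SubstitutionModel,
                 site_rates: SiteRates) -> PartialLikelihood:
    """Fold an arbitrary number of children (used at the top trifurcation)."""
    v = _propagate(partials[0], lengths[0], model, site_rates)
    scale = partials[0].log_scale.copy()
    for p, t in zip(partials[1:], lengths[1:]):
        v *= _propagate(p, t, model, site_rates)
        scale += p.log_scale
    norm = v.sum(axis=1)
    v /= norm[:, None]
    return PartialLikelihood(vec=v, log_scale=np.log(norm) + scale)


def edge_site_logliks(p1: PartialLikelihood, p2: PartialLikelihood, t: float,
                      model: SubstitutionModel,
                      site_rates: SiteRates) -> np.ndarray:
    """Per-site log-likelihood of the tree evaluated across one edge:
    ln sum_xy pi_x p1[x] P(x->y|t r) p2[y], plus both accumulated scales."""
    pi = model.stationary
    if len(site_rates.rates) == 1:
        P = transition_matrix(model, t * site_rates.rates[0])
        s = np.einsum("li,lj,ij->l", p1.vec, p2.vec, pi[:, None] * P)
        out = np.log(s) + p1.log_scale + p2.log_scale
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("non-finite site log-likelihood "
                                     "(scaling bookkeeping broke down)")
        return out
    s = np.empty(p1.length)
    for k, idx in enumerate(site_rates.groups):
        if idx.size == 0:
            continue
        P = transition_matrix(model, t * site_rates.rates[k])
        M = pi[:, None] * P
        s[idx] = np.einsum("li,lj,ij->l", p1.vec[idx], p2.vec[idx], M)
    out = np.log(s) + p1.log_scale + p2.log_scale
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite site log-likelihood "
                                 "(scaling bookkeeping broke down)")
    return out


def edge_loglik(p1: PartialLikelihood, p2: PartialLikelihood, t: float,
                model: SubstitutionModel, site_rates: SiteRates) -> float:
    return float(edge_site_logliks(p1, p2, t, model, site_rates).sum())


# --------------------------------------------------------------------------
# Tree-level computation

def assign_leaf_partials(tree: Tree, aln: Alignment) -> None:
    rows = dict(zip(aln.names, aln.rows))
    for leaf in tree.leaves():
        leaf.partial = leaf_partial(rows[leaf.name], aln.letters)


def recompute_partials(tree: Tree, model: SubstitutionModel,
                       site_rates: SiteRates) -> None:
    """Exact posteriors for every internal node, children before parents."""
    for node in tree.postorder():
        if node.is_leaf or node is tree.root:
            continue
        c1, c2 = node.children
        node.partial = combine_children(c1.partial, c2.partial,
                                        c1.length, c2.length, model, site_rates)


def refresh_partials_to_root(node: Node, model: SubstitutionModel,
                             site_rates: SiteRates) -> None:
    """Recompute posteriors from `node` up to (excluding) the top node."""
    while node is not None and node.parent is not None:
        if not node.is_leaf:
            c1, c2 = node.children
            node.partial = combine_children(c1.partial, c2.partial,
                                            c1.length, c2.length, model,
                                            site_rates)
        node = node.parent


def compute_up_posterior(node: Node, model: SubstitutionModel,
                         site_rates: SiteRates) -> PartialLikelihood:
    """Posterior of the rest of the tree as seen from `node`'s parent edge.

    Recurrence: a node's up-posterior combines its parent's up-posterior
    with its sibling's posterior; at the top trifurcation it combines the
    other two children.  Storage is bounded by the depth of the recursion.
    """
    parent = node.parent
    if parent is None:
        raise ValueError("the top node has no up-posterior")
    others = [c for c in parent.children if c is not node]
    for o in others:
        if o.partial is None:
            raise RuntimeError("stale partials: sibling posterior missing")
    if parent.parent is None:
        return combine_many([o.partial for o in others],
                            [o.length for o in others], model, site_rates)
    up = compute_up_posterior(parent, model, site_rates)
    return combine_children(up, others[0].partial, parent.length,
                            others[0].length, model, site_rates)


def tree_site_logliks(tree: Tree, model: SubstitutionModel,
                      site_rates: SiteRates) -> np.ndarray:
    c = tree.root.children
    rest = combine_many([x.partial for x in c[1:]], [x.length for x in c[1:]],
                        model, site_rates)
    return edge_site_logliks(c[0].partial, rest, c[0].length, model, site_rates)


def tree_loglik(tree: Tree, model: SubstitutionModel,
                site_rates: SiteRates) -> float:
    return float(tree_site_logliks(tree, model, site_rates).sum())


# --------------------------------------------------------------------------
# One-dimensional optimization (Brent)

def brent_minimize(f: Callable[[float], float], x0: float,
                   bounds: tuple[float, float],
                   tol_abs: float = BRANCH_TOL_ABS,
                   tol_rel: float = BRANCH_TOL_REL,
                   max_iter: int = 100) -> float:
    """Brent's method with the bracketing and stopping rules of the search.

    The initial bracket is (x0/2, x0, 2*x0), or (min, 2*min, 4*min) when the
    guess sits below the lower bound; if the middle point is not the best
    the interval is expanded toward the better end until it brackets (or
    hits a bound, in which case the bound is returned for monotone f).
    Iteration stops when the step falls below max(tol_abs, tol_rel*|x|).
    """
    lo, hi = bounds
    if x0 < lo:
        xs = [lo, min(2 * lo, hi), min(4 * lo, hi)]
    else:
        x0 = min(x0, hi)
        xs = [max(x0 / 2, lo), x0, min(2 * x0, hi)]
    xs = sorted(set(xs))
    while len(xs) < 3:  # degenerate guesses at a bound: wedge in midpoints
        cands = sorted(set([lo] + xs + [hi]))
        gaps = [(cands[i + 1] - cands[i], i) for i in range(len(cands) - 1)]
        width, i = max(gaps)
        if width <= tol_abs:  # bounds collapsed; nothing left to search
            return xs[0]
        xs.append((cands[i] + cands[i + 1]) / 2.0)
        xs = sorted(set(xs))
    fa, fb, fc = (f(x) for x in xs)
    a, b, c = xs
    if not all(map(math.isfinite, (fa, fb, fc))):
        raise FloatingPointError("objective not finite on the initial bracket")
    # expand until the middle point is best (or a bound is reached)
    while not (fb <= fa and fb <= fc):
        if fa < fc:
            if a <= lo:
                if fa <= fb:
                    return a
                break
            a, b, c, fb, fc = max(lo, a / 2), a, b, fa, fb
            fa = f(a)
        else:
            if c >= hi:
                if fc <= fb:
                    return c
                break
            a, b, c, fa, fb = b, c, min(hi, 2 * c), fb, fc
            fc = f(c)

    # standard Brent loop on [a, c] with current best b
    x = w = v = b
    fx = fw = fv = fb
    d = e = 0.0
    for _ in range(max_iter):
        m = 0.5 * (a + c)
        tol1 = max(tol_abs, tol_rel * abs(x))
        tol2 = 2.0 * tol1
        if abs(x - m) <= tol2 - 0.5 * (c - a):
            break
        use_golden = True
        if abs(e) > tol1:
            r = (x - w) * (fx - fv)
            q = (x - v) * (fx - fw)
            p = (x - v) * q - (x - w) * r
            q = 2.0 * (q - r)
            if q > 0:
                p = -p
            q = abs(q)
            if abs(p) < abs(0.5 * q * e) and q * (a - x) < p < q * (c - x):
                d_new = p / q
                u = x + d_new
                if (u - a) < tol2 or (c - u) < tol2:
                    d_new = tol1 if x < m else -tol1
                e, d = d, d_new
                use_golden = False
        if use_golden:
            e = (c - x) if x < m else (a - x)
            d = 0.381966011 * e
        u = x + d if abs(d) >= tol1 else x + (tol1 if d > 0 else -tol1)
        fu = f(u)
        if fu <= fx:
            if u >= x:
                a = x
            else:
                c = x
            v, w, x = w, x, u
            fv, fw, fx = fw, fx, fu
        else:
            if u < x:
                a = u
            else:
                c = u
            if fu <= fw or w == x:
                v, w = w, u
                fv, fw = fw, fu
            elif fu <= fv or v == x or v == w:
                v, fv = u, fu
    return x


# --------------------------------------------------------------------------
# Branch-length optimization

def optimize_branch(p1: PartialLikelihood, p2: PartialLikelihood,
                    t0: float, model: SubstitutionModel,
                    site_rates: SiteRates,
                    bounds: tuple[float, float] = (MIN_BRANCH_LENGTH,
                                                   MAX_BRANCH_LENGTH),
                    ) -> tuple[float, float]:
    """Maximize the edge likelihood over the branch length.

    Returns (new length, log-likelihood at it); never returns a length whose
    likelihood is below the clamped starting point's."""
    def neg(t: float) -> float:
        return -edge_loglik(p1, p2, t, model, site_rates)

    start = min(max(t0, bounds[0]), bounds[1])
    t = brent_minimize(neg, start, bounds)
    f_t, f_start = neg(t), neg(start)
    if f_start < f_t:
        t, f_t = start, f_start
    return t, -f_t


def optimize_all_lengths(tree: Tree, model: SubstitutionModel,
                         site_rates: SiteRates, rounds: int = 2,
                         ) -> Tree:
    """Post-order pass optimizing, at each node, the three incident branch
    lengths in series for `rounds` rounds (at the top: its three children).

    The node's posterior is refreshed afterwards, so by the end of the pass
    every stored posterior is exact under the new lengths."""
    for node in tree.postorder():
        if node.is_leaf:
            continue
        if node is tree.root:
            c1, c2, c3 = node.children
            for _ in range(rounds):
                for target, o1, o2 in ((c1, c2, c3), (c2, c1, c3), (c3, c1, c2)):
                    rest = combine_children(o1.partial, o2.partial,
                                            o1.length, o2.length, model,
                                            site_rates)
                    target.length, _ = optimize_branch(
                        target.partial, rest, target.length, model, site_rates)
            continue
        c1, c2 = node.children
        up = compute_up_posterior(node, model, site_rates)
        for _ in range(rounds):
            rest1 = combine_children(c2.partial, up, c2.length, node.length,
                                     model, site_rates)
            c1.length, _ = optimize_branch(c1.partial, rest1, c1.length,
                                           model, site_rates)
            rest2 = combine_children(c1.partial, up, c1.length, node.length,
                                     model, site_rates)
            c2.length, _ = optimize_branch(c2.partial, rest2, c2.length,
                                           model, site_rates)
            below = combine_children(c1.partial, c2.partial, c1.length,
                                     c2.length, model, site_rates)
            node.length, _ = optimize_branch(below, up, node.length,
                                             model, site_rates)
            node.partial = below
    return tree
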