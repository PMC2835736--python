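"""Maximum-likelihood phase: NNI search with heuristics, GTR, CAT, Gamma20.

The phase takes the minimum-evolution tree and runs a fixed pipeline:

1. approximate posteriors for every internal node from decayed averages of
   its children (replaced by exact values as the search touches them);
2. one round of branch lengths under a simplified model (no CAT; JC in
   place of GTR);
3. one round of ML NNIs under the simplified model;
4. with GTR: optimize the six exchangeabilities (two passes), switch
   models, recompute posteriors, one round of branch lengths;
5. with CAT: assign a per-site rate category from a 20-rate ladder,
   recompute posteriors, one round of branch lengths;
6. further NNI rounds with subtree skipping and the star-topology test,
   until no quartet improves by more than 0.1 log-likelihood units or a
   2*ceil(log2 N) round limit is reached;
7. a final NNI round with both heuristics off;
8. one round of branch lengths;
9. SH-like local supports (see :mod:`profiletree.sh_support`).

Every accepted operation can only increase the tree's log-likelihood under
the model and rates in force at that moment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.optimize
import scipy.special
import scipy.stats

from . import lik_engine as lk
from .lik_engine import MIN_BRANCH_LENGTH, PartialLikelihood, SiteRates
from .me_phase import total_length
from .msa_io import Alignment
from .subst_models import (SubstitutionModel, build_model,
                           empirical_frequencies)
from .tree import Node, Tree

NNI_ABANDON_LL = 5.0          # drop alternates this much worse after round 1
NNI_CONVERGENCE_LL = 0.1      # largest quartet gain that still counts as converged
STAR_TEST_LL = 5.0            # current-vs-star margin that skips alternates
SKIP_IMPROVEMENT_LL = 0.1     # "significant improvement" for subtree skipping

CAT_RATE_MIN = 0.05
CAT_RATE_MAX = 20.0
CAT_PRIOR_SHAPE = 3.0
CAT_PRIOR_SCALE = 1.0 / 3.0

ARR_CURRENT, ARR_AC_BD, ARR_AD_BC = "AB|CD", "AC|BD", "AD|BC"


# --------------------------------------------------------------------------
# Search state

@dataclass
class SearchState:
    """Round counter plus the per-node history behind the two heuristics."""

    n_leaves: int
    round: int = 0
    subtree_improved: dict = field(default_factory=dict)  # node id -> round
    nni_affected: dict = field(default_factory=dict)      # node id -> round
    node_swapped: dict = field(default_factory=dict)      # node id -> round
    converged: bool = False

    @property
    def max_rounds(self) -> int:
        return 2 * math.ceil(math.log2(max(self.n_leaves, 2)))

    def record_improvement(self, node: Node) -> None:
        while node is not None:
            self.subtree_improved[node.id] = self.round
            node = node.parent

    def record_nni(self, node: Node) -> None:
        self.node_swapped[node.id] = self.round
        touched = [node, node.parent] + list(node.children)
        if node.parent is not None:
            touched += [c for c in node.parent.children if c is not node]
        for n in touched:
            if n is not None:
                self.nni_affected[n.id] = self.round

    def unchanged_last_round(self, node: Node) -> bool:
        return self.node_swapped.get(node.id) != self.round - 1


def should_skip_subtree(state: SearchState, node: Node) -> bool:
    """Skip a subtree that saw no significant improvement in either of the
    previous two rounds, provided no node adjacent to its parent was part
    of a significantly improving NNI last round.  Needs two rounds of
    history, so it never fires before round 3."""
    if state.round < 3:
        return False
    if state.subtree_improved.get(node.id, -1) >= state.round - 2:
        return False
    parent = node.parent
    if parent is not None:
        adjacent = list(parent.children)
        if parent.parent is not None:
            adjacent.append(parent.parent)
        for a in adjacent:
            if state.nni_affected.get(a.id) == state.round - 1:
                return False
    return True


def star_test(ll_current_opt: float, ll_star: float) -> bool:
    """True when the resolved topology beats the star approximation (the
    same quartet with the internal branch pinned at the minimum length) by
    more than 5 log-likelihood units."""
    return ll_current_opt - ll_star > STAR_TEST_LL


# --------------------------------------------------------------------------
# Quartet optimization

def _optimize_quartet(pA, pB, pC, pD, lens, model, site_rates, rounds=1):
    """One or more rounds of the five branch optimizations for a quartet
    ((A,B),(C,D)): the internal edge first, then A, B, C, D.

    `lens` is (tA, tB, tC, tD, tint).  Returns (new lens, final LL)."""
    tA, tB, tC, tD, tint = lens
    ll = None
    for _ in range(rounds):
        AB = lk.combine_children(pA, pB, tA, tB, model, site_rates)
        CD = lk.combine_children(pC, pD, tC, tD, model, site_rates)
        tint, ll = lk.optimize_branch(AB, CD, tint, model, site_rates)
        BCD = lk.combine_children(pB, CD, tB, tint, model, site_rates)
        tA, ll = lk.optimize_branch(pA, BCD, tA, model, site_rates)
        ACD = lk.combine_children(pA, CD, tA, tint, model, site_rates)
        tB, ll = lk.optimize_branch(pB, ACD, tB, model, site_rates)
        AB = lk.combine_children(pA, pB, tA, tB, model, site_rates)
        ABD = lk.combine_children(AB, pD, tint, tD, model, site_rates)
        tC, ll = lk.optimize_branch(pC, ABD, tC, model, site_rates)
        ABC = lk.combine_children(AB, pC, tint, tC, model, site_rates)
        tD, ll = lk.optimize_branch(pD, ABC, tD, model, site_rates)
    return (tA, tB, tC, tD, tint), ll


def _node_quartet(node: Node, model, site_rates):
    """Partials, lengths and write-back targets for the quartet at `node`.

    A, B are the node's children; C is the sibling; D is either the third
    child of the top trifurcation or the up-posterior of the parent."""
    A, B = node.children
    parent = node.parent
    others = [c for c in parent.children if c is not node]
    C = others[0]
    if parent.parent is None:
        Dnode, pD, tD = others[1], others[1].partial, others[1].length
    else:
        Dnode = None
        pD = lk.compute_up_posterior(parent, model, site_rates)
        tD = parent.length
    return A, B, C, Dnode, pD, tD


def _write_back(node: Node, arrangement: str, lens, Cnode: Node,
                Dnode: Optional[Node]) -> None:
    """Apply an arrangement and its re-optimized lengths around `node`."""
    A, B = node.children
    if arrangement == ARR_AC_BD:
        Tree.swap_subtrees(B, Cnode)
    elif arrangement == ARR_AD_BC:
        if Dnode is not None:
            Tree.swap_subtrees(B, Dnode)
        else:
            Tree.swap_subtrees(A, Cnode)
    tA, tB, tC, tD, tint = lens
    # lengths travel with the subtrees, wherever they ended up
    A.length, B.length, Cnode.length = tA, tB, tC
    if Dnode is not None:
        Dnode.length = tD
    else:
        node.parent.length = tD
    node.length = tint


def ml_nni_round(tree: Tree, model: SubstitutionModel, site_rates: SiteRates,
                 state: SearchState, heuristics_on: bool = True,
                 mlacc: int = 1, on_visit=None) -> dict:
    """One depth-first post-order round of ML NNIs.

    Per node: evaluate the three quartet arrangements with one round of
    branch optimization each, abandon alternates more than 5 LL units worse
    than the current one, give survivors a second round, adopt the best,
    and write the re-optimized lengths back.  Returns round statistics."""
    state.round += 1
    stats = {"round": state.round, "swaps": 0, "max_gain": 0.0,
             "skipped_subtrees": 0, "star_skips": 0, "visited": 0}

    def visit(node: Node) -> None:
        if node.is_leaf:
            return
        if (heuristics_on and node.parent is not None
                and should_skip_subtree(state, node)):
            stats["skipped_subtrees"] += 1
            return
        # snapshot: swaps at a child rewrite this list in place, which
        # would otherwise re-visit moved subtrees and skip their exchanges
        for child in list(node.children):
            visit(child)
        if node.parent is None:
            return
        process(node)
        # keep every stored posterior exact: the write-back changed edge
        # lengths incident to the parent, so ancestors are stale until
        # recomputed (a swap can also process a node after its new parent)
        lk.refresh_partials_to_root(node, model, site_rates)
        if on_visit is not None:
            on_visit(node)

    def process(node: Node) -> None:
        stats["visited"] += 1
        A, B = node.children
        Cnode_etc = _node_quartet(node, model, site_rates)
        A, B, C, Dnode, pD, tD = Cnode_etc
        lens0 = (A.length, B.length, C.length, tD, node.length)
        pA, pB, pC = A.partial, B.partial, C.partial

        AB0 = lk.combine_children(pA, pB, lens0[0], lens0[1], model, site_rates)
        CD0 = lk.combine_children(pC, pD, lens0[2], lens0[3], model, site_rates)
        ll_initial = lk.edge_loglik(AB0, CD0, lens0[4], model, site_rates)

        if (heuristics_on and state.unchanged_last_round(node)
                and state.round > 1):
            tint_opt, ll_opt = lk.optimize_branch(AB0, CD0, lens0[4],
                                                  model, site_rates)
            ll_star = lk.edge_loglik(AB0, CD0, MIN_BRANCH_LENGTH,
                                     model, site_rates)
            if star_test(ll_opt, ll_star):
                node.length = tint_opt
                # AB0 is the node's exact posterior under the current child
                # lengths (which a child's earlier write-back may have moved)
                node.partial = AB0
                stats["star_skips"] += 1
                if ll_opt - ll_initial > SKIP_IMPROVEMENT_LL:
                    state.record_improvement(node)
                return

        arrangements = {
            ARR_CURRENT: (pA, pB, pC, pD, lens0),
            ARR_AC_BD: (pA, pC, pB, pD,
                        (lens0[0], lens0[2], lens0[1], lens0[3], lens0[4])),
            ARR_AD_BC: (pA, pD, pB, pC,
                        (lens0[0], lens0[3], lens0[1], lens0[2], lens0[4])),
        }
        rounds1 = mlacc if mlacc >= 2 else 1
        results = {}
        for arr, (q1, q2, q3, q4, lens) in arrangements.items():
            results[arr] = _optimize_quartet(q1, q2, q3, q4, lens, model,
                                             site_rates, rounds=rounds1)
        if mlacc < 2:
            ll_cur = results[ARR_CURRENT][1]
            survivors = [arr for arr in (ARR_AC_BD, ARR_AD_BC)
                         if results[arr][1] >= ll_cur - NNI_ABANDON_LL]
            if survivors:
                for arr in survivors + [ARR_CURRENT]:
                    q1, q2, q3, q4, _ = arrangements[arr]
                    results[arr] = _optimize_quartet(
                        q1, q2, q3, q4, results[arr][0], model, site_rates,
                        rounds=1)

        ll_cur = results[ARR_CURRENT][1]
        best_arr = max(results, key=lambda a: results[a][1])
        best_lens, best_ll = results[best_arr]
        gain = best_ll - ll_cur
        if best_arr != ARR_CURRENT and gain > 0.0:
            stats["max_gain"] = max(stats["max_gain"], gain)
            stats["swaps"] += 1
            if gain > SKIP_IMPROVEMENT_LL:
                state.record_nni(node)
        else:
            best_arr, best_lens, best_ll = ARR_CURRENT, *results[ARR_CURRENT]

        # quartet lengths in canonical (A, B, C, D, int) order for write-back
        if best_arr == ARR_AC_BD:
            tA, tC, tB, tD2, tint = best_lens
            lens_wb = (tA, tB, tC, tD2, tint)
        elif best_arr == ARR_AD_BC:
            tA, tD2, tB, tC, tint = best_lens
            lens_wb = (tA, tB, tC, tD2, tint)
        else:
            lens_wb = best_lens
        _write_back(node, best_arr, lens_wb, C, Dnode)
        c1, c2 = node.children
        node.partial = lk.combine_children(c1.partial, c2.partial, c1.length,
                                           c2.length, model, site_rates)
        if best_ll - ll_initial > SKIP_IMPROVEMENT_LL:
            state.record_improvement(node)

    visit(tree.root)
    return stats


# --------------------------------------------------------------------------
# GTR parameter optimization

def optimize_gtr_rates(tree: Tree, aln: Alignment,
                       site_rates: Optional[SiteRates] = None,
                       passes: int = 2) -> SubstitutionModel:
    """Fit the six GTR exchangeabilities on a fixed topology and lengths.

    The stationary distribution is the empirical base frequencies; the AG
    rate is pinned to 1 for identifiability and the remaining five are
    optimized in turn with Brent's method, for two passes, recomputing all
    posteriors at every candidate model."""
    if aln.alphabet != "nt":
        raise ValueError("GTR applies to nucleotide data only")
    if site_rates is None:
        site_rates = SiteRates.uniform(aln.length)
    pi = empirical_frequencies(aln)
    rates = np.ones(6)
    AG = 1  # index into GTR_PAIRS; pinned

    def loglik_for(r: np.ndarray) -> float:
        model = build_model("gtr", stationary=pi, gtr_rates=r)
        lk.recompute_partials(tree, model, site_rates)
        return lk.tree_loglik(tree, model, site_rates)

    for _ in range(passes):
        for idx in range(6):
            if idx == AG:
                continue

            def neg(v: float, idx=idx) -> float:
                trial = rates.copy()
                trial[idx] = v
                return -loglik_for(trial)

            rates[idx] = lk.brent_minimize(neg, rates[idx], (1e-4, 1e3),
                                           tol_abs=1e-3, tol_rel=1e-2)
    model = build_model("gtr", stationary=pi, gtr_rates=rates)
    lk.recompute_partials(tree, model, site_rates)
    return model


# --------------------------------------------------------------------------
# CAT rate categories

@dataclass
class RateAssignment:
    """A per-site rate category assignment over a fixed log-spaced ladder.

    ``rates`` is the pre-rescale ladder; ``rescale`` is the common factor
    that makes the mean assigned rate exactly 1.  The per-site, per-rate
    log-likelihood table is retained for the Gamma20 rescaling step."""

    rates: np.ndarray        # (K,) ladder, endpoints 0.05 and 20
    site_cat: np.ndarray     # (L,)
    rescale: float
    site_loglik_table: np.ndarray  # (K, L) at the pre-rescale ladder
    prior_shape: float = CAT_PRIOR_SHAPE
    prior_scale: float = CAT_PRIOR_SCALE

    def site_rates(self) -> SiteRates:
        return SiteRates(rates=self.rates * self.rescale,
                         site_cat=self.site_cat)


def rate_ladder(K: int = 20) -> np.ndarray:
    return np.exp(np.linspace(math.log(CAT_RATE_MIN), math.log(CAT_RATE_MAX), K))


def per_rate_site_logliks(tree: Tree, model: SubstitutionModel,
                          ladder: np.ndarray) -> np.ndarray:
    """Per-site tree log-likelihood with every branch scaled by each ladder
    rate (equivalent to a per-site rate multiplier); shape (K, L)."""
    L = next(iter(tree.leaves())).partial.length
    table = np.empty((len(ladder), L))
    for k, r in enumerate(ladder):
        sr = SiteRates(rates=np.array([r]), site_cat=np.zeros(L, dtype=np.intp))
        lk.recompute_partials(tree, model, sr)
        table[k] = lk.tree_site_logliks(tree, model, sr)
    return table


def assign_cat_rates(tree: Tree, aln: Alignment, model: SubstitutionModel,
                     K: int = 20) -> RateAssignment:
    """Bayesian per-site rate selection: each site gets the ladder rate
    maximizing its log-likelihood plus the log of a gamma(3, 1/3) prior
    (mean 1, deliberately peaked to avoid overfitting); the chosen rates
    are then rescaled by a common factor so their mean over sites is 1."""
    ladder = rate_ladder(K)
    table = per_rate_site_logliks(tree, model, ladder)
    log_prior = scipy.stats.gamma.logpdf(ladder, a=CAT_PRIOR_SHAPE,
                                         scale=CAT_PRIOR_SCALE)
    site_cat = np.argmax(table + log_prior[:, None], axis=0)
    mean_rate = float(ladder[site_cat].mean())
    return RateAssignment(rates=ladder, site_cat=site_cat,
                          rescale=1.0 / mean_rate, site_loglik_table=table)


# --------------------------------------------------------------------------
# Gamma20 shape + rescale correction

@dataclass
class Gamma20Result:
    shape: float            # fitted gamma shape alpha
    scale_factor: float     # branch-length rescaling s
    tree_length: float      # total branch length after rescaling
    loglik: float           # Gamma20 log-likelihood


def _gamma20_weights(ladder: np.ndarray, alpha: float, s: float) -> np.ndarray:
    """Discrete-gamma weights over the fixed ladder: the gamma(alpha, mean s)
    density at each ladder rate times the log-spacing cell width."""
    dlog = math.log(ladder[1] / ladder[0])
    logw = scipy.stats.gamma.logpdf(ladder, a=alpha, scale=s / alpha) \
        + np.log(ladder * dlog)
    logw -= scipy.special.logsumexp(logw)
    return logw


def gamma20_loglik(assignment: RateAssignment, alpha: float, s: float) -> float:
    logw = _gamma20_weights(assignment.rates, alpha, s)
    return float(scipy.special.logsumexp(
        assignment.site_loglik_table + logw[:, None], axis=0).sum())


def gamma20_rescale(assignment: RateAssignment, tree: Tree) -> Gamma20Result:
    """Fit a gamma shape and a branch rescaling to the retained per-site,
    per-rate likelihood table, mixing over the fixed 20-rate ladder."""
    def neg(params: np.ndarray) -> float:
        alpha, s = np.exp(params)
        return -gamma20_loglik(assignment, alpha, s)

    res = scipy.optimize.minimize(neg, x0=np.log([CAT_PRIOR_SHAPE, 1.0]),
                                  method="Nelder-Mead",
                                  options={"xatol": 1e-4, "fatol": 1e-6,
                                           "maxiter": 400})
    alpha, s = np.exp(res.x)
    return Gamma20Result(shape=float(alpha), scale_factor=float(s),
                         tree_length=float(total_length(tree) * s),
                         loglik=float(-res.fun))


# --------------------------------------------------------------------------
# Step 1: approximate posteriors

def approximate_initial_partials(tree: Tree, aln: Alignment) -> None:
    """Seed internal posteriors with branch-length-decayed averages of the
    children (weights e^-t, mimicking substitution attenuation).  Exact
    values replace these as the search revisits each node."""
    lk.assign_leaf_partials(tree, aln)
    for node in tree.postorder():
        if node.is_leaf or node is tree.root:
            continue
        c1, c2 = node.children
        w1, w2 = math.exp(-c1.length), math.exp(-c2.length)
        v = (w1 * c1.partial.vec + w2 * c2.partial.vec) / (w1 + w2)
        v /= v.sum(axis=1)[:, None]
        node.partial = PartialLikelihood(
            vec=v, log_scale=c1.partial.log_scale + c2.partial.log_scale)


# --------------------------------------------------------------------------
# The pipeline

@dataclass
class MlResult:
    tree: Tree
    model: SubstitutionModel
    site_rates: SiteRates
    rate_assignment: Optional[RateAssignment]
    gamma20: Optional[Gamma20Result]
    trace: list                 # (label, loglik) after each pipeline step
    nni_rounds: int
    converged: bool
    round_stats: list


def run_ml_pipeline(tree: Tree, aln: Alignment, model_kind: str = "jc",
                    use_cat: bool = True, cat_K: int = 20, mlacc: int = 1,
                    gamma: bool = False, heuristics: bool = True,
                    ) -> MlResult:
    """Run ML steps 1-8 on a minimum-evolution tree (supports are separate).

    ``model_kind`` is "jc" or "gtr" for nucleotides, "jtt" for proteins.
    ``heuristics=False`` disables subtree skipping and the star test in
    every round (the final round always runs without them)."""
    if model_kind in ("jc", "gtr") and aln.alphabet != "nt":
        raise ValueError("nucleotide model on non-nucleotide data")
    if model_kind == "jtt" and aln.alphabet != "aa":
        raise ValueError("JTT applies to amino-acid data")

    simple_model = build_model("jc" if aln.alphabet == "nt" else "jtt")
    site_rates = SiteRates.uniform(aln.length)
    trace: list[tuple[str, float]] = []
    stats_log: list[dict] = []
    state = SearchState(n_leaves=tree.n_leaves)

    # (1) approximate posteriors
    approximate_initial_partials(tree, aln)
    # (2) one round of branch lengths, simplified model
    lk.optimize_all_lengths(tree, simple_model, site_rates)
    trace.append(("lengths_simple", lk.tree_loglik(tree, simple_model, site_rates)))
    # (3) one round of ML NNIs, simplified model, heuristics off
    stats_log.append(ml_nni_round(tree, simple_model, site_rates, state,
                                  heuristics_on=False, mlacc=mlacc))
    trace.append(("nni_round_1", lk.tree_loglik(tree, simple_model, site_rates)))

    model = simple_model
    rate_assignment = None
    # (4) GTR parameters
    if model_kind == "gtr":
        model = optimize_gtr_rates(tree, aln, site_rates)
        trace.append(("gtr_switch", lk.tree_loglik(tree, model, site_rates)))
        lk.optimize_all_lengths(tree, model, site_rates)
        trace.append(("lengths_gtr", lk.tree_loglik(tree, model, site_rates)))
    # (5) CAT rate categories
    if use_cat:
        rate_assignment = assign_cat_rates(tree, aln, model, K=cat_K)
        site_rates = rate_assignment.site_rates()
        lk.recompute_partials(tree, model, site_rates)
        trace.append(("cat_switch", lk.tree_loglik(tree, model, site_rates)))
        lk.optimize_all_lengths(tree, model, site_rates)
        trace.append(("lengths_cat", lk.tree_loglik(tree, model, site_rates)))
    # (6) NNI rounds with heuristics until convergence
    converged = False
    while state.round < state.max_rounds:
        stats = ml_nni_round(tree, model, site_rates, state,
                             heuristics_on=heuristics, mlacc=mlacc)
        stats_log.append(stats)
        trace.append((f"nni_round_{state.round}",
                      lk.tree_loglik(tree, model, site_rates)))
        if stats["max_gain"] <= NNI_CONVERGENCE_LL:
            converged = True
            break
    state.converged = converged
    # (7) safety-valve round, heuristics off
    stats_log.append(ml_nni_round(tree, model, site_rates, state,
                                  heuristics_on=False, mlacc=mlacc))
    trace.append((f"nni_final_{state.round}",
                  lk.tree_loglik(tree, model, site_rates)))
    # (8) final branch lengths
    lk.optimize_all_lengths(tree, model, site_rates)
    trace.append(("lengths_final", lk.tree_loglik(tree, model, site_rates)))

    gamma_res = None
    if gamma:
        if rate_assignment is None:
            rate_assignment = assign_cat_rates(tree, aln, model, K=cat_K)
            lk.recompute_partials(tree, model, site_rates)
        gamma_res = gamma20_rescale(rate_assignment, tree)

    return MlResult(tree=tree, model=model, site_rates=site_rates,
                    rate_assignment=rate_assignment, gamma20=gamma_res,
                    trace=trace, nni_rounds=state.round, converged=converged,
                    round_stats=stats_log)
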