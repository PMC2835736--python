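"""Likelihood engine: pruning vs exhaustive enumeration, scaling, Brent."""

import itertools

import numpy as np
import pytest
import scipy.optimize

import profiletree as pt
from profiletree import lik_engine as lk
from profiletree.subst_models import transition_matrix
from conftest import (brute_force_loglik, brute_force_site_logliks,
                      random_resolved_tree)


def _sim(n, L, seed, **kw):
    truth, aln = pt.simulate(pt.SimulationSpec(n_taxa=n, seq_length=L,
                                               seed=seed, **kw))
    return truth, aln


def _setup(tree, aln, model, site_rates=None):
    sr = site_rates or lk.SiteRates.uniform(aln.length)
    lk.assign_leaf_partials(tree, aln)
    lk.recompute_partials(tree, model, sr)
    return sr


def test_leaf_partial_indicator_and_gap_bookkeeping():
    p = lk.leaf_partial("A-C", "ACGT")
    assert np.allclose(p.vec[0], [1, 0, 0, 0])
    assert np.allclose(p.vec[1], 0.25)
    assert p.log_scale[1] == pytest.approx(np.log(4))
    # a single gap site contributes likelihood exactly 1 under any model
    m = pt.build_model("jc")
    ll = lk.edge_loglik(lk.leaf_partial("-", "ACGT"),
                        lk.leaf_partial("A", "ACGT"), 0.5, m,
                        lk.SiteRates.uniform(1))
    direct = np.log(0.25)  # pi_A; the gap side integrates to 1
    assert ll == pytest.approx(direct, abs=1e-12)


def test_combine_children_matches_explicit_double_loop(jc_model):
    rng = np.random.default_rng(1)
    L, a = 3, 4
    sr = lk.SiteRates(rates=np.array([0.5, 1.7]),
                      site_cat=np.array([0, 1, 0]))
    v1 = rng.random((L, a)); v1 /= v1.sum(1)[:, None]
    v2 = rng.random((L, a)); v2 /= v2.sum(1)[:, None]
    p1 = lk.PartialLikelihood(vec=v1, log_scale=np.array([0.1, 0.0, -0.2]))
    p2 = lk.PartialLikelihood(vec=v2, log_scale=np.zeros(L))
    t1, t2 = 0.3, 0.07
    got = lk.combine_children(p1, p2, t1, t2, jc_model, sr)
    for i in range(L):
        r = sr.per_site[i]
        P1 = transition_matrix(jc_model, t1 * r)
        P2 = transition_matrix(jc_model, t2 * r)
        raw = np.array([
            sum(P1[x, y] * v1[i, y] for y in range(a)) *
            sum(P2[x, z] * v2[i, z] for z in range(a)) for x in range(a)])
        assert np.allclose(got.vec[i], raw / raw.sum(), atol=1e-12)
        assert got.log_scale[i] == pytest.approx(
            np.log(raw.sum()) + p1.log_scale[i] + p2.log_scale[i], abs=1e-12)


def test_combine_saturated_branches_give_stationary_rows(jc_model):
    p = lk.leaf_partial("AC", "ACGT")
    sat = lk.combine_children(p, p, 1e4, 1e4, jc_model,
                              lk.SiteRates.uniform(2))
    assert np.allclose(sat.vec, 0.25, atol=1e-6)


def test_two_identical_leaves_at_zero_length_jc():
    m = pt.build_model("jc")
    p = lk.leaf_partial("ACGT", "ACGT")
    ll = lk.edge_loglik(p, p, 0.0, m, lk.SiteRates.uniform(4))
    assert ll == pytest.approx(4 * np.log(0.25), abs=1e-12)


@pytest.mark.parametrize("n,model_kind,seed", [
    (4, "jc", 2), (5, "jc", 3), (6, "jc", 4), (4, "gtr", 5), (6, "gtr", 6),
])
def test_pruning_equals_exhaustive_state_enumeration(n, model_kind, seed):
    truth, aln = _sim(n, 30, seed, mean_root_to_tip=0.4)
    if model_kind == "gtr":
        model = pt.build_model("gtr", stationary=[0.3, 0.2, 0.25, 0.25],
                               gtr_rates=[1, 3, 0.5, 0.8, 2.5, 1])
    else:
        model = pt.build_model("jc")
    sr = _setup(truth, aln, model)
    got = lk.tree_loglik(truth, model, sr)
    want = brute_force_loglik(truth, aln, model)
    assert got == pytest.approx(want, abs=1e-10)


def test_pruning_with_gaps_and_site_rates_matches_enumeration():
    truth, aln = _sim(5, 20, 7, gap_fraction=0.15)
    model = pt.build_model("jc")
    rng = np.random.default_rng(0)
    sr = lk.SiteRates(rates=np.array([0.3, 1.0, 4.0]),
                      site_cat=rng.integers(3, size=aln.length))
    _setup(truth, aln, model, sr)
    got = lk.tree_loglik(truth, model, sr)
    want = brute_force_loglik(truth, aln, model, sr)
    assert got == pytest.approx(want, abs=1e-10)


def test_loglik_invariant_under_evaluation_edge():
    truth, aln = _sim(6, 40, 9)
    model = pt.build_model("jc")
    sr = _setup(truth, aln, model)
    reference = lk.tree_loglik(truth, model, sr)
    for node in truth.postorder():
        if node.parent is None:
            continue
        up = lk.compute_up_posterior(node, model, sr)
        ll = lk.edge_loglik(node.partial, up, node.length, model, sr)
        assert ll == pytest.approx(reference, abs=1e-8)


def test_up_posterior_on_three_leaf_tree_is_combine_of_other_two(jc_model):
    aln = pt.Alignment(names=list("ABC"), rows=["ACGT", "AGGT", "ACGA"],
                       alphabet="nt")
    root = pt.Node()
    for nm, ln in [("A", 0.1), ("B", 0.2), ("C", 0.15)]:
        root.add(pt.Node(nm, ln))
    tree = pt.Tree(root)
    sr = _setup(tree, aln, jc_model)
    a, b, c = root.children
    up = lk.compute_up_posterior(a, jc_model, sr)
    direct = lk.combine_children(b.partial, c.partial, b.length, c.length,
                                 jc_model, sr)
    assert np.allclose(up.vec, direct.vec, atol=1e-12)
    assert np.allclose(up.log_scale, direct.log_scale, atol=1e-12)


def test_scaled_representation_reconstructs_unscaled_pruning():
    """Site log-likelihoods from the normalized+log-scale representation
    equal an unscaled double-precision enumeration, site by site."""
    truth, aln = _sim(5, 15, 12)
    model = pt.build_model("jc")
    sr = _setup(truth, aln, model)
    got = lk.tree_site_logliks(truth, model, sr)
    want = brute_force_site_logliks(truth, aln, model)
    assert np.allclose(got, want, atol=1e-10)


# --------------------------------------------------------------------------
# Brent

def test_brent_quadratic_and_boundary_cases():
    assert lk.brent_minimize(lambda x: (x - 2) ** 2, 1.0, (1e-4, 10)) == \
        pytest.approx(2.0, abs=1e-4)
    # monotone increasing: settles on the lower bound
    assert lk.brent_minimize(lambda x: 3 * x, 5.0, (0.5, 10)) == \
        pytest.approx(0.5, abs=1e-3)
    # guess below the minimum bound
    assert lk.brent_minimize(lambda x: (x - 0.3) ** 2, 1e-6, (1e-4, 10)) == \
        pytest.approx(0.3, abs=1e-3)
    # guess sitting exactly on the upper bound still terminates
    assert lk.brent_minimize(lambda x: (x - 3.0) ** 2, 10.0, (1e-4, 10)) == \
        pytest.approx(3.0, abs=1e-3)


def test_brent_against_scipy_on_assorted_unimodal_functions():
    funcs = [lambda x: (x - 0.77) ** 4 + 0.1 * x,
             lambda x: -np.exp(-(x - 1.3) ** 2),
             lambda x: x - np.log(x)]
    for f in funcs:
        ours = lk.brent_minimize(f, 0.5, (1e-4, 10))
        ref = scipy.optimize.minimize_scalar(
            f, bounds=(1e-4, 10), method="bounded", options={"xatol": 1e-8}).x
        assert ours == pytest.approx(ref, abs=max(1e-3, 1e-2 * ref))


@pytest.mark.parametrize("p", [0.05, 0.1, 0.2, 0.3, 0.45, 0.6])
def test_branch_mle_matches_jc_closed_form(p):
    L = 1000
    k = round(p * L)
    row1 = "A" * L
    row2 = "C" * k + "A" * (L - k)
    m = pt.build_model("jc")
    sr = lk.SiteRates.uniform(L)
    p1 = lk.leaf_partial(row1, "ACGT")
    p2 = lk.leaf_partial(row2, "ACGT")
    t, ll = lk.optimize_branch(p1, p2, 0.1, m, sr)
    expected = -0.75 * np.log(1 - 4 * (k / L) / 3)
    assert t == pytest.approx(expected, abs=max(1e-4, 1e-3 * expected))


def test_optimize_branch_identical_children_hits_floor_and_never_decreases():
    m = pt.build_model("jc")
    L = 200
    sr = lk.SiteRates.uniform(L)
    p = lk.leaf_partial("ACGT" * 50, "ACGT")
    t, ll = lk.optimize_branch(p, p, 0.5, m, sr)
    assert t == pytest.approx(lk.MIN_BRANCH_LENGTH, abs=1e-6)
    ll_before = lk.edge_loglik(p, p, 0.5, m, sr)
    assert ll >= ll_before


def test_optimize_all_lengths_matches_joint_optimizer_and_is_monotone():
    truth, aln = _sim(6, 300, 17, mean_root_to_tip=0.4)
    model = pt.build_model("jc")
    sr = lk.SiteRates.uniform(aln.length)
    rng = np.random.default_rng(3)
    tree = truth
    for node in tree.postorder():
        if node.parent is not None:
            node.length = float(rng.uniform(0.01, 0.8))
    _setup(tree, aln, model, sr)
    lls = [lk.tree_loglik(tree, model, sr)]
    for _ in range(3):
        lk.optimize_all_lengths(tree, model, sr)
        lls.append(lk.tree_loglik(tree, model, sr))
    for a, b in zip(lls, lls[1:]):
        assert b >= a - 1e-9

    # independent joint optimization over all branch lengths at once
    edges = [n for n in tree.postorder() if n.parent is not None]
    opt_lens = [n.length for n in edges]

    def neg(x):
        for node, v in zip(edges, x):
            node.length = float(v)
        lk.recompute_partials(tree, model, sr)
        return -lk.tree_loglik(tree, model, sr)

    x0 = np.array([n.length for n in edges])
    res = scipy.optimize.minimize(neg, x0, method="L-BFGS-B",
                                  bounds=[(1e-4, 10)] * len(edges))
    assert lls[-1] >= -res.fun - 1e-3

    # converged pass is a fixed point
    for node, v in zip(edges, opt_lens):
        node.length = float(v)
    lk.recompute_partials(tree, model, sr)
    before = [n.length for n in edges]
    lk.optimize_all_lengths(tree, model, sr)
    after = [n.length for n in edges]
    assert max(abs(a - b) for a, b in zip(before, after)) < 5e-3
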