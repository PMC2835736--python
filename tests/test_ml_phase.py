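"""ML phase: NNI rounds, heuristics, GTR/CAT fitting, Gamma20, pipeline."""

import numpy as np
import pytest

import profiletree as pt
from profiletree import lik_engine as lk, me_phase, ml_phase
from conftest import random_resolved_tree


def _pipeline_input(n, L, seed, **kw):
    truth, aln = pt.simulate(pt.SimulationSpec(n_taxa=n, seq_length=L,
                                               seed=seed, **kw))
    tree = pt.minimum_evolution_tree(aln)
    return truth, aln, tree


def test_ml_nni_round_fixes_a_swapped_quartet_and_raises_loglik():
    truth, aln = pt.simulate(pt.SimulationSpec(n_taxa=8, seq_length=2000,
                                               seed=101, mean_root_to_tip=0.4))
    tree = truth.copy()
    node = next(n for n in tree.internal_edge_nodes()
                if n.parent.parent is not None)
    pt.Tree.swap_subtrees(node.children[1],
                          next(c for c in node.parent.children
                               if c is not node))
    model = pt.build_model("jc")
    sr = lk.SiteRates.uniform(aln.length)
    lk.assign_leaf_partials(tree, aln)
    lk.recompute_partials(tree, model, sr)
    lk.optimize_all_lengths(tree, model, sr)
    ll0 = lk.tree_loglik(tree, model, sr)
    state = ml_phase.SearchState(n_leaves=8)
    stats = ml_phase.ml_nni_round(tree, model, sr, state, heuristics_on=False)
    ll1 = lk.tree_loglik(tree, model, sr)
    assert stats["swaps"] >= 1
    assert ll1 > ll0
    assert pt.split_accuracy(tree, truth) == 1.0


def test_no_signal_star_data_changes_nothing():
    """All internal branches at the floor: no quartet improves materially."""
    truth = random_resolved_tree(10, seed=5, mean_depth=0.3)
    for n in truth.postorder():
        if n.parent is not None and not n.is_leaf:
            n.length = 1e-4
    _, aln = pt.simulate(pt.SimulationSpec(n_taxa=10, seq_length=300,
                                           seed=6, tree=truth.copy(),
                                           branch_floor=1e-5))
    tree = truth.copy()
    model = pt.build_model("jc")
    sr = lk.SiteRates.uniform(aln.length)
    lk.assign_leaf_partials(tree, aln)
    lk.recompute_partials(tree, model, sr)
    lk.optimize_all_lengths(tree, model, sr)
    state = ml_phase.SearchState(n_leaves=10)
    stats = ml_phase.ml_nni_round(tree, model, sr, state, heuristics_on=False)
    assert stats["max_gain"] <= ml_phase.NNI_CONVERGENCE_LL


def test_subtree_skipping_gating_rules():
    tree = random_resolved_tree(16, seed=8)
    node = next(tree.internal_edge_nodes().__iter__())
    state = ml_phase.SearchState(n_leaves=16)
    state.round = 1
    assert not ml_phase.should_skip_subtree(state, node)  # no history
    state.round = 4
    assert ml_phase.should_skip_subtree(state, node)      # quiet history
    state.subtree_improved[node.id] = 3                   # improved last round
    assert not ml_phase.should_skip_subtree(state, node)
    state.subtree_improved[node.id] = 1                   # long ago
    assert ml_phase.should_skip_subtree(state, node)
    # an adjacent significantly-improving NNI vetoes the skip
    state.nni_affected[node.parent.children[0].id] = 3
    assert not ml_phase.should_skip_subtree(state, node)


def test_star_test_margin_and_trivial_case():
    assert not ml_phase.star_test(100.0, 100.0)       # zero margin never skips
    assert not ml_phase.star_test(-50.0, -54.9)
    assert ml_phase.star_test(-50.0, -56.0)


def test_star_test_skips_strongly_resolved_quartet():
    """A long internal branch and plenty of sites trip the star test."""
    truth, aln = pt.simulate(pt.SimulationSpec(n_taxa=6, seq_length=1000,
                                               seed=12, mean_root_to_tip=0.5))
    tree = truth.copy()
    model = pt.build_model("jc")
    sr = lk.SiteRates.uniform(aln.length)
    lk.assign_leaf_partials(tree, aln)
    lk.recompute_partials(tree, model, sr)
    lk.optimize_all_lengths(tree, model, sr)
    state = ml_phase.SearchState(n_leaves=6)
    ml_phase.ml_nni_round(tree, model, sr, state, heuristics_on=False)
    stats = ml_phase.ml_nni_round(tree, model, sr, state, heuristics_on=True)
    assert stats["star_skips"] >= 1


def test_abandonment_drops_clearly_worse_alternates():
    """With strong signal both alternates fall > 5 LL units behind and the
    second optimization round runs on the current arrangement only; the
    node is still evaluated correctly (no swap)."""
    truth, aln = pt.simulate(pt.SimulationSpec(n_taxa=6, seq_length=3000,
                                               seed=14, mean_root_to_tip=0.5))
    tree = truth.copy()
    model = pt.build_model("jc")
    sr = lk.SiteRates.uniform(aln.length)
    lk.assign_leaf_partials(tree, aln)
    lk.recompute_partials(tree, model, sr)
    lk.optimize_all_lengths(tree, model, sr)
    node = tree.internal_edge_nodes()[0]
    A, B, C, Dnode, pD, tD = ml_phase._node_quartet(node, model, sr)
    lens0 = (A.length, B.length, C.length, tD, node.length)
    cur = ml_phase._optimize_quartet(A.partial, B.partial, C.partial, pD,
                                     lens0, model, sr)
    alt = ml_phase._optimize_quartet(
        A.partial, C.partial, B.partial, pD,
        (lens0[0], lens0[2], lens0[1], lens0[3], lens0[4]), model, sr)
    assert cur[1] - alt[1] > ml_phase.NNI_ABANDON_LL


def test_gtr_recovery_on_jc_data_is_near_uniform():
    truth, aln = pt.simulate(pt.SimulationSpec(n_taxa=10, seq_length=5000,
                                               seed=20, mean_root_to_tip=0.4))
    tree = truth.copy()
    model = pt.build_model("jc")
    sr = lk.SiteRates.uniform(aln.length)
    lk.assign_leaf_partials(tree, aln)
    lk.recompute_partials(tree, model, sr)
    lk.optimize_all_lengths(tree, model, sr)
    fitted = ml_phase.optimize_gtr_rates(tree, aln, sr)
    rates = fitted.gtr_rates
    assert rates.max() / rates.min() < 1.15


def test_gtr_recovery_of_transition_bias():
    truth, aln = pt.simulate(pt.SimulationSpec(n_taxa=10, seq_length=5000,
                                               seed=21, model="hky", kappa=4.0,
                                               rate_cv=1e-3,
                                               mean_root_to_tip=0.4))
    tree = truth.copy()
    model = pt.build_model("jc")
    sr = lk.SiteRates.uniform(aln.length)
    lk.assign_leaf_partials(tree, aln)
    lk.recompute_partials(tree, model, sr)
    lk.optimize_all_lengths(tree, model, sr)
    ll0 = lk.tree_loglik(tree, model, sr)
    fitted = ml_phase.optimize_gtr_rates(tree, aln, sr)
    ll1 = lk.tree_loglik(tree, fitted, sr)
    assert ll1 >= ll0
    r = fitted.gtr_rates  # order AC, AG, AT, CG, CT, GT
    transitions = [r[1], r[4]]
    transversions = [r[0], r[2], r[3], r[5]]
    assert min(transitions) > max(transversions)
    ratio = np.mean(transitions) / np.mean(transversions)
    assert ratio == pytest.approx(4.0, rel=0.2)


def test_gtr_rejects_protein_data():
    _, aln = pt.simulate(pt.SimulationSpec(n_taxa=6, seq_length=100,
                                           model="jtt", seed=2))
    with pytest.raises(ValueError):
        ml_phase.optimize_gtr_rates(pt.Tree(pt.Node()), aln)


def test_cat_ladder_and_rescaled_mean():
    ladder = ml_phase.rate_ladder(20)
    assert len(ladder) == 20
    assert ladder[0] == pytest.approx(0.05) and ladder[-1] == pytest.approx(20.0)
    assert np.all(np.diff(ladder) > 0)
    ratios = ladder[1:] / ladder[:-1]
    assert np.allclose(ratios, ratios[0])  # log-spaced

    truth, aln = pt.simulate(pt.SimulationSpec(n_taxa=10, seq_length=500,
                                               seed=30))
    tree = truth.copy()
    model = pt.build_model("jc")
    sr = lk.SiteRates.uniform(aln.length)
    lk.assign_leaf_partials(tree, aln)
    lk.recompute_partials(tree, model, sr)
    assignment = ml_phase.assign_cat_rates(tree, aln, model)
    assigned = assignment.site_rates().per_site
    assert float(assigned.mean()) == pytest.approx(1.0, abs=1e-6)


def test_cat_assigns_low_rate_to_invariant_column():
    """Needs a tree long enough for the data to beat the peaked prior."""
    truth, aln = pt.simulate(pt.SimulationSpec(n_taxa=64, seq_length=300,
                                               seed=31))
    rows = [r[:-1] + "A" for r in aln.rows]  # force one invariant column
    aln2 = pt.Alignment(names=aln.names, rows=rows, alphabet="nt")
    tree = truth.copy()
    model = pt.build_model("jc")
    lk.assign_leaf_partials(tree, aln2)
    sr = lk.SiteRates.uniform(aln2.length)
    lk.recompute_partials(tree, model, sr)
    assignment = ml_phase.assign_cat_rates(tree, aln2, model)
    assert assignment.site_cat[-1] <= 2  # among the lowest three rates


def test_cat_rate_ranks_recover_simulated_rate_classes():
    """Sites simulated at relative rates 0.2 / 1 / 5 get monotone medians."""
    base = random_resolved_tree(16, seed=40, mean_depth=0.4)
    blocks = []
    for i, r in enumerate((0.2, 1.0, 5.0)):
        scaled = base.copy()
        for n in scaled.postorder():
            if n.length is not None:
                n.length *= r
        _, aln_r = pt.simulate(pt.SimulationSpec(
            n_taxa=16, seq_length=300, seed=41 + i, tree=scaled,
            rate_cv=1e-3, branch_floor=1e-9))
        blocks.append(aln_r)
    rows = ["".join(b.row(name) for b in blocks) for name in blocks[0].names]
    aln = pt.Alignment(names=blocks[0].names, rows=rows, alphabet="nt")
    tree = base.copy()
    model = pt.build_model("jc")
    lk.assign_leaf_partials(tree, aln)
    sr = lk.SiteRates.uniform(aln.length)
    lk.recompute_partials(tree, model, sr)
    lk.optimize_all_lengths(tree, model, sr)
    assignment = ml_phase.assign_cat_rates(tree, aln, model)
    pre = assignment.rates[assignment.site_cat]
    med = [np.median(pre[i * 300:(i + 1) * 300]) for i in range(3)]
    assert med[0] < med[1] < med[2]


def test_gamma20_degenerate_no_rate_variation():
    truth, aln = pt.simulate(pt.SimulationSpec(n_taxa=12, seq_length=800,
                                               seed=50, rate_cv=1e-3,
                                               mean_root_to_tip=0.4))
    tree = truth.copy()
    model = pt.build_model("jc")
    lk.assign_leaf_partials(tree, aln)
    sr = lk.SiteRates.uniform(aln.length)
    lk.recompute_partials(tree, model, sr)
    lk.optimize_all_lengths(tree, model, sr)
    assignment = ml_phase.assign_cat_rates(tree, aln, model)
    res = ml_phase.gamma20_rescale(assignment, tree)
    assert res.shape >= 10.0
    assert res.scale_factor == pytest.approx(1.0, rel=0.2)
    assert res.tree_length > 0 and np.isfinite(res.tree_length)
    # the mixture dominates its own alpha -> infinity vertex limit
    ll_vertex = ml_phase.gamma20_loglik(assignment, 1e6, res.scale_factor)
    assert res.loglik >= ll_vertex - 1e-6


def test_subtree_skipping_prunes_most_nodes_once_converged():
    """On a converged larger tree the skipping heuristic avoids visiting
    at least half of the internal nodes in the last heuristic round."""
    truth, aln = pt.simulate(pt.SimulationSpec(n_taxa=64, seq_length=500,
                                               seed=3))
    tree = pt.minimum_evolution_tree(aln)
    res = pt.run_ml_pipeline(tree, aln)
    assert res.converged
    eligible = 64 - 3  # internal edges
    heuristic_rounds = res.round_stats[1:-1]  # drop first and safety rounds
    last = heuristic_rounds[-1]
    assert last["skipped_subtrees"] > 0
    assert 1.0 - last["visited"] / eligible >= 0.5


def test_pipeline_monotone_trace_and_accuracy_improvement():
    truth, aln, tree = _pipeline_input(16, 800, 60)
    me_acc = pt.split_accuracy(tree, truth)
    result = pt.run_ml_pipeline(tree, aln)
    labels = [lab for lab, _ in result.trace]
    lls = dict(result.trace)
    # monotone within the simplified-model segment
    assert lls["nni_round_1"] >= lls["lengths_simple"] - 1e-6
    # monotone from the CAT switch onwards (fixed model and rates)
    cat_idx = labels.index("cat_switch")
    tail = [ll for _, ll in result.trace[cat_idx:]]
    for a, b in zip(tail, tail[1:]):
        assert b >= a - (1e-8 * abs(a) + 1e-9)
    assert result.nni_rounds <= ml_phase.SearchState(16).max_rounds + 1
    assert pt.split_accuracy(result.tree, truth) >= me_acc
    for node in result.tree.postorder():
        if node.parent is not None:
            assert node.length >= lk.MIN_BRANCH_LENGTH - 1e-12


def test_pipeline_nocat_monotone_and_improves_on_me_lengths():
    truth, aln, tree = _pipeline_input(16, 500, 61)
    model = pt.build_model("jc")
    sr = lk.SiteRates.uniform(aln.length)
    lk.assign_leaf_partials(tree, aln)
    lk.recompute_partials(tree, model, sr)
    ll_me = lk.tree_loglik(tree, model, sr)
    result = pt.run_ml_pipeline(tree, aln, use_cat=False)
    lls = [ll for _, ll in result.trace]
    for a, b in zip(lls, lls[1:]):
        assert b >= a - (1e-8 * abs(a) + 1e-9)
    assert lls[-1] >= ll_me


def test_mlacc_forces_extra_rounds_and_is_monotone():
    truth, aln, tree = _pipeline_input(8, 300, 62)
    result = pt.run_ml_pipeline(tree, aln, use_cat=False, mlacc=2)
    lls = [ll for _, ll in result.trace]
    for a, b in zip(lls, lls[1:]):
        assert b >= a - (1e-8 * abs(a) + 1e-9)
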