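"""Shared fixtures and independent oracles for the test suite."""

import itertools

import numpy as np
import pytest
from hypothesis import settings

import profiletree as pt

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from profiletree.subst_models import transition_matrix


# --------------------------------------------------------------------------
# Independent likelihood oracle: exhaustive summation over internal states.

def brute_force_site_logliks(tree, aln, model, site_rates=None):
    """Per-site log-likelihood by enumerating all internal-state assignments.

    Independent of the pruning engine: walks edges explicitly and sums
    pi(root state) * prod P(parent->child | t * r_site) over every
    assignment of states to internal nodes.  Gap characters contribute a
    factor of 1.  Exponential in the number of internal nodes; tiny trees
    only.
    """
    letters = aln.letters
    index = {c: i for i, c in enumerate(letters)}
    rows = dict(zip(aln.names, aln.rows))
    internals = [n for n in tree.postorder() if not n.is_leaf]
    a = model.n_states
    L = aln.length
    rates = np.ones(L) if site_rates is None else np.asarray(site_rates.per_site)
    out = np.empty(L)
    for site in range(L):
        r = rates[site]
        P = {}
        for node in tree.postorder():
            if node.parent is not None:
                P[node.id] = transition_matrix(model, node.length * r)
        total = 0.0
        for assign in itertools.product(range(a), repeat=len(internals)):
            state = {n.id: s for n, s in zip(internals, assign)}
            term = model.stationary[state[tree.root.id]]
            for node in tree.postorder():
                if node.parent is None:
                    continue
                su = state[node.parent.id]
                if node.is_leaf:
                    ch = rows[node.name][site]
                    if ch in index:
                        term *= P[node.id][su, index[ch]]
                else:
                    term *= P[node.id][su, state[node.id]]
            total += term
        out[site] = np.log(total)
    return out


def brute_force_loglik(tree, aln, model, site_rates=None):
    return float(brute_force_site_logliks(tree, aln, model, site_rates).sum())


# --------------------------------------------------------------------------
# Path-distance oracle for NJ / additivity tests.

def leaf_path_distances(tree):
    """(names, matrix) of summed branch lengths between every leaf pair."""
    leaves = tree.leaves()
    names = [l.name for l in leaves]

    def path_to_root(node):
        chain = {}
        dist = 0.0
        while node is not None:
            chain[node.id] = dist
            dist += node.length or 0.0
            node = node.parent
        return chain

    chains = [path_to_root(l) for l in leaves]
    n = len(leaves)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = chains[i].keys() & chains[j].keys()
            D[i, j] = D[j, i] = min(chains[i][k] + chains[j][k]
                                    for k in shared)
    return names, D


# --------------------------------------------------------------------------
# Small reusable fixtures.

@pytest.fixture
def tiny_nt_alignment():
    return pt.Alignment(names=["A", "B", "C"],
                        rows=["ACGT", "ACGT", "ACGA"], alphabet="nt")


@pytest.fixture
def sim12():
    """Moderate 12-taxon nucleotide simulation shared by several tests."""
    spec = pt.SimulationSpec(n_taxa=12, seq_length=600, seed=42)
    return pt.simulate(spec)


@pytest.fixture
def jc_model():
    return pt.build_model("jc")


def random_resolved_tree(n, seed, mean_depth=0.5):
    rng = np.random.default_rng(seed)
    return pt.yule_tree(n, rng, mean_root_to_tip=mean_depth)
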