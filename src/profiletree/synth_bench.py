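"""Synthetic alignments on random trees, and split-accuracy scoring.

The generator emulates a 16S-like simulation protocol: a random pure-birth
tree rescaled to a target mean root-to-tip path length, branch lengths
floored at 0.001 substitutions/site, per-site evolutionary rates drawn
from a 16-category discretization of a gamma distribution with coefficient
of variation 0.7 (shape = 1/cv^2), and characters evolved root-to-tip from
the model's transition probabilities.  There is no indel process; gaps, if
requested, are i.i.d. masking.

Topological accuracy is the proportion of the true tree's nontrivial
splits recovered by the inferred tree (the converse of the Robinson-Foulds
distance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.special
import scipy.stats

from .msa_io import Alignment
from .subst_models import SubstitutionModel, build_model, transition_matrix
from .tree import Node, Tree, collapse_root_bifurcation

DEFAULT_RATE_CV = 0.7
DEFAULT_N_RATE_CATEGORIES = 16
DEFAULT_BRANCH_FLOOR = 0.001
DEFAULT_MEAN_ROOT_TO_TIP = 1.0


@dataclass
class SimulationSpec:
    """Study conditions for one simulated dataset."""

    n_taxa: int
    seq_length: int
    model: str = "jc"                 # jc | hky | jtt
    kappa: float = 1.0                # hky transition/transversion rate ratio
    base_freqs: Optional[np.ndarray] = None
    rate_cv: float = DEFAULT_RATE_CV
    n_rate_categories: int = DEFAULT_N_RATE_CATEGORIES
    branch_floor: float = DEFAULT_BRANCH_FLOOR
    mean_root_to_tip: float = DEFAULT_MEAN_ROOT_TO_TIP
    gap_fraction: float = 0.0
    tree: Optional[Tree] = None       # user tree overrides the birth process
    seed: int = 0

    @property
    def gamma_shape(self) -> float:
        return 1.0 / self.rate_cv ** 2


def _hky_model(kappa: float, base_freqs) -> SubstitutionModel:
    pi = np.full(4, 0.25) if base_freqs is None else np.asarray(base_freqs, float)
    # alphabet ACGT: transitions are AG and CT
    rates = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
    return build_model("gtr", stationary=pi, gtr_rates=rates)


def _sim_model(spec: SimulationSpec) -> SubstitutionModel:
    if spec.model == "jc":
        return build_model("jc")
    if spec.model == "hky":
        return _hky_model(spec.kappa, spec.base_freqs)
    if spec.model == "jtt":
        return build_model("jtt")
    raise ValueError(f"unknown simulation model: {spec.model!r}")


def yule_tree(n_taxa: int, rng: np.random.Generator,
              mean_root_to_tip: float = DEFAULT_MEAN_ROOT_TO_TIP) -> Tree:
    """Pure-birth tree rescaled so the mean root-to-tip path length equals
    `mean_root_to_tip` substitutions/site."""
    root = Node()
    active = [root.add(Node(length=0.0)), root.add(Node(length=0.0))]
    while len(active) < n_taxa:
        dt = rng.exponential(1.0 / len(active))
        for lineage in active:
            lineage.length += dt
        parent = active.pop(rng.integers(len(active)))
        active.append(parent.add(Node(length=0.0)))
        active.append(parent.add(Node(length=0.0)))
    dt = rng.exponential(1.0 / len(active))
    for lineage in active:
        lineage.length += dt
    for i, leaf in enumerate(active):
        leaf.name = f"t{i + 1}"
    # depth of every leaf, for rescaling
    depths = []

    def walk(node: Node, depth: float) -> None:
        depth += node.length or 0.0
        if node.is_leaf:
            depths.append(depth)
        for c in node.children:
            walk(c, depth)

    walk(root, 0.0)
    scale = mean_root_to_tip / float(np.mean(depths))
    top = collapse_root_bifurcation(root)
    for node in Tree(top).postorder():
        if node.length is not None:
            node.length *= scale
    return Tree(top)


def discrete_gamma_rates(shape: float, K: int) -> np.ndarray:
    """K equal-probability categories, each represented by its mean rate
    (normalized to mean exactly 1)."""
    edges = scipy.stats.gamma.ppf(np.linspace(0.0, 1.0, K + 1), a=shape,
                                  scale=1.0 / shape)
    # mean within [lo, hi) of gamma(shape, 1/shape), via the shape+1 identity
    upper = scipy.special.gammainc(shape + 1.0, edges[1:] * shape)
    lower = scipy.special.gammainc(shape + 1.0, edges[:-1] * shape)
    rates = K * (upper - lower)
    return rates / rates.mean()


def _evolve(parent_states: np.ndarray, t: float, rates: np.ndarray,
            model: SubstitutionModel, rng: np.random.Generator) -> np.ndarray:
    """Sample child states per site given parent states and branch length."""
    child = np.empty_like(parent_states)
    u = rng.random(len(parent_states))
    for r in np.unique(rates):
        idx = np.nonzero(rates == r)[0]
        P = transition_matrix(model, t * r)
        cum = np.cumsum(P, axis=1)
        rows = cum[parent_states[idx]]
        child[idx] = (rows < u[idx, None]).sum(axis=1)
    return np.minimum(child, model.n_states - 1)


def simulate(spec: SimulationSpec) -> tuple[Tree, Alignment]:
    """Simulated (true tree, alignment) under the spec; deterministic per seed."""
    if spec.n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    if spec.seq_length < 1:
        raise ValueError("need at least 1 position")
    rng = np.random.default_rng(spec.seed)
    model = _sim_model(spec)
    tree = spec.tree if spec.tree is not None else \
        yule_tree(spec.n_taxa, rng, spec.mean_root_to_tip)
    for node in tree.postorder():
        if node.length is not None and node.length < spec.branch_floor:
            node.length = spec.branch_floor

    category_rates = discrete_gamma_rates(spec.gamma_shape,
                                          spec.n_rate_categories)
    site_rates = category_rates[
        rng.integers(spec.n_rate_categories, size=spec.seq_length)]

    letters = model.letters
    states: dict[int, np.ndarray] = {}
    states[tree.root.id] = rng.choice(model.n_states, size=spec.seq_length,
                                      p=model.stationary)
    rows: dict[str, str] = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        states[node.id] = _evolve(states[node.parent.id], node.length,
                                  site_rates, model, rng)
        if node.is_leaf:
            seq = "".join(letters[s] for s in states[node.id])
            if spec.gap_fraction > 0.0:
                mask = rng.random(spec.seq_length) < spec.gap_fraction
                seq = "".join("-" if m else c for c, m in zip(seq, mask))
            rows[node.name] = seq
    names = tree.leaf_names()
    aln = Alignment(names=names, rows=[rows[n] for n in names],
                    alphabet="nt" if model.alphabet == "nt" else "aa")
    return tree, aln


def split_accuracy(inferred: Tree, truth: Tree) -> float:
    """Fraction of the true tree's nontrivial splits present in `inferred`."""
    if set(inferred.leaf_names()) != set(truth.leaf_names()):
        raise ValueError("trees have different leaf sets")
    true_splits = truth.splits()
    if not true_splits:
        return 1.0
    return len(true_splits & inferred.splits()) / len(true_splits)
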