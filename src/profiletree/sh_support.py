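"""SH-like local support values from RELL site resampling.

For every internal edge the per-site log-likelihoods of the current
topology (current, already-optimized branch lengths) and of the two NNI
alternatives (quartet branch lengths re-optimized for up to two rounds)
are compared over 1,000 multinomial site resamples, without re-optimizing
anything per replicate (RELL).  Each topology's resampled log-likelihood
is centered by its own expected resampled value - which equals its
observed log-likelihood - so the comparison reduces to the fraction of
replicates in which the current topology's resampled log-likelihood
strictly exceeds both alternatives'.

The same replicate weight matrix is shared across all edges; independence
across edges is not claimed.  If there are poorly resolved nodes nearby
the support values should be interpreted cautiously, because a
high-likelihood alternate topology might not have been considered.
"""

from __future__ import annotations

import math

import numpy as np

from . import lik_engine as lk
from .lik_engine import SiteRates
from .ml_phase import _node_quartet, _optimize_quartet
from .subst_models import SubstitutionModel
from .tree import Node, Tree

N_RESAMPLES = 1000


def bootstrap_sd(p: float, B: int) -> float:
    """Sampling standard deviation of a support estimated from B replicates."""
    return math.sqrt(p * (1.0 - p) / B)


def _edge_site_lls(node: Node, model, site_rates) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site log-likelihoods for the current and two NNI topologies."""
    A, B, C, Dnode, pD, tD = _node_quartet(node, model, site_rates)
    pA, pB, pC = A.partial, B.partial, C.partial
    tA, tB, tC, tint = A.length, B.length, C.length, node.length

    AB = lk.combine_children(pA, pB, tA, tB, model, site_rates)
    CD = lk.combine_children(pC, pD, tC, tD, model, site_rates)
    ll_cur = lk.edge_site_logliks(AB, CD, tint, model, site_rates)

    out = [ll_cur]
    for q2, q3, lens in (
            (pC, pB, (tA, tC, tB, tD, tint)),   # (A,C | B,D)
            (pD, pB, (tA, tD, tB, tC, tint))):  # (A,D | B,C)
        lens2, _ = _optimize_quartet(pA, q2, q3,
                                     pD if q2 is pC else pC,
                                     lens, model, site_rates, rounds=2)
        nA, n2, n3, n4, nint = lens2
        J1 = lk.combine_children(pA, q2, nA, n2, model, site_rates)
        J2 = lk.combine_children(q3, pD if q2 is pC else pC, n3, n4,
                                 model, site_rates)
        out.append(lk.edge_site_logliks(J1, J2, nint, model, site_rates))
    return tuple(out)


def resample_weights(L: int, seed: int, n_resamples: int = N_RESAMPLES) -> np.ndarray:
    """Shared multinomial site-weight matrix, shape (n_resamples, L)."""
    rng = np.random.default_rng(seed)
    return rng.multinomial(L, np.full(L, 1.0 / L), size=n_resamples).astype(float)


def local_supports(tree: Tree, model: SubstitutionModel,
                   site_rates: SiteRates, seed: int = 0,
                   n_resamples: int = N_RESAMPLES) -> dict[int, float]:
    """SH-like support for every internal edge; deterministic given seed.

    Supports are stored on each internal node (``node.support``) and also
    returned keyed by node id."""
    weights = None
    supports: dict[int, float] = {}
    for node in tree.internal_edge_nodes():
        ll_cur, ll_alt1, ll_alt2 = _edge_site_lls(node, model, site_rates)
        if weights is None:
            weights = resample_weights(len(ll_cur), seed, n_resamples)
        r_cur = weights @ ll_cur
        r_alt1 = weights @ ll_alt1
        r_alt2 = weights @ ll_alt2
        wins = (r_cur > r_alt1) & (r_cur > r_alt2)
        support = float(wins.mean())
        node.support = support
        supports[node.id] = support
    return supports
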