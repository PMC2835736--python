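"""Reversible substitution models: JC, GTR (nucleotide) and JTT (protein).

A model is a stationary distribution pi together with a reversible rate
matrix Q (rows sum to zero) scaled to one expected substitution per unit
time, ``-sum_i pi_i Q_ii = 1``.  Transition probabilities come from the
eigendecomposition ``Q = V diag(lambda) V^-1``, computed on the
pi-symmetrized form for numerical stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from ._jtt_data import JTT_EXCHANGEABILITIES, JTT_FREQUENCIES, JTT_ORDER
from .msa_io import AA_ALPHABET, NT_ALPHABET

# GTR exchangeability order for the six nucleotide conversions.
GTR_PAIRS = ("AC", "AG", "AT", "CG", "CT", "GT")


@dataclass
class SubstitutionModel:
    kind: str                      # "jc", "gtr" or "jtt"
    alphabet: str                  # "nt" or "aa"
    stationary: np.ndarray         # (a,)
    rate_matrix: np.ndarray        # (a, a), unit expected rate
    eigenvalues: np.ndarray        # (a,)
    V: np.ndarray                  # (a, a)
    Vinv: np.ndarray               # (a, a)
    gtr_rates: np.ndarray | None = None   # 6 exchangeabilities (nt GTR)
    _pcache: dict = field(default_factory=dict, repr=False)

    @property
    def n_states(self) -> int:
        return len(self.stationary)

    @property
    def letters(self) -> str:
        return NT_ALPHABET if self.alphabet == "nt" else AA_ALPHABET


def _exchangeability_matrix(letters: str, pairs, rates) -> np.ndarray:
    a = len(letters)
    S = np.zeros((a, a))
    for pair, r in zip(pairs, rates):
        i, j = letters.index(pair[0]), letters.index(pair[1])
        S[i, j] = S[j, i] = r
    return S


def _jtt_exchangeabilities() -> np.ndarray:
    a = 20
    S = np.zeros((a, a))
    k = 0
    for j in range(a):          # column-major lower triangle
        for i in range(j + 1, a):
            S[i, j] = S[j, i] = JTT_EXCHANGEABILITIES[k]
            k += 1
    # Reorder from the published ordering to our alphabet ordering.
    perm = [JTT_ORDER.index(c) for c in AA_ALPHABET]
    return S[np.ix_(perm, perm)]


def build_model(kind: str, stationary=None, gtr_rates=None) -> SubstitutionModel:
    """Assemble, normalize and eigendecompose a reversible model.

    ``stationary`` defaults to uniform (JC) or the JTT equilibrium
    frequencies (JTT); for GTR pass the empirical base frequencies.
    ``gtr_rates`` are the six exchangeabilities in :data:`GTR_PAIRS` order.
    """
    kind = kind.lower()
    if kind == "jc":
        alphabet, a = "nt", 4
        pi = np.full(a, 0.25) if stationary is None else np.asarray(stationary, float)
        S = _exchangeability_matrix(NT_ALPHABET, GTR_PAIRS, [1.0] * 6)
        rates = None
    elif kind == "gtr":
        alphabet, a = "nt", 4
        if stationary is None:
            raise ValueError("GTR requires stationary frequencies")
        pi = np.asarray(stationary, float)
        rates = np.ones(6) if gtr_rates is None else np.asarray(gtr_rates, float)
        if np.any(rates <= 0):
            raise ValueError("GTR exchangeabilities must be positive")
        S = _exchangeability_matrix(NT_ALPHABET, GTR_PAIRS, rates)
    elif kind == "jtt":
        alphabet, a = "aa", 20
        pi = (np.asarray(JTT_FREQUENCIES, float)[
                  [JTT_ORDER.index(c) for c in AA_ALPHABET]]
              if stationary is None else np.asarray(stationary, float))
        S = _jtt_exchangeabilities()
        rates = None
    else:
        raise ValueError(f"unknown model kind: {kind!r}")

    if np.any(pi <= 0):
        raise ValueError("stationary frequencies must all be positive")
    pi = pi / pi.sum()

    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(pi, np.diag(Q))
    Q /= mu

    # Eigendecomposition via the symmetric similarity transform
    # B = diag(sqrt(pi)) Q diag(1/sqrt(pi)).
    sq = np.sqrt(pi)
    B = (Q * sq[:, None]) / sq[None, :]
    lam, U = scipy.linalg.eigh((B + B.T) / 2.0)
    V = U / sq[:, None]
    Vinv = U.T * sq[None, :]

    return SubstitutionModel(kind=kind, alphabet=alphabet, stationary=pi,
                             rate_matrix=Q, eigenvalues=lam, V=V, Vinv=Vinv,
                             gtr_rates=None if rates is None else np.asarray(rates, float))


def transition_matrix(model: SubstitutionModel, t: float) -> np.ndarray:
    """P(t) = V exp(lambda t) V^-1, clipped to [0, 1]; rows sum to 1."""
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    key = round(float(t), 12)
    P = model._pcache.get(key)
    if P is None:
        P = (model.V * np.exp(model.eigenvalues * t)) @ model.Vinv
        np.clip(P, 0.0, 1.0, out=P)
        if len(model._pcache) > 4096:
            model._pcache.clear()
        model._pcache[key] = P
    return P


def transition_matrices(model: SubstitutionModel, ts) -> np.ndarray:
    """Batched P(t) for an array of branch lengths, shape (len(ts), a, a)."""
    ts = np.asarray(ts, float)
    E = np.exp(np.multiply.outer(ts, model.eigenvalues))     # (k, a)
    P = np.einsum("xe,ke,ey->kxy", model.V, E, model.Vinv)
    np.clip(P, 0.0, 1.0, out=P)
    return P


def empirical_frequencies(aln) -> np.ndarray:
    """Character frequencies over non-gap positions, with a small pseudocount."""
    letters = aln.letters
    counts = np.ones(len(letters))  # pseudocount keeps frequencies positive
    index = {c: i for i, c in enumerate(letters)}
    for row in aln.rows:
        for ch in row:
            i = index.get(ch)
            if i is not None:
                counts[i] += 1
    return counts / counts.sum()
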