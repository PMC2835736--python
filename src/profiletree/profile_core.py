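"""Profiles of subtrees, profile dissimilarity and log-corrected distances.

The minimum-evolution phase represents every subtree by a profile: an L x a
matrix of per-position character frequencies plus a per-position weight in
[0, 1] giving the fraction of non-gap contribution.  Distances between
subtrees are computed directly between profiles, which is what lets the
search avoid maintaining an all-pairs distance matrix.

Distance corrections
--------------------
Raw dissimilarities are mapped to additive evolutionary distances by a log
correction: Jukes-Cantor ``-3/4 ln(1 - 4d/3)`` for nucleotides and a
scoredist-style single-log form ``-1.3 ln(1 - d)`` for amino acids, where
the amino-acid ``d`` averages a dissimilarity matrix derived from BLOSUM45.
Both corrections are capped at 3.0 substitutions/site to keep arithmetic
finite past saturation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .msa_io import AA_ALPHABET, Alignment, NT_ALPHABET

logger = logging.getLogger(__name__)

MAX_CORRECTED_DISTANCE = 3.0
_AA_LOG_FACTOR = 1.3


@dataclass
class Profile:
    """Per-position character frequencies with per-position weights.

    Profiles are treated as immutable once built, which lets distance
    computations cache the weighted frequencies (and their product with a
    dissimilarity matrix) per profile."""

    freq: np.ndarray    # (L, a); rows with weight > 0 sum to 1
    weight: np.ndarray  # (L,) in [0, 1]
    _wf: np.ndarray | None = None
    _wfD: np.ndarray | None = None
    _wfD_key: int | None = None

    @property
    def length(self) -> int:
        return self.freq.shape[0]

    def weighted_freq(self) -> np.ndarray:
        if self._wf is None:
            self._wf = self.freq * self.weight[:, None]
        return self._wf

    def weighted_freq_dot(self, D: np.ndarray) -> np.ndarray:
        if self._wfD is None or self._wfD_key != id(D):
            self._wfD = self.weighted_freq() @ D
            self._wfD_key = id(D)
        return self._wfD


def leaf_profile(row: str, letters: str) -> Profile:
    """Indicator profile of one aligned sequence; gaps get weight 0."""
    L, a = len(row), len(letters)
    freq = np.zeros((L, a))
    weight = np.zeros(L)
    index = {c: i for i, c in enumerate(letters)}
    for pos, ch in enumerate(row):
        i = index.get(ch)
        if i is not None:
            freq[pos, i] = 1.0
            weight[pos] = 1.0
    return Profile(freq=freq, weight=weight)


def average_profiles(p1: Profile, p2: Profile) -> Profile:
    """Unweighted (child-symmetric), gap-aware average of two profiles.

    Frequencies are combined in proportion to the children's weights (a
    position covered in only one child copies that child); the new weight
    is the plain mean of the two weights, which is what makes the join
    "unweighted" across subtrees of different sizes.
    """
    if p1.freq.shape != p2.freq.shape:
        raise ValueError("profiles have mismatched dimensions")
    wsum = p1.weight + p2.weight
    denom = np.where(wsum > 0, wsum, 1.0)
    freq = (p1.freq * p1.weight[:, None] + p2.freq * p2.weight[:, None]) / denom[:, None]
    return Profile(freq=freq, weight=wsum / 2.0)


def profile_dissimilarity(p1: Profile, p2: Profile, D: np.ndarray) -> float:
    """Average per-position dissimilarity ``f1^T D f2`` between profiles.

    Positions are weighted by ``w1*w2`` so that positions lacking coverage
    in either profile are ignored.  With no overlapping coverage at all the
    distance is saturated (treated as maximal) and a warning is logged.
    """
    if p1.freq.shape != p2.freq.shape:
        raise ValueError("profiles have mismatched dimensions")
    denom = float(np.dot(p1.weight, p2.weight))
    if denom <= 0.0:
        logger.warning("profiles share no covered positions; "
                       "distance treated as saturated")
        return float(D.max())
    # w1 w2 f1^T D f2 summed over positions == (w1 f1)^T D (w2 f2) summed
    num = float(np.dot(p1.weighted_freq_dot(D).ravel(),
                       p2.weighted_freq().ravel()))
    return num / denom


# --------------------------------------------------------------------------
# Dissimilarity matrices

def nt_dissimilarity_matrix() -> np.ndarray:
    """0/1 mismatch matrix for nucleotides."""
    return 1.0 - np.eye(4)


def _jtt_background() -> np.ndarray:
    from ._jtt_data import JTT_FREQUENCIES, JTT_ORDER
    perm = [JTT_ORDER.index(c) for c in AA_ALPHABET]
    return np.asarray(JTT_FREQUENCIES, float)[perm]


def aa_dissimilarity_matrix() -> np.ndarray:
    """Amino-acid dissimilarity derived from the BLOSUM45 similarity matrix.

    BLOSUM45 log-odds scores ``b_ij`` (1/3-bit units) are mapped to a
    similarity scale ``S_ij = 2^(b_ij/3)``, normalized by the geometric mean
    of the self-similarities, ``D_ij = 1 - S_ij / sqrt(S_ii S_jj)``, and
    finally rescaled so the background-frequency-weighted mean off-diagonal
    dissimilarity is 1.  The diagonal is exactly zero.
    """
    blosum = substitution_matrices.load("BLOSUM45")
    a = len(AA_ALPHABET)
    b = np.empty((a, a))
    for i, ci in enumerate(AA_ALPHABET):
        for j, cj in enumerate(AA_ALPHABET):
            b[i, j] = blosum[ci, cj]
    S = np.power(2.0, b / 3.0)
    diag = np.sqrt(np.diag(S))
    D = 1.0 - S / np.outer(diag, diag)
    np.fill_diagonal(D, 0.0)
    pi = _jtt_background()
    W = np.outer(pi, pi)
    np.fill_diagonal(W, 0.0)
    D /= (W * D).sum() / W.sum()
    return D


def dissimilarity_matrix(alphabet: str) -> np.ndarray:
    return nt_dissimilarity_matrix() if alphabet == "nt" else aa_dissimilarity_matrix()


# --------------------------------------------------------------------------
# Log corrections

def log_correct_nt(d: float) -> float:
    """Jukes-Cantor correction, capped at MAX_CORRECTED_DISTANCE."""
    arg = 1.0 - 4.0 * d / 3.0
    if arg <= np.exp(-MAX_CORRECTED_DISTANCE / 0.75):
        return MAX_CORRECTED_DISTANCE
    return min(-0.75 * np.log(arg), MAX_CORRECTED_DISTANCE)


def log_correct_aa(d: float) -> float:
    """Scoredist-style single-log correction, capped."""
    arg = 1.0 - d
    if arg <= np.exp(-MAX_CORRECTED_DISTANCE / _AA_LOG_FACTOR):
        return MAX_CORRECTED_DISTANCE
    return min(-_AA_LOG_FACTOR * np.log(arg), MAX_CORRECTED_DISTANCE)


def log_correct(d: float, alphabet: str) -> float:
    return log_correct_nt(d) if alphabet == "nt" else log_correct_aa(d)


def corrected_profile_distance(p1: Profile, p2: Profile, D: np.ndarray,
                               alphabet: str) -> float:
    return log_correct(profile_dissimilarity(p1, p2, D), alphabet)


# --------------------------------------------------------------------------
# All-pairs matrix

def make_matrix(aln: Alignment) -> np.ndarray:
    """Symmetric matrix of log-corrected pairwise leaf-profile distances."""
    if aln.n < 2:
        raise ValueError("need at least two sequences")
    letters = aln.letters
    D = dissimilarity_matrix(aln.alphabet)
    profiles = [leaf_profile(r, letters) for r in aln.rows]
    out = np.zeros((aln.n, aln.n))
    for i in range(aln.n):
        for j in range(i + 1, aln.n):
            out[i, j] = out[j, i] = log_correct(
                profile_dissimilarity(profiles[i], profiles[j], D), aln.alphabet)
    return out


def write_phylip_matrix(names: list[str], matrix: np.ndarray, handle) -> None:
    """Square Phylip distance-matrix format: count line, then name + row."""
    handle.write(f"{len(names)}\n")
    for name, row in zip(names, matrix):
        handle.write(f"{name:<10s} " + " ".join(f"{v:.6f}" for v in row) + "\n")
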