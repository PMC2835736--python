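# Methods

`profiletree` infers approximately-maximum-likelihood phylogenies with the
heuristic search strategy designed for very large alignments: a
profile-based neighbor-joining starting tree, minimum-evolution (ME)
refinement by nearest-neighbor interchanges (NNIs) and restricted
subtree-pruning-regrafting (SPR) moves, a maximum-likelihood (ML) NNI
phase under the CAT per-site rate approximation, and SH-like local support
values from RELL resampling. This note records the model, the numerical
conventions, and the design choices made where the design was genuinely
open.

## Profiles and the minimum-evolution phase

A subtree is summarized by a *profile*: an L x a matrix of per-position
character frequencies plus a per-position weight in [0, 1] equal to the
fraction of non-gap contribution. A leaf profile is an indicator matrix
with weight 1 at covered positions and 0 at gaps; an internal profile is
the *unweighted* average of its two children — frequencies are mixed in
proportion to the children's weights (a position covered in only one
child copies that child) and the new weight is the plain mean of the two.
Unweighted joins trade a small amount of starting-tree accuracy for
speed; the ML NNIs erase the difference.

The dissimilarity of two profiles is the coverage-weighted (w1*w2) mean
over positions of `f1^T D f2`. For nucleotides D is the 0/1 mismatch
matrix. For amino acids D is derived from the BLOSUM45 log-odds matrix:
scores are mapped to a similarity scale `S_ij = 2^(b_ij/3)`, normalized
by the geometric mean of self-similarities, `D_ij = 1 - S_ij /
sqrt(S_ii S_jj)`, and rescaled so that the background-frequency-weighted
mean off-diagonal entry is 1. The exponent base and the normalization are
this package's conventions; any smooth monotone mapping of the same
matrix would serve.

Raw dissimilarities are log-corrected into additive distances:
Jukes-Cantor `-3/4 ln(1 - 4d/3)` for nucleotides and the scoredist-style
single-log form `-1.3 ln(1 - d)` for amino acids, both capped at 3.0
substitutions/site so that arithmetic stays finite past saturation. When
two profiles share no covered positions at all the distance is treated as
saturated and a warning is logged.

**Starting tree.** Neighbor joining with the classical Q criterion
`Q(i,j) = (n-2) d(i,j) - r(i) - r(j)` evaluated on *uncorrected* profile
dissimilarities; a joined pair is replaced by its average profile and
distances to the new node are recomputed from profiles rather than
reduced algebraically. Provisional branch lengths use the
Studier-Keppler formulas, floored at 0. Ties in Q keep the first
(row-major) candidate, which makes runs reproducible.

**ME NNIs.** For the quartet (A,B | C,D) around an internal edge the
length change of switching to (A,C | B,D) is estimated as
`(d(A,C) + d(B,D) - d(A,B) - d(C,D)) / 2` with log-corrected profile
distances (the halving follows the balanced-minimum-evolution
convention; with profile-based distances the estimate is approximate
rather than exact). Strictly negative deltas are applied immediately,
profiles on the path to the top are refreshed, and sweeps repeat until
no change or ceil(log2 N) + 1 sweeps. Ties keep the current topology.

**Linear SPRs.** Each candidate SPR is treated as a chain of NNIs whose
deltas add. For every node, moves up to two edges away are enumerated
exhaustively; each length-2 state is then extended greedily along its
single best next step up to a total length of 10. The best strictly
negative cumulative move per node is applied at once. Two rounds are run.
When the pruned node's parent is the top trifurcation the tree is first
re-hung at another internal node so the detach/regraft mechanics are
uniform.

**ME branch lengths** come from the standard four-point (internal) and
three-point (leaf) combinations of log-corrected profile distances,
floored at 0. They only seed the ML phase.

## Likelihood engine

Partial likelihoods ("posteriors") are stored row-normalized — each
site's vector sums to 1 — with the log of every normalization constant
accumulated in a per-site counter, so exact site log-likelihoods are
always recoverable. Rather than rescaling only when a site's row drops
below a threshold, every combine renormalizes every site; this is the
same bookkeeping applied unconditionally and keeps the stored invariant
simple. All vectors are double precision.

Stationary frequencies enter exactly once, inside the edge likelihood
`sum_xy pi_x p1[x] P(x->y|t) p2[y]`; partials stay convention-free. The
up-posterior (the rest of the tree seen from a node's parent edge) is
computed on demand by the usual recurrence — parent's up-posterior
combined with the sibling's posterior, the other two children at the top
trifurcation — so storage stays bounded by the tree depth.

Models: Jukes-Cantor, GTR (six exchangeabilities over empirical base
frequencies), and JTT with its published equilibrium frequencies.
Eigendecomposition is done on the pi-symmetrized generator for
stability; transition matrices are `V exp(Lambda t) V^-1` clipped to
[0, 1], with a small cache keyed on the (rounded) branch length.

**Brent optimization.** Branch lengths and model parameters are
optimized one dimension at a time with Brent's method. The initial
bracket is (x0/2, x0, 2 x0), or (min, 2 min, 4 min) when the guess sits
below the lower bound; if the middle point is not the best the interval
is expanded toward the better end until it brackets, returning the bound
for monotone objectives. Degenerate guesses on a bound are handled by
wedging midpoints into the largest remaining gap. Iteration stops when
the step falls below max(0.0001, 0.1% of x). Branch lengths live in
[0.0001, 10]; the lower bound is the minimum branch length reported in
the output, the upper bound is this package's choice (saturation makes
larger values indistinguishable). `optimize_branch` never returns a
length whose likelihood is below the starting point's, which is what
makes every accepted operation non-decreasing in log-likelihood.

## The ML pipeline

Steps, in order: (1) seed internal posteriors with branch-length-decayed
(e^-t) averages of the children — the weight is this package's choice,
mimicking substitution attenuation; the search replaces these with exact
values as it goes; (2) one round of branch lengths under a simplified
model (no CAT, JC in place of GTR; JTT is already parameter-free for
proteins); (3) one round of ML NNIs under the simplified model; (4) with
GTR, fit the six exchangeabilities — AG pinned to 1 for identifiability,
the other five optimized in turn for two passes with all posteriors
recomputed per candidate — then one round of lengths; (5) with CAT,
assign per-site rates and one round of lengths; (6) further NNI rounds
with subtree skipping and the star-topology test until no quartet
improves by more than 0.1 log-likelihood units, capped at 2 ceil(log2 N)
rounds; (7) one final NNI round with both heuristics off; (8) a final
round of branch lengths; (9) SH-like supports.

A *round of branch lengths* is a post-order pass that, at each node,
optimizes the three incident branch lengths in series for two rounds
(the three children at the top trifurcation) and refreshes the node's
posterior.

**A round of ML NNIs** visits nodes in depth-first post-order. At each
internal edge the three arrangements of the quartet (children A, B;
sibling C; rest-of-tree D) each get one round of quartet optimization —
internal edge first, then the branches to A, B, C, D, reusing the
intermediate posteriors (AB, CD, BCD, ACD, ABD, ABC). Arrangements more
than 5 log-likelihood units worse than the current one are abandoned; any
survivors (and the current arrangement) get a second round. The best
arrangement is adopted, its re-optimized lengths are written back, and
the node's posterior is recomputed. With `mlacc >= 2` every arrangement
gets that many rounds and nothing is abandoned.

**Subtree skipping** (rounds >= 3, heuristics on): a subtree is not
entered if nothing inside it improved by more than 0.1 log-likelihood
units in either of the two previous rounds and no node adjacent to its
parent was part of a significantly improving NNI (same 0.1 threshold —
the package's reading of "significantly" for the adjacency check) in the
previous round. **Star-topology test** (heuristics on, node unchanged in
the previous round): if the current quartet, after optimizing only the
internal branch, beats the same quartet with the internal branch pinned
at 0.0001 by more than 5 log-likelihood units, the alternates are not
evaluated at all.

**CAT.** Twenty relative rates logarithmically spaced between 0.05 and
20. For each rate the per-site log-likelihood of the tree is computed
with every branch scaled by that rate (equivalent to a per-site rate
multiplier); each site receives the rate maximizing site log-likelihood
plus the log of a gamma prior with shape 3 and scale 1/3 (mean 1,
deliberately more peaked than real rate variation, to avoid overfitting
on small alignments); the chosen rates are then rescaled by one common
factor so their mean over sites is exactly 1. On short total tree
lengths the prior dominates weak per-site signal — an invariant column
is only pushed into the lowest rates once the tree is long enough
(roughly total length 10+), which the tests exercise explicitly.

**Gamma20 rescaling.** From the retained per-site, per-rate likelihood
table, a discrete-gamma mixture over the fixed 20-rate ladder is fitted
with two free parameters: the shape alpha and a branch rescaling s. The
ladder weights are the gamma(alpha, mean s) density at each ladder rate
times the log-spacing cell width, normalized; (alpha, s) are optimized by
Nelder-Mead in log space. The supplement that motivates this step gives
no closed form, so the weight construction is this package's convention.
Reported: alpha, s, the rescaled total tree length, and the mixture
log-likelihood.

## SH-like supports

For each internal edge, per-site log-likelihoods of the current topology
(current branch lengths) and of the two NNI alternatives (quartet
lengths re-optimized for up to two rounds, no write-back) are compared
over 1,000 multinomial site resamples without re-optimization (RELL).
Centering each topology's resampled log-likelihood by its own expected
resampled value — which equals its observed log-likelihood — and asking
whether the current topology's centered advantage survives reduces
algebraically to counting the replicates where the current topology's
resampled log-likelihood strictly exceeds both alternatives'. Ties count
against the split, so an edge with no signal gets support well below
1/2. One replicate weight matrix is shared across all edges (a speed
choice; independence across edges is not claimed). Supports should be
read cautiously near poorly resolved nodes, because a high-likelihood
alternate topology might not have been considered.

## Synthetic data

The generator emulates a 16S-like protocol: a pure-birth (Yule) tree
rescaled so the mean root-to-tip path is 1.0 substitutions/site (the
package's default depth; any branch below 0.001 is raised to 0.001),
per-site rates drawn from a 16-category discretization of a gamma
distribution with coefficient of variation 0.7 (shape = 1/cv^2 ~ 2.04,
equal-probability categories represented by their means), and characters
evolved root-to-tip from exact transition probabilities under JC, HKY
(kappa = 1 by default, i.e. no transition bias) or JTT. There is no
indel process; gaps, when requested, are i.i.d. masking. Accuracy is
scored as the fraction of the true tree's nontrivial splits recovered —
the converse of the Robinson-Foulds distance.

What the simulations do *not* emulate: realistic indel placement,
compositional heterogeneity, among-lineage rate variation, alignment
error. Passing tests therefore demonstrate correctness of the algorithms
under the generative model, not robustness to real-data pathologies.

## Problem sizes and numerical conventions

The bundled checks run the full pipeline on twenty simulated 32-taxon,
1000-nt alignments (accuracy and monotonicity), twenty 16-taxon, 500-nt
alignments (support calibration), and parameter-recovery fixtures at
L = 5000; the acceptance script uses ten seeds per battery. These sizes
are the package's chosen desk scale: large enough for every code path
(including both search heuristics) to fire, small enough to iterate on.
The O(N^2) neighbor joining and the O(N sqrt(N))-style accelerations of
the original large-scale implementations are intentionally out of scope
at this scale.

Degenerate inputs: alignments with fewer than 3 distinct sequences are
rejected; byte-identical sequences are collapsed before inference and
re-attached afterwards as zero-length cherries (keeping the output
bifurcating); all-gap columns carry weight 0 everywhere and drop out of
every distance; a quartet whose profiles share no covered positions is
treated as saturated. Every branch length in ML output lies in
[0.0001, 10].

## Known limitations

* The exact constants of the amino-acid correction (the 1.3 factor, the
  BLOSUM45 normalization) are conventions standing in for unpublished
  values; nucleotide behavior is unaffected.
* Ambiguity codes are treated as gaps rather than partial-information
  vectors.
* ME tree-length deltas on profile distances are approximations; the
  search only uses their sign and relative magnitude.
* GTR fitting uses two coordinate-ascent passes by design; on data with
  a strong transition bias the fitted transition/transversion ratio is
  typically recovered within ~15% but not exactly, and strong among-site
  rate variation biases it further if fitted without CAT.
* Supports from shared resample weights are correlated across edges.
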