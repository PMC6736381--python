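# Methods

## The model

`rotasub` implements empirical substitution models on an expanded protein
alphabet in which each character records an amino acid together with the
discrete chi1 rotamer configuration of its side chain. chi1 — the
N–Calpha–Cbeta–Cgamma dihedral (with the residue-specific fourth atom:
Ogamma for SER, Ogamma1 for THR, Cgamma1 for ILE/VAL, Sgamma for CYS) — is
strictly rotameric: three wells near +60°, −180° and −60° for most residues,
two for proline (≈+27°, ≈−25°), and none for alanine or glycine. This yields
17·3 + 2 + 2·1 = 55 states. Evolution is modelled as a reversible
continuous-time Markov chain on these states, so the model drops into the
standard phylogenetic machinery (pruning likelihoods, +G rate heterogeneity,
+F frequency replacement, simulation, ancestral reconstruction) unchanged
except for the alphabet size.

### Estimation pipeline

1. **Rotamer assignment.** chi1 angles are computed from coordinates with
   the IUPAC sign convention and binned by equidistant well boundaries:
   [0°,120°) → 1, [120°,180°] ∪ [−180°,−120°) → 2, [−120°,0°) → 3; proline
   splits at 0°. Residues are masked (UNKNOWN, frame preserved) when the
   mean B-factor of the four chi1 atoms exceeds 30 Å², the peptide bond to
   the next residue exceeds 1.8 Å, or the residue is nonstandard or
   disordered (missing chi1 atoms / zero occupancy). Resolution filtering is
   treated as a structure-level metadata predicate.
2. **Counting.** Within each family, aligned rotasequences are compared
   along a circular (planar depth-first, wrap-around included) tour of a
   neighbour-joining tree built from p-distances (gaps pairwise-deleted; NJ
   input taxa sorted lexicographically so results are input-order
   invariant). Pairs under 75% rotasequence identity are skipped. Counts are
   accumulated symmetrically — 1 to each ordering of a difference, 2 to the
   diagonal for a conserved site — so row sums equal state observation
   counts.
3. **Normalization.** Each amino-acid-pair submatrix of the 55-state count
   matrix is rescaled to sum to the corresponding count from an unfiltered
   20-state count matrix, removing the composition bias introduced by the
   B-factor filter (which, e.g., can never remove ALA/GLY) while keeping
   the observed rotamer exchange pattern.
4. **Rates and scaling.** Off-diagonal rates are each state's substitution
   events as a proportion of all its observations (conservation counts in
   the denominator); frequencies are row sums over the total; symmetric
   counts then guarantee detailed balance. The matrix is scaled twice:
   by ρ = |Σ_i π_i q_ii| to one expanded-state substitution per unit time,
   then by ρ* (the equilibrium proportion of state changes that alter the
   amino acid) so that branch lengths count amino-acid substitutions and are
   directly comparable with 20-state models. The process then performs
   (1−ρ*)/ρ* additional pure-rotamer changes per unit time.
5. **Exchangeabilities.** s_ij = q_ij/π_j, symmetric under reversibility;
   model files store these with the frequencies (PAML-dat-like lower
   triangle, with a header flag recording the scaling convention — our own
   serialization, since no standard exists for 55 states). Inverting the
   relation with new frequencies is the +F mechanism; after inversion the
   matrix is rescaled per its convention.

### Cross-state-space comparison

A 20-state likelihood is mapped to the 55-state space by the per-observation
frequency-ratio correction, log L_55 ≈ log L_20 + Σ log(π55[d]/π20[c]),
before AIC comparison. The correction is exact when the fine states are
conditionally independent of each other given the compound data. For a
uniform-expansion CTMC that holds only when no two taxa share an amino acid
at a site: the expanded chain keeps some within-amino-acid rotamer-label
memory (the probability of no event along a path preserves the label), which
correlates labels between taxa. We verified both facts numerically; the
restricted identity is asserted exactly (1e-9) in the test suite and the
general case is treated as the approximation it is. For empirical parameter
counting, fixed-rate empirical models count branch lengths only (plus the
gamma shape for +G and states−1 frequencies for +F); exchangeabilities are
data, not parameters.

Two structure-free 20→55 expansions serve as baselines: uniform (counts
spread evenly over each rotamer-pair submatrix; lumps back exactly onto the
base model, KL ≡ 0) and frequency-aware (counts spread as the product of
supplied 55-state frequencies). Reversing the counts→rates map from an
exchangeability file requires a conservation diagonal; we fill it so row
sums are proportional to π, the unique choice under which the inversion is
exact up to time scale (a zero diagonal provably row-rescales the
generator).

Information loss from replacing the rotamer-aware model with its 20-state
counterpart is the KL divergence, in bits, between the amino-acid
distributions reached at time t from a given rotamer state under the two
models, averaged over start states with equilibrium weights. Transition
probabilities below 1e-14 are treated as structural zeros (P(t) entries are
clipped at 0).

## Numerical choices

* **P(t).** Symmetric eigendecomposition of diag(√π) Q diag(1/√π)
  (valid by reversibility), cached per model; entries clipped to [0,1] and
  rows renormalized. The generic `transition_matrix(Q, t)` falls back to
  scaling-and-squaring `expm`.
* **Pruning.** Per-node rescaling by the per-site maximum, log-scale
  accumulators; gap/unknown tips are all-ones partials. +G uses Yang's
  mean-per-equal-probability-bin discretization (K = 4 default), rates
  renormalized to exact unit mean.
* **Branch lengths.** Coordinate-wise optimization against down/up partial
  caches refreshed once per round; each proposed simultaneous (Jacobi)
  update is damped by a halving line search until the total log-likelihood
  improves, which restores the monotonicity a plain Jacobi step lacks.
  Per-branch minimization pre-brackets on a log grid around the current
  value before bounded Brent — the negative log-likelihood plateaus at
  large t and undirected golden-section probes can miss the basin. Bounds
  [1e-6, 100], tolerance 1e-6, 50 rounds maximum; the same bracketing guards
  the gamma-shape optimizer (α ∈ [0.02, 100]). +F optimizes softmax-
  transformed frequencies with L-BFGS, rebuilding the rate matrix at each
  evaluation.
* **Ancestral reconstruction.** Marginal posteriors are down×up products
  normalized per site; joint reconstruction is max-product dynamic
  programming in log space with ties broken toward the lowest state index.
  Ambiguous observed tips are marginalized; leave-leaves-out removes a
  terminal sibling pair as missing data, keeps the original pendant branch
  length, and reads the target leaf's state (maximized over, for the joint
  algorithm); sites with no remaining observed taxa return UNKNOWN and are
  excluded from accuracy denominators.
* **Association statistics.** Pearson chi-square on the (possibly
  non-integer) normalized counts with marginal-based expectations;
  Bergsma's bias-corrected Cramér's V; Bonferroni over the testable pairs.
  Torsion densities are 72×72 (5°) periodic histograms with optional von
  Mises kernel smoothing; the overlap integral is the sum of pointwise
  minimum cell masses.

## Synthetic data

The fixtures module generates everything the tests need: toy expanded
alphabets (default four pseudo-residues with multiplicities 3/3/2/1, nine
states, chosen so exhaustive enumeration oracles stay affordable), random
symmetric count matrices with heavy diagonals and within-amino-acid exchange
boosted ×20 — on the 55-state alphabet this gives ≈1.76 state changes per
amino-acid substitution, matching the magnitude reported for empirical
rotamer data (≈1.79) — ideal-geometry coordinates realizing prescribed chi1
angles via internal-to-Cartesian (NeRF) placement, planted substitution
families with recorded internal-node sequences and branch event tallies,
and von Mises torsion-angle mixtures. Simulation draws root states from π
and child states from P(t) rows (statistically identical to event-by-event
simulation of the chain); random topologies come from sequential random
attachment at a uniformly chosen branch, uniform over labelled rooted
topologies, with i.i.d. uniform branch lengths on [0.01, 0.5].

What a green test on synthetic data does establish: internal consistency of
the estimation algebra, exactness of the dynamic programming against
enumeration, statistical calibration of estimators at stated sample sizes.
What it does not: that real structural data satisfy the model (real chi1
distributions are backbone-dependent and rotamer changes are correlated
between neighbouring sites); fixtures make no attempt to mimic PDB
statistics.

## Known limitations

* The published 55-state empirical matrix is not bundled; checks that need
  it look under `data/ram55/` and fail when absent.
* No topology search — trees are inputs; branch lengths, α, and frequencies
  are optimized on a fixed topology. Exhaustive enumeration is feasible only
  at toy sizes.
* No multiple-hit correction in counting beyond the 75% identity filter; no
  chi2+ angles; no indel or codon models; alternate conformers resolve to
  the highest-occupancy atom only.
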