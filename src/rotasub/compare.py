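"""Model comparison across state spaces.

A 20-state amino-acid model and a 55-state rotamer-aware model live in
different state spaces, so their likelihoods are not directly comparable.
The state-space correction maps a compound-alphabet (amino acid) likelihood
onto the distinct (rotamer) alphabet through per-observation equilibrium
frequency ratios:

    log L_D = log L_C + sum_{taxa p} sum_{sites q} log(pi_D[d(p,q)] / pi_C[c(p,q)])

Corrected log-likelihoods feed the usual AIC = 2k - 2 log L. Note the
correction is exact when fine states are conditionally independent given the
compound data; for a uniform-expansion CTMC it is exact whenever no two taxa
share an amino acid at a site, and an approximation otherwise (the expanded
chain retains some within-amino-acid rotamer-label memory along lineages).

Two 20 -> 55 expansions are provided for building structure-free reference
models in the expanded space: a uniform expansion (no information about the
new states beyond their existence) and a frequency-aware expansion that
respects a supplied 55-state frequency vector.

The Kullback-Leibler module quantifies, in bits, the information about the
future amino-acid distribution that is lost when the rotamer-aware model is
approximated by its 20-state counterpart, as a function of divergence time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet_io import Alphabet, RotasequenceAlignment
from .model_build import RateModel, model_from_counts
from .counting import mask_counts


class CompareError(ValueError):
    pass


# ---------------------------------------------------------------------------
# AIC and the state-space likelihood correction
# ---------------------------------------------------------------------------

def aic(loglik: float, k: int) -> float:
    if k < 0:
        raise CompareError("parameter count must be nonnegative")
    return 2.0 * k - 2.0 * loglik


def state_corrected_loglik(loglik20: float,
                           rotaseq_alignment: RotasequenceAlignment,
                           pi55: np.ndarray, pi20: np.ndarray) -> float:
    """Correct a compound (amino-acid) log-likelihood to the expanded space.

    Gap/unknown cells contribute no correction term. Raises if an observed
    state has zero frequency in either model.
    """
    alphabet = rotaseq_alignment.alphabet
    codes = rotaseq_alignment.codes
    observed = codes[codes >= 0]
    fine = np.asarray(pi55, dtype=float)
    coarse = np.asarray(pi20, dtype=float)
    fine_obs = fine[observed]
    coarse_obs = coarse[alphabet.group_of[observed]]
    if (fine_obs <= 0).any() or (coarse_obs <= 0).any():
        raise CompareError("zero equilibrium frequency for an observed state")
    return float(loglik20 + np.log(fine_obs / coarse_obs).sum())


@dataclass
class ModelFitReport:
    """One model's fit to one data set, on a common (corrected) scale."""

    name: str
    n_states: int
    loglik: float                 # raw log-likelihood in the model's own space
    corrected_loglik: float       # mapped to the expanded space where needed
    k: int
    aic: float


def fit_report(name: str, n_states: int, loglik: float, k: int,
               corrected_loglik: float | None = None) -> ModelFitReport:
    cl = loglik if corrected_loglik is None else corrected_loglik
    return ModelFitReport(name=name, n_states=n_states, loglik=loglik,
                          corrected_loglik=cl, k=k, aic=aic(cl, k))


# ---------------------------------------------------------------------------
# 20 -> 55 model expansions
# ---------------------------------------------------------------------------

def counts_from_exchangeabilities(S: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Reconstruct a (scale-free) symmetric count matrix from a model.

    n_ij ∝ pi_i s_ij pi_j is the unique symmetric solution (up to scale) for
    the off-diagonal cells. Exchangeability files carry no conservation
    information, so the diagonal is chosen to make row sums proportional to
    pi — the condition under which the count -> rate map inverts exactly (up
    to the overall time scale, which the later rescaling fixes anyway).
    """
    pi = np.asarray(pi, dtype=float)
    N = pi[:, None] * np.asarray(S, dtype=float) * pi[None, :]
    np.fill_diagonal(N, 0.0)
    off_rows = N.sum(axis=1)
    c = float((off_rows / pi).max()) * 1.25   # headroom keeps diagonal > 0
    np.fill_diagonal(N, c * pi - off_rows)
    return N


def expand_uniform(counts20: np.ndarray, alphabet: Alphabet,
                   name: str = "exp") -> RateModel:
    """Uniform expansion: spread each amino-acid count evenly over its
    rotamer-pair submatrix, then run the standard estimation pipeline.

    The result is the most-uninformed expression of the 20-state model in
    the expanded space: its equilibrium frequencies are pi_A / |R_A| and its
    transition probabilities lump exactly back onto the 20-state model.
    """
    M = np.asarray(counts20, dtype=float)
    g = alphabet.group_of
    sizes = alphabet.group_sizes
    weight = 1.0 / (sizes[g][:, None] * sizes[g][None, :])
    expanded = M[np.ix_(g, g)] * weight
    return model_from_counts(expanded, alphabet, scaling="superscaled",
                             name=name)


def expand_by_freq(counts20: np.ndarray, pi55: np.ndarray, alphabet: Alphabet,
                   name: str = "byfreq-exp") -> RateModel:
    """Frequency-aware expansion: spread counts as pi_(A,R) pi_(A',R') n_AA'."""
    M = np.asarray(counts20, dtype=float)
    pi55 = np.asarray(pi55, dtype=float)
    g = alphabet.group_of
    expanded = pi55[:, None] * pi55[None, :] * M[np.ix_(g, g)]
    return model_from_counts(expanded, alphabet, scaling="superscaled",
                             name=name)


def lumped_model(model55: RateModel, counts55: np.ndarray | None = None,
                 name: str = "lumped") -> RateModel:
    """The 20-state counterpart built by merging expanded-state counts."""
    if counts55 is None:
        # reconstruct scale-free counts from the model itself
        S = model55.exchangeabilities
        counts55 = counts_from_exchangeabilities(S, model55.pi)
    merged = mask_counts(counts55, model55.alphabet)
    return model_from_counts(merged, model55.alphabet.masked(),
                             scaling="superscaled", name=name)


# ---------------------------------------------------------------------------
# KL divergence profiles
# ---------------------------------------------------------------------------

#: probabilities below this are treated as structural zeros (P(t) entries are
#: clipped, so exact zeros and 1e-17 roundoff must not be distinguished)
_P_FLOOR = 1e-14


def _lump_matrix(alphabet: Alphabet) -> np.ndarray:
    """0/1 matrix L (n_states x n_groups) summing fine states into groups."""
    L = np.zeros((alphabet.n_states, alphabet.n_groups))
    L[np.arange(alphabet.n_states), alphabet.group_of] = 1.0
    return L


def kl_divergence(model55: RateModel, model20: RateModel, state: int,
                  t: float) -> float:
    """Information loss (bits) about the amino acid reached at time t when a
    20-state model replaces the expanded model, starting from ``state``.

    The expanded model's row of P(t) is summed over the rotamer
    configurations of each target amino acid and compared with the 20-state
    row of the state's amino acid. Returns ``inf`` if the 20-state model
    assigns zero probability where the expanded model has mass.
    """
    if t < 0:
        raise CompareError("negative time")
    L = _lump_matrix(model55.alphabet)
    p_fine = model55.transition_matrix(t)[state] @ L   # over amino acids
    a = int(model55.alphabet.group_of[state])
    p_coarse = model20.transition_matrix(t)[a]
    mask = p_fine > _P_FLOOR
    if (p_coarse[mask] <= _P_FLOOR).any():
        return float("inf")
    return float(np.sum(p_fine[mask]
                        * np.log2(p_fine[mask] / p_coarse[mask])))


def kl_profile(model55: RateModel, model20: RateModel,
               t_grid: np.ndarray | None = None):
    """Equilibrium-frequency-weighted mean KL curve over all start states.

    Returns (t_grid, profile) with the profile in bits per site.
    """
    if t_grid is None:
        t_grid = np.logspace(np.log10(0.01), np.log10(5.0), 200)
    t_grid = np.asarray(t_grid, dtype=float)
    L = _lump_matrix(model55.alphabet)
    group = model55.alphabet.group_of
    profile = np.empty(len(t_grid))
    for i, t in enumerate(t_grid):
        Pf = model55.transition_matrix(t) @ L          # (55, 20)
        Pc = model20.transition_matrix(t)[group]       # (55, 20)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(Pf > _P_FLOOR, Pf * np.log2(Pf / Pc), 0.0)
        profile[i] = float(model55.pi @ terms.sum(axis=1))
    return t_grid, profile
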