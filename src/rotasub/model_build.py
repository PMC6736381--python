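"""Building reversible rate models from normalized substitution counts.

The pipeline follows the classic Dayhoff-style recipe on the expanded state
space. From a symmetric normalized count matrix N (diagonal = conservation
counts) the instantaneous rate matrix is

    q_ij = n_ij / sum_k n_ik            (i != j, denominator includes n_ii)

with the diagonal closed so rows sum to zero, and equilibrium frequencies
pi_i = rowsum_i / total. Two scalings follow:

* rotamer-unit scaling: divide by rho = |sum_i pi_i q_ii| so that one
  expanded-state substitution is expected per unit time;
* superscaling: divide further by rho*, the equilibrium proportion of state
  changes that alter the amino acid, so that one *amino-acid* substitution is
  expected per unit time. Superscaled branch lengths are directly comparable
  with those of ordinary 20-state models; the process then performs
  (1 - rho*)/rho* additional pure-rotamer changes per unit time.

Exchangeabilities factor out the target frequency, s_ij = q_ij / pi_j; they
are symmetric for reversible models and can be recombined with any frequency
vector (the +F mechanism) by inverting the same relation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet_io import Alphabet

_TOL = 1e-10


class ModelError(ValueError):
    pass


@dataclass
class RateModel:
    """A reversible continuous-time Markov substitution model."""

    alphabet: Alphabet
    Q: np.ndarray
    pi: np.ndarray
    name: str = ""
    rho: float | None = None        # rotamer-unit scaling constant
    rho_star: float | None = None   # amino-acid superscaling constant
    scaling: str = "none"           # none | rotamer | superscaled
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        n = self.alphabet.n_states
        if self.Q.shape != (n, n) or self.pi.shape != (n,):
            raise ModelError("Q/pi dimensions do not match the alphabet")
        validate_rate_matrix(self.Q, self.pi)

    @property
    def n_states(self) -> int:
        return self.alphabet.n_states

    @property
    def exchangeabilities(self) -> np.ndarray:
        return irm_to_exchangeabilities(self.Q, self.pi)

    # -- transition probabilities ----------------------------------------
    def _eigendecompose(self):
        """Symmetric eigendecomposition of diag(sqrt(pi)) Q diag(1/sqrt(pi)).

        Valid for reversible models; gives numerically stable P(t) for
        arbitrary t at the cost of one decomposition.
        """
        if self._eig is None:
            sq = np.sqrt(self.pi)
            B = (sq[:, None] * self.Q) / sq[None, :]
            B = (B + B.T) / 2.0
            w, U = np.linalg.eigh(B)
            self._eig = (w, U, sq)
        return self._eig

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(tQ); rows sum to 1, entries clamped to [0, 1]."""
        if t < 0:
            raise ModelError(f"negative time {t}")
        w, U, sq = self._eigendecompose()
        P = (U * np.exp(w * t)) @ U.T
        P = P / sq[:, None] * sq[None, :]
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def validate_rate_matrix(Q: np.ndarray, pi: np.ndarray,
                         tol: float = 1e-8) -> None:
    off = Q.copy()
    np.fill_diagonal(off, 0.0)
    if (off < -tol).any():
        raise ModelError("negative off-diagonal rates")
    if np.abs(Q.sum(axis=1)).max() > tol:
        raise ModelError("rate-matrix rows do not sum to zero")
    if (pi <= 0).any():
        raise ModelError("equilibrium frequencies must be strictly positive")
    if abs(pi.sum() - 1.0) > 1e-6:
        raise ModelError("equilibrium frequencies must sum to 1")
    flux = pi[:, None] * Q
    asym = np.abs(flux - flux.T).max() / max(np.abs(flux).max(), 1e-300)
    if asym > 1e-6:
        raise ModelError(f"detailed balance violated (relative error {asym:.2e})")


# ---------------------------------------------------------------------------
# counts -> rates -> scalings
# ---------------------------------------------------------------------------

def counts_to_irm(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unscaled IRM and equilibrium frequencies from symmetric counts.

    Off-diagonal rates are each state's substitution events as a proportion
    of all its observations (conservation counts included in the
    denominator); frequencies are the row sums over the grand total.
    """
    N = np.asarray(counts, dtype=float)
    if N.ndim != 2 or N.shape[0] != N.shape[1]:
        raise ModelError("counts must be square")
    if (N < 0).any():
        raise ModelError("counts must be nonnegative")
    if not np.allclose(N, N.T, rtol=1e-8, atol=1e-8):
        raise ModelError("counts must be symmetric")
    rowsums = N.sum(axis=1)
    zero = np.flatnonzero(rowsums == 0)
    if zero.size:
        raise ModelError(f"zero observations for state index {zero[0]}")
    Q = N / rowsums[:, None]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    pi = rowsums / N.sum()
    return Q, pi


def scale_to_rotamer_unit(Q: np.ndarray, pi: np.ndarray) \
        -> tuple[np.ndarray, float]:
    """Scale so one expanded-state substitution is expected per unit time.

    Returns (Q*, rho) with rho the magnitude of sum_i pi_i q_ii (the
    equilibrium total rate).
    """
    rho = float(abs(np.sum(pi * np.diag(Q))))
    if rho == 0:
        raise ModelError("zero process: cannot scale")
    return Q / rho, rho


def superscale(Q_star: np.ndarray, pi: np.ndarray, alphabet: Alphabet) \
        -> tuple[np.ndarray, float]:
    """Scale so one amino-acid-changing substitution is expected per unit time.

    rho* is the equilibrium proportion of state changes that alter the amino
    acid, computed from a rotamer-unit-scaled matrix.
    """
    group = alphabet.group_of
    different = group[:, None] != group[None, :]
    rho_star = float(np.sum(pi[:, None] * np.where(different, Q_star, 0.0)))
    if rho_star <= 0:
        raise ModelError("no amino-acid-changing rate: cannot superscale")
    return Q_star / rho_star, rho_star


def irm_to_exchangeabilities(Q: np.ndarray, pi: np.ndarray,
                             rtol: float = 1e-8) -> np.ndarray:
    """s_ij = q_ij / pi_j (zero diagonal); errors if the result is asymmetric."""
    S = Q / pi[None, :]
    np.fill_diagonal(S, 0.0)
    scale = max(np.abs(S).max(), 1e-300)
    if np.abs(S - S.T).max() / scale > rtol:
        raise ModelError("reversibility violation: exchangeabilities asymmetric")
    return (S + S.T) / 2.0


def exchangeabilities_to_irm(S: np.ndarray, pi: np.ndarray,
                             alphabet: Alphabet,
                             rescale: str = "superscaled",
                             name: str = "") -> RateModel:
    """Assemble a model from exchangeabilities and (possibly new) frequencies.

    This is the +F mechanism: general-purpose exchangeabilities combined with
    data-set-specific frequencies. ``rescale`` is one of ``none``,
    ``rotamer`` (unit total rate) or ``superscaled`` (unit amino-acid rate).
    """
    S = np.asarray(S, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if S.shape[0] != len(pi) or len(pi) != alphabet.n_states:
        raise ModelError("dimension mismatch between S, pi and alphabet")
    if not np.allclose(S, S.T):
        raise ModelError("exchangeabilities must be symmetric")
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rho = rho_star = None
    scaling = "none"
    if rescale in ("rotamer", "superscaled"):
        Q, rho = scale_to_rotamer_unit(Q, pi)
        scaling = "rotamer"
    if rescale == "superscaled":
        Q, rho_star = superscale(Q, pi, alphabet)
        scaling = "superscaled"
    elif rescale not in ("none", "rotamer"):
        raise ModelError(f"unknown rescale mode {rescale!r}")
    return RateModel(alphabet, Q, pi, name=name, rho=rho, rho_star=rho_star,
                     scaling=scaling)


def model_from_counts(counts: np.ndarray, alphabet: Alphabet,
                      scaling: str = "superscaled",
                      name: str = "") -> RateModel:
    """Full pipeline: counts -> IRM -> rotamer-unit scaling -> superscaling."""
    Q, pi = counts_to_irm(counts)
    rho = rho_star = None
    if scaling in ("rotamer", "superscaled"):
        Q, rho = scale_to_rotamer_unit(Q, pi)
    if scaling == "superscaled":
        Q, rho_star = superscale(Q, pi, alphabet)
    elif scaling not in ("none", "rotamer"):
        raise ModelError(f"unknown scaling mode {scaling!r}")
    return RateModel(alphabet, Q, pi, name=name, rho=rho, rho_star=rho_star,
                     scaling=scaling)
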