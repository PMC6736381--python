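"""Exchange-pattern analysis of normalized rotamer substitution counts.

For each pair of distinct amino acids the off-diagonal block of the
normalized count matrix is a contingency table between the chi1
configurations of the two residues (3x3 for most pairs, 2x3 for pairs
involving proline; pairs involving alanine or glycine are degenerate and
untestable). Association is tested with Pearson's chi-square (Bonferroni
corrected) and quantified with bias-corrected Cramer's V; the diagonal ratio
measures the tendency to conserve the chi1 configuration on exchange.

Backbone context similarity is an overlap integral of two (phi, psi)
densities on the torus, O_ij = integral of min(f_i, f_j); overlaps can then
be rank-correlated with exchangeabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .alphabet_io import Alphabet

#: biochemical grouping of the three-rotamer residues (methionine excluded)
BIOCHEMICAL_GROUPS = {
    "aliphatic": {"ILE", "LEU", "VAL"},
    "aromatic": {"PHE", "TRP", "TYR"},
    "positive": {"ARG", "LYS", "HIS"},
    "carboxylamine": {"ASN", "GLN"},
    "negative": {"ASP", "GLU"},
    "hydroxyl": {"SER", "THR"},
}


class StatsError(ValueError):
    pass


def biochemical_group(residue: str) -> str | None:
    for group, members in BIOCHEMICAL_GROUPS.items():
        if residue.upper() in members:
            return group
    return None


# ---------------------------------------------------------------------------
# association measures
# ---------------------------------------------------------------------------

def chi_square_independence(table: np.ndarray) -> tuple[float, float, int]:
    """Pearson chi-square test of row/column independence.

    Expected counts come from the marginals; works on the (possibly
    non-integer) normalized counts as given. Returns (chi2, p, dof).
    """
    T = np.asarray(table, dtype=float)
    if T.ndim != 2 or min(T.shape) < 2:
        raise StatsError("need at least a 2x2 table")
    if T.sum() <= 0:
        raise StatsError("empty table")
    chi2, p, dof, _ = sps.chi2_contingency(T, correction=False)
    return float(chi2), float(p), int(dof)


def cramers_v_corrected(table: np.ndarray) -> float:
    """Bias-corrected Cramer's V (Bergsma's correction).

    phi~^2 = max(0, chi2/n - (r-1)(c-1)/(n-1)); r~ = r - (r-1)^2/(n-1) and
    analogously c~; V~ = sqrt(phi~^2 / min(r~ - 1, c~ - 1)).
    """
    T = np.asarray(table, dtype=float)
    if T.ndim != 2 or min(T.shape) < 2:
        raise StatsError("degenerate table: single row or column")
    n = T.sum()
    if n <= 1:
        raise StatsError("need total count > 1")
    chi2, _, _ = chi_square_independence(T)
    r, c = T.shape
    phi2 = max(0.0, chi2 / n - (r - 1) * (c - 1) / (n - 1))
    r_t = r - (r - 1) ** 2 / (n - 1)
    c_t = c - (c - 1) ** 2 / (n - 1)
    denom = min(r_t - 1, c_t - 1)
    if denom <= 0:
        raise StatsError("degenerate corrected dimensions")
    return float(np.sqrt(phi2 / denom))


def diagonal_ratio(table: np.ndarray) -> float:
    """Fraction of counts on the diagonal of a square table (chi1 conserved)."""
    T = np.asarray(table, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise StatsError("diagonal ratio requires a square table")
    total = T.sum()
    if total <= 0:
        raise StatsError("zero total")
    return float(np.trace(T) / total)


@dataclass
class SubmatrixTest:
    """Association test for one amino-acid pair's rotamer exchange block."""

    pair: tuple[str, str]
    table: np.ndarray
    shape: tuple[int, int]
    chi2: float | None
    p_raw: float | None
    p_bonferroni: float | None
    cramers_v: float | None
    diag_ratio: float | None
    groups: tuple[str | None, str | None]
    testable: bool
    reason: str | None = None


def submatrix_tests(counts: np.ndarray, alphabet: Alphabet,
                    n_tests: int | None = None) -> list[SubmatrixTest]:
    """Independence tests for every unordered pair of multi-rotamer residues.

    Pairs where either residue has a single state are skipped as degenerate;
    pairs with a zero row or column marginal are flagged untestable. The
    Bonferroni factor defaults to the number of testable pairs.
    """
    N = np.asarray(counts, dtype=float)
    g = alphabet.group_of
    results: list[SubmatrixTest] = []
    multi = [i for i in range(alphabet.n_groups) if alphabet.group_sizes[i] > 1]
    for ai in range(len(multi)):
        for bi in range(ai + 1, len(multi)):
            a, b = multi[ai], multi[bi]
            rows = np.flatnonzero(g == a)
            cols = np.flatnonzero(g == b)
            T = N[np.ix_(rows, cols)]
            pair = (alphabet.groups[a], alphabet.groups[b])
            grp = (biochemical_group(pair[0]), biochemical_group(pair[1]))
            dr = diagonal_ratio(T) if T.shape[0] == T.shape[1] and T.sum() > 0 \
                else None
            if T.sum() <= 0 or (T.sum(axis=0) == 0).any() \
                    or (T.sum(axis=1) == 0).any():
                results.append(SubmatrixTest(pair, T, T.shape, None, None,
                                             None, None, dr, grp, False,
                                             "zero marginal"))
                continue
            try:
                chi2, p, _ = chi_square_independence(T)
                v = cramers_v_corrected(T)
            except StatsError as exc:  # e.g. total too small for the
                results.append(SubmatrixTest(  # bias-corrected dimensions
                    pair, T, T.shape, None, None, None, None, dr, grp,
                    False, str(exc)))
                continue
            results.append(SubmatrixTest(pair, T, T.shape, chi2, p, None,
                                         v, dr, grp, True))
    m = n_tests if n_tests is not None else sum(r.testable for r in results)
    for r in results:
        if r.testable:
            r.p_bonferroni = min(1.0, r.p_raw * m)
    return results


# ---------------------------------------------------------------------------
# Ramachandran overlap
# ---------------------------------------------------------------------------

@dataclass
class TorsionDensity:
    """A periodic probability distribution over (phi, psi) on a regular grid.

    ``mass`` holds the probability in each cell (sums to 1); the grid covers
    (-180, 180] x (-180, 180] with equal square bins.
    """

    mass: np.ndarray

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, dtype=float)
        if self.mass.ndim != 2 or self.mass.shape[0] != self.mass.shape[1]:
            raise StatsError("torsion grid must be square")
        if (self.mass < 0).any():
            raise StatsError("negative density")
        total = self.mass.sum()
        if abs(total - 1.0) > 1e-6:
            raise StatsError(f"density mass {total} not normalized")

    @property
    def n_bins(self) -> int:
        return self.mass.shape[0]

    @classmethod
    def from_samples(cls, phi: np.ndarray, psi: np.ndarray,
                     n_bins: int = 72, smooth_kappa: float | None = None
                     ) -> "TorsionDensity":
        """Histogram density on an ``n_bins`` x ``n_bins`` grid (5-degree bins
        by default), with optional periodic von-Mises kernel smoothing."""
        phi = np.array([wrap for wrap in map(_wrap, np.ravel(phi))])
        psi = np.array([wrap for wrap in map(_wrap, np.ravel(psi))])
        edges = np.linspace(-180.0, 180.0, n_bins + 1)
        H, _, _ = np.histogram2d(phi, psi, bins=[edges, edges])
        if smooth_kappa is not None:
            H = _von_mises_smooth(H, smooth_kappa)
        if H.sum() == 0:
            raise StatsError("no samples")
        return cls(H / H.sum())


def _wrap(a: float) -> float:
    a = (float(a) + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def _von_mises_smooth(H: np.ndarray, kappa: float) -> np.ndarray:
    """Circular smoothing by convolution with a von Mises kernel per axis."""
    n = H.shape[0]
    theta = 2 * np.pi * np.fft.fftfreq(n, d=1.0 / n) / n
    kernel = np.exp(kappa * np.cos(theta))
    kernel /= kernel.sum()
    out = np.real(np.fft.ifft(np.fft.fft(H, axis=0)
                              * np.fft.fft(kernel)[:, None], axis=0))
    out = np.real(np.fft.ifft(np.fft.fft(out, axis=1)
                              * np.fft.fft(kernel)[None, :], axis=1))
    return np.clip(out, 0.0, None)


def ramachandran_overlap(f_i: TorsionDensity, f_j: TorsionDensity) -> float:
    """Overlap integral of two torsion densities: sum of pointwise minima.

    Both densities must share a grid (no resampling of mismatched grids).
    """
    if f_i.n_bins != f_j.n_bins:
        raise StatsError(
            f"grid mismatch: {f_i.n_bins} vs {f_j.n_bins} bins")
    return float(np.minimum(f_i.mass, f_j.mass).sum())


# ---------------------------------------------------------------------------
# overlap vs exchangeability correlation
# ---------------------------------------------------------------------------

def overlap_exchangeability_correlation(S: np.ndarray,
                                        overlaps: np.ndarray,
                                        alphabet: Alphabet,
                                        scope: str = "global"):
    """Spearman correlation between exchangeabilities and backbone overlaps.

    ``scope='global'`` pools the off-diagonal-block state pairs of all
    multi-rotamer amino-acid pairs and returns ``(rho, p)``;
    ``scope='per-pair'`` returns a dict with one ``(rho, p)`` per amino-acid
    pair (pairs with fewer than 3 points are skipped) plus the fraction of
    pairs with positive rho under ``'positive_fraction'``.
    """
    S = np.asarray(S, dtype=float)
    O = np.asarray(overlaps, dtype=float)
    g = alphabet.group_of
    multi = [i for i in range(alphabet.n_groups) if alphabet.group_sizes[i] > 1]
    if scope == "global":
        xs, ys = [], []
        for ai in range(len(multi)):
            for bi in range(ai + 1, len(multi)):
                rows = np.flatnonzero(g == multi[ai])
                cols = np.flatnonzero(g == multi[bi])
                xs.append(S[np.ix_(rows, cols)].ravel())
                ys.append(O[np.ix_(rows, cols)].ravel())
        rho, p = sps.spearmanr(np.concatenate(xs), np.concatenate(ys))
        return float(rho), float(p)
    if scope != "per-pair":
        raise StatsError(f"unknown scope {scope!r}")
    out: dict = {}
    rhos = []
    for ai in range(len(multi)):
        for bi in range(ai + 1, len(multi)):
            a, b = multi[ai], multi[bi]
            rows = np.flatnonzero(g == a)
            cols = np.flatnonzero(g == b)
            x = S[np.ix_(rows, cols)].ravel()
            y = O[np.ix_(rows, cols)].ravel()
            if len(x) < 3:
                continue
            rho, p = sps.spearmanr(x, y)
            out[(alphabet.groups[a], alphabet.groups[b])] = (float(rho),
                                                             float(p))
            rhos.append(rho)
    out["positive_fraction"] = float(np.mean([r > 0 for r in rhos])) \
        if rhos else float("nan")
    return out
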