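"""Tabulating substitution counts from rotasequence alignments.

Counts are gathered by comparing pairs of aligned rotasequences chosen by a
circular tour through a neighbour-joining tree of the family: consecutive
leaves on a planar depth-first tour (including the wrap-around pair) are
compared, so every leaf enters exactly two comparisons and each observed
difference is counted at most twice. Pairs below 75% rotasequence identity
are skipped to limit multiple-hit artefacts.

Count matrices are symmetric with conservation counts on the diagonal: a
differing site adds one count to each of the two orderings, a conserved site
adds two to its diagonal cell, so row sums equal the number of observations
of each state.

``normalize_counts`` rescales each amino-acid-pair submatrix of the expanded
count matrix to sum to the corresponding 20-state count, recovering the
residue frequencies of an unfiltered amino-acid data set while preserving
the observed rotamer exchange pattern.
"""

from __future__ import annotations

import numpy as np

from .alphabet_io import Alphabet, RotasequenceAlignment
from .trees import IndexedTree, read_newick

SKIP = None
DEFAULT_IDENTITY_MIN = 0.75


class CountingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# NJ tree and circular tour
# ---------------------------------------------------------------------------

def nj_tree(distance_matrix: np.ndarray, taxa: list[str]):
    """Neighbour-joining (Saitou-Nei) tree from a symmetric distance matrix."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or D.shape[0] != len(taxa):
        raise CountingError("distance matrix shape does not match taxa")
    if np.isnan(D).any():
        raise CountingError("NaN distances")
    if not np.allclose(D, D.T):
        raise CountingError("distance matrix must be symmetric")
    if D.shape[0] < 3:
        raise CountingError("neighbour joining needs at least 3 taxa")
    skb = nj(DistanceMatrix(D, ids=list(taxa)))
    return read_newick(str(skb))


def p_distance_matrix(alignment: RotasequenceAlignment) \
        -> tuple[np.ndarray, list[str]]:
    """Pairwise p-distances (1 - identity), gap/unknown sites pairwise-deleted.

    Taxa are ordered lexicographically so the NJ tree (and hence the circular
    tour) does not depend on the input row order.
    """
    order = sorted(range(alignment.n_taxa), key=lambda i: alignment.taxa[i])
    taxa = [alignment.taxa[i] for i in order]
    codes = alignment.codes[order]
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (codes[i] >= 0) & (codes[j] >= 0)
            m = ok.sum()
            D[i, j] = D[j, i] = \
                1.0 - (codes[i][ok] == codes[j][ok]).sum() / m if m else 1.0
    return D, taxa


def circular_leaf_order(tree) -> list[str]:
    """Planar depth-first leaf ordering of the tree (a cyclic tour)."""
    itree = tree if isinstance(tree, IndexedTree) else IndexedTree(tree)
    return [itree.labels[v] for v in itree.postorder if itree.is_leaf[v]]


def tour_pairs(leaf_order: list[str]) -> list[tuple[str, str]]:
    """Consecutive pairs on the circular tour, wrap-around included.

    ``n`` leaves yield ``n`` comparisons with every leaf of degree 2; the
    2-leaf case collapses to a single comparison.
    """
    n = len(leaf_order)
    if n < 2:
        return []
    if n == 2:
        return [(leaf_order[0], leaf_order[1])]
    return [(leaf_order[i], leaf_order[(i + 1) % n]) for i in range(n)]


# ---------------------------------------------------------------------------
# pairwise counting
# ---------------------------------------------------------------------------

def pair_counts(seq_a: np.ndarray, seq_b: np.ndarray, n_states: int,
                identity_min: float = DEFAULT_IDENTITY_MIN):
    """Symmetric count increments for one aligned pair, or ``SKIP``.

    Sites where either state is gap/unknown are ignored. If the identity
    over the remaining sites is below ``identity_min`` (strictly), or no
    sites remain, the pair is skipped.
    """
    a = np.asarray(seq_a)
    b = np.asarray(seq_b)
    if a.shape != b.shape:
        raise CountingError(
            f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    ok = (a >= 0) & (b >= 0)
    m = int(ok.sum())
    if m == 0:
        return SKIP
    a, b = a[ok], b[ok]
    identity = float((a == b).sum()) / m
    if identity < identity_min:
        return SKIP
    N = np.zeros((n_states, n_states))
    np.add.at(N, (a, b), 1.0)
    np.add.at(N, (b, a), 1.0)
    return N


def accumulate_family(alignment: RotasequenceAlignment,
                      identity_min: float = DEFAULT_IDENTITY_MIN) -> np.ndarray:
    """Circular-tour substitution counts for one family alignment."""
    if alignment.n_taxa < 2:
        raise CountingError("need at least 2 taxa")
    n_states = alignment.alphabet.n_states
    if alignment.n_taxa == 2:
        pairs = [(alignment.taxa[0], alignment.taxa[1])]
    else:
        D, taxa = p_distance_matrix(alignment)
        if np.allclose(D, 0):
            # all sequences identical: any topology; use the sorted order
            pairs = tour_pairs(taxa)
        else:
            tree = nj_tree(D, taxa)
            pairs = tour_pairs(circular_leaf_order(tree))
    total = np.zeros((n_states, n_states))
    for ta, tb in pairs:
        inc = pair_counts(alignment.row(ta), alignment.row(tb), n_states,
                          identity_min)
        if inc is not SKIP:
            total += inc
    return total


# ---------------------------------------------------------------------------
# normalization against 20-state counts
# ---------------------------------------------------------------------------

def mask_counts(counts: np.ndarray, alphabet: Alphabet) -> np.ndarray:
    """Merge expanded-state counts into amino-acid (group) counts."""
    g = alphabet.group_of
    ng = alphabet.n_groups
    out = np.zeros((ng, ng))
    gi, gj = np.meshgrid(g, g, indexing="ij")
    np.add.at(out, (gi, gj), counts)
    return out


def normalize_counts(counts55: np.ndarray, counts20: np.ndarray,
                     alphabet: Alphabet,
                     pseudocount: float | None = None) -> np.ndarray:
    """Rescale each amino-acid-pair submatrix to match the 20-state counts.

    For every pair (A, A') the submatrix of the expanded counts is scaled to
    sum to the amino-acid count n_AA'. A submatrix with zero observed counts
    but positive target raises an error unless a ``pseudocount`` is given, in
    which case the target mass is spread uniformly over the submatrix.
    """
    N = np.asarray(counts55, dtype=float)
    M = np.asarray(counts20, dtype=float)
    g = alphabet.group_of
    ng = alphabet.n_groups
    if N.shape != (alphabet.n_states,) * 2 or M.shape != (ng, ng):
        raise CountingError("count-matrix dimensions do not match alphabet")
    out = np.zeros_like(N)
    for a in range(ng):
        rows = np.flatnonzero(g == a)
        for b in range(a, ng):
            cols = np.flatnonzero(g == b)
            sub = N[np.ix_(rows, cols)]
            s = sub.sum()
            target = M[a, b]
            if s > 0:
                scaled = sub * (target / s)
            elif target > 0:
                if pseudocount is None:
                    raise CountingError(
                        f"no expanded counts for amino-acid pair "
                        f"({alphabet.groups[a]}, {alphabet.groups[b]}) with "
                        f"nonzero 20-state count {target}")
                scaled = np.full_like(sub, target / sub.size)
            else:
                scaled = sub * 0.0
            out[np.ix_(rows, cols)] = scaled
            if a != b:
                out[np.ix_(cols, rows)] = scaled.T
    return out
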