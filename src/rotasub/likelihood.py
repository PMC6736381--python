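"""Phylogenetic likelihood on expanded state spaces.

Implements transition probabilities P(t) = exp(tQ), the pruning algorithm
with per-node rescaling, discretized-gamma rate heterogeneity (+G), maximum
likelihood estimation of branch lengths, the gamma shape, and state
frequencies (+F), and the branch-score (Euclidean) tree distance.

Gap and unknown characters are treated as total ambiguity (all-ones
conditional vectors). All computations assume a reversible model, which
makes the likelihood invariant to root placement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp
from scipy.stats import gamma as gamma_dist

from .alphabet_io import RotasequenceAlignment
from .model_build import (RateModel, exchangeabilities_to_irm,
                          irm_to_exchangeabilities)
from .trees import IndexedTree, TreeError, as_indexed, clone

DEFAULT_MIN_BL = 1e-6
DEFAULT_MAX_BL = 100.0


class LikelihoodError(ValueError):
    pass


# ---------------------------------------------------------------------------
# transition probabilities and gamma rates
# ---------------------------------------------------------------------------

def transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(tQ) for a generic rate matrix (scaling-and-squaring)."""
    from scipy.linalg import expm

    if t < 0:
        raise LikelihoodError(f"negative time {t}")
    P = expm(np.asarray(Q, dtype=float) * t)
    np.clip(P, 0.0, 1.0, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


@dataclass(frozen=True)
class GammaRates:
    """Discretized gamma among-site rate variation with equal-weight bins."""

    alpha: float
    rates: tuple[float, ...]

    @property
    def k(self) -> int:
        return len(self.rates)


def discrete_gamma(alpha: float, k: int = 4) -> GammaRates:
    """Equal-probability bins with category means (Yang's mean method)."""
    if alpha <= 0:
        raise LikelihoodError(f"gamma shape must be positive: {alpha}")
    if k < 1:
        raise LikelihoodError("at least one category required")
    # shape alpha, rate alpha -> mean 1; bin boundaries at quantiles i/k
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1 / alpha)
    # E[X ; a<X<b] for Gamma(alpha, rate alpha) = CDF_{alpha+1}(b) - CDF_{alpha+1}(a)
    upper = gamma_dist.cdf(edges, a=alpha + 1, scale=1 / alpha)
    means = k * np.diff(upper)
    means = means / means.mean()  # exact unit mean despite roundoff
    return GammaRates(alpha=float(alpha), rates=tuple(float(m) for m in means))


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def _check_taxa(itree: IndexedTree, alignment: RotasequenceAlignment) -> dict:
    tree_taxa = set(itree.leaf_label_list())
    aln_taxa = set(alignment.taxa)
    if tree_taxa != aln_taxa:
        missing = sorted(tree_taxa - aln_taxa)
        extra = sorted(aln_taxa - tree_taxa)
        raise LikelihoodError(
            f"taxon mismatch: in tree but not alignment {missing}; "
            f"in alignment but not tree {extra}")
    return {t: i for i, t in enumerate(alignment.taxa)}


def _leaf_partial(codes: np.ndarray, n_states: int) -> np.ndarray:
    """(n_states, n_sites) indicator partials; gap/unknown -> all ones."""
    n_sites = len(codes)
    L = np.zeros((n_states, n_sites))
    observed = codes >= 0
    L[codes[observed], np.flatnonzero(observed)] = 1.0
    L[:, ~observed] = 1.0
    return L


def _down_pass(itree: IndexedTree, model: RateModel, tips: dict[int, np.ndarray],
               rate: float = 1.0, edge_lengths: np.ndarray | None = None):
    """Post-order conditional likelihoods with per-node rescaling.

    Returns (partials, log_scalers): partials[v] is (n_states, n_sites), the
    likelihood of data below v given the state at v; log_scalers[v] holds the
    per-site log of the factored-out scale.
    """
    t = itree.edge_length if edge_lengths is None else edge_lengths
    n = itree.n_nodes
    down: list[np.ndarray | None] = [None] * n
    logs: list[np.ndarray | None] = [None] * n
    n_sites = next(iter(tips.values())).shape[1]
    for v in itree.postorder:
        if itree.is_leaf[v]:
            down[v] = tips[v]
            logs[v] = np.zeros(n_sites)
            continue
        part = np.ones((model.n_states, n_sites))
        scale = np.zeros(n_sites)
        for c in itree.children[v]:
            P = model.transition_matrix(t[c] * rate)
            part = part * (P @ down[c])
            scale += logs[c]
        m = part.max(axis=0)
        m = np.where(m > 0, m, 1.0)
        down[v] = part / m
        logs[v] = scale + np.log(m)
    return down, logs


def _up_pass(itree: IndexedTree, model: RateModel, down, dlogs,
             rate: float = 1.0, edge_lengths: np.ndarray | None = None):
    """Pre-order 'outside' vectors G[v]: pi-weighted likelihood of all data
    outside the subtree of v, expressed at node v (G[root] = pi)."""
    t = itree.edge_length if edge_lengths is None else edge_lengths
    n = itree.n_nodes
    n_sites = down[0].shape[1]
    G: list[np.ndarray | None] = [None] * n
    Glogs: list[np.ndarray | None] = [None] * n
    G[0] = np.tile(model.pi[:, None], (1, n_sites))
    Glogs[0] = np.zeros(n_sites)
    for u in itree.preorder:
        if itree.is_leaf[u]:
            continue
        kids = itree.children[u]
        contrib = [model.transition_matrix(t[c] * rate) @ down[c] for c in kids]
        for j, v in enumerate(kids):
            A = G[u].copy()
            Alog = Glogs[u].copy()
            for jj, c in enumerate(kids):
                if jj == j:
                    continue
                A = A * contrib[jj]
                Alog += dlogs[c]
            P = model.transition_matrix(t[v] * rate)
            Gv = P.T @ A
            m = Gv.max(axis=0)
            m = np.where(m > 0, m, 1.0)
            G[v] = Gv / m
            Glogs[v] = Alog + np.log(m)
    return G, Glogs


def _site_loglik_categories(itree, alignment, model, rates, edge_lengths=None):
    """Per-site log-likelihood, averaged over gamma categories if given."""
    row = _check_taxa(itree, alignment)
    tips = {v: _leaf_partial(alignment.codes[row[itree.labels[v]]],
                             model.n_states)
            for v in itree.leaves}
    cat_rates = rates.rates if rates is not None else (1.0,)
    per_cat = []
    for r in cat_rates:
        down, logs = _down_pass(itree, model, tips, rate=r,
                                edge_lengths=edge_lengths)
        siteL = model.pi @ down[0]
        with np.errstate(divide="ignore"):
            per_cat.append(np.log(siteL) + logs[0])
    if len(per_cat) == 1:
        return per_cat[0]
    return logsumexp(np.vstack(per_cat), axis=0) - np.log(len(per_cat))


def pruning_loglik(tree, alignment: RotasequenceAlignment, model: RateModel,
                   rates: GammaRates | None = None,
                   return_per_site: bool = False):
    """Total (and optionally per-site) log-likelihood by Felsenstein pruning."""
    itree = as_indexed(tree)
    site_ll = _site_loglik_categories(itree, alignment, model, rates)
    total = float(site_ll.sum())
    if return_per_site:
        return total, site_ll
    return total


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

def _edge_objective(itree, model, rates, tips, edge_lengths, v):
    """Return f(t) = -logL as a function of the length of the edge above v."""
    cat_rates = rates.rates if rates is not None else (1.0,)
    cache = []
    for r in cat_rates:
        down, dlogs = _down_pass(itree, model, tips, rate=r,
                                 edge_lengths=edge_lengths)
        G, Glogs = _up_pass(itree, model, down, dlogs, rate=r,
                            edge_lengths=edge_lengths)
        # G[v] already includes P over the current edge; rebuild A at parent
        u = itree.parent[v]
        A = G[u].copy()
        Alog = Glogs[u].copy()
        for c in itree.children[u]:
            if c == v:
                continue
            P = model.transition_matrix(edge_lengths[c] * r)
            A = A * (P @ down[c])
            Alog += dlogs[c]
        cache.append((r, A, Alog, down[v], dlogs[v]))

    def f(t: float) -> float:
        per_cat = []
        for r, A, Alog, Dv, Dlog in cache:
            P = model.transition_matrix(t * r)
            siteL = np.einsum("is,is->s", A, P @ Dv)
            with np.errstate(divide="ignore"):
                per_cat.append(np.log(siteL) + Alog + Dlog)
        if len(per_cat) == 1:
            return -float(per_cat[0].sum())
        return -float((logsumexp(np.vstack(per_cat), axis=0)
                       - np.log(len(per_cat))).sum())

    return f


def _optimize_edge(f, t0: float, min_bl: float, max_bl: float) -> float:
    """Minimize f over [min_bl, max_bl]: coarse log-spaced bracketing around
    the current value, then bounded Brent inside the bracket.

    Direct bounded Brent is unreliable here because the negative
    log-likelihood flattens into a plateau at large t and the golden-section
    probes can skip the basin entirely.
    """
    t0 = min(max(t0, min_bl), max_bl)
    grid = sorted({min_bl, max_bl,
                   *(min(max(t0 * m, min_bl), max_bl)
                     for m in (0.0625, 0.25, 0.5, 1.0, 2.0, 4.0, 16.0, 64.0))})
    vals = [f(t) for t in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if lo == hi:
        return float(lo)
    res = minimize_scalar(f, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x) if res.fun <= vals[i] else float(grid[i])


def optimize_branch_lengths(tree, alignment: RotasequenceAlignment,
                            model: RateModel,
                            rates: GammaRates | None = None,
                            tol: float = 1e-6, max_rounds: int = 50,
                            min_bl: float = DEFAULT_MIN_BL,
                            max_bl: float = DEFAULT_MAX_BL):
    """Coordinate-wise ML branch lengths on a fixed topology.

    Each round refreshes the conditional partials once and optimizes every
    branch with bounded Brent against them; rounds repeat until the total
    log-likelihood improves by less than ``tol``. Returns (tree, logL) with a
    new tree carrying the optimized lengths.
    """
    work = clone(tree) if isinstance(tree, dendropy.Tree) else clone(tree.tree)
    itree = IndexedTree(work)
    row = _check_taxa(itree, alignment)
    tips = {v: _leaf_partial(alignment.codes[row[itree.labels[v]]],
                             model.n_states)
            for v in itree.leaves}
    lengths = np.clip(itree.edge_length.copy(), min_bl, max_bl)
    lengths[0] = 0.0
    def total(ls: np.ndarray) -> float:
        return float(_site_loglik_categories(itree, alignment, model, rates,
                                             edge_lengths=ls).sum())

    best = total(lengths)
    converged = False
    for _ in range(max_rounds):
        # Jacobi step: optimize every edge against round-start partials ...
        proposal = lengths.copy()
        for v in range(1, itree.n_nodes):
            f = _edge_objective(itree, model, rates, tips, lengths, v)
            proposal[v] = _optimize_edge(f, lengths[v], min_bl, max_bl)
        # ... then damp the simultaneous update until it improves
        new, accepted = best, None
        lam = 1.0
        while lam > 2 ** -9:
            trial = lengths + lam * (proposal - lengths)
            trial[0] = 0.0
            val = total(trial)
            if val > best:
                new, accepted = val, trial
                break
            lam /= 2.0
        if accepted is None:
            converged = True     # no direction of improvement left
            break
        improved = new - best
        lengths, best = accepted, new
        if improved < tol:
            converged = True
            break
    if not converged and max_rounds > 0:
        warnings.warn("branch-length optimization stopped before convergence; "
                      "returning best lengths found", stacklevel=2)
    itree.set_edge_lengths(lengths)
    return work, best


def optimize_alpha(tree, alignment: RotasequenceAlignment, model: RateModel,
                   k: int = 4, bounds: tuple[float, float] = (0.02, 100.0)):
    """ML estimate of the gamma shape on a fixed tree. Returns (alpha, logL)."""
    itree = as_indexed(tree)

    def f(a: float) -> float:
        return -pruning_loglik(itree, alignment, model, discrete_gamma(a, k))

    # pre-bracket on a log grid: the likelihood flattens for large alpha and
    # plain bounded Brent can stall on the plateau
    grid = np.geomspace(bounds[0], bounds[1], 12)
    vals = [f(a) for a in grid]
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(f, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-4})
    if res.fun <= vals[i]:
        return float(res.x), -float(res.fun)
    return float(grid[i]), -float(vals[i])


def optimize_frequencies(tree, alignment: RotasequenceAlignment,
                         model: RateModel,
                         rates: GammaRates | None = None,
                         tol: float = 1e-7):
    """+F: ML state frequencies with the model's exchangeabilities held fixed.

    The frequencies are optimized on the softmax-transformed simplex; the
    rate matrix is rebuilt (and rescaled per the model's convention) at every
    evaluation. Returns (pi_hat, refitted model, logL).
    """
    itree = as_indexed(tree)
    S = irm_to_exchangeabilities(model.Q, model.pi)
    rescale = model.scaling if model.scaling != "none" else "rotamer"

    def build(z: np.ndarray) -> RateModel:
        logits = np.concatenate([z, [0.0]])
        pi = np.exp(logits - logsumexp(logits))
        pi = np.clip(pi, 1e-12, None)
        pi /= pi.sum()
        return exchangeabilities_to_irm(S, pi, model.alphabet, rescale=rescale)

    def f(z: np.ndarray) -> float:
        return -pruning_loglik(itree, alignment, build(z), rates)

    z0 = np.log(model.pi[:-1] / model.pi[-1])
    res = minimize(f, z0, method="L-BFGS-B",
                   options={"ftol": tol, "maxiter": 500})
    fitted = build(res.x)
    return fitted.pi, fitted, -float(res.fun)


# ---------------------------------------------------------------------------
# tree distance
# ---------------------------------------------------------------------------

def euclidean_tree_distance(tree1: dendropy.Tree, tree2: dendropy.Tree) -> float:
    """Branch-score distance: sqrt of summed squared branch-length differences
    over the union of bipartitions (absent bipartition = length 0)."""
    from dendropy.calculate import treecompare

    l1, l2 = set(t.taxon.label for t in tree1.leaf_node_iter() if t.taxon), \
        set(t.taxon.label for t in tree2.leaf_node_iter() if t.taxon)
    if l1 != l2:
        raise TreeError(f"leaf sets differ: {sorted(l1 ^ l2)}")
    ns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=tree1.as_string(schema="newick"),
                           schema="newick", taxon_namespace=ns,
                           preserve_underscores=True)
    t2 = dendropy.Tree.get(data=tree2.as_string(schema="newick"),
                           schema="newick", taxon_namespace=ns,
                           preserve_underscores=True)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return float(treecompare.euclidean_distance(t1, t2))
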