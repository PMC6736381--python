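"""Random trees and alignment simulation under any rate model.

Trees have random binary topologies built by sequential random attachment
with i.i.d. uniform branch lengths. Sequences evolve by exact
transition-probability sampling: the root is drawn from the equilibrium
frequencies and each child state from the parent's row of P(branch length),
independently across sites. This samples from exactly the same marginal
process as event-by-event simulation of the Markov chain.
"""

from __future__ import annotations

import dendropy
import numpy as np

from .alphabet_io import RotasequenceAlignment
from .likelihood import GammaRates
from .model_build import RateModel
from .trees import IndexedTree, as_indexed, clone


class SimulationError(ValueError):
    pass


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_tree(n_taxa: int, bl_range: tuple[float, float] = (0.01, 0.5),
                seed=None, taxon_prefix: str = "t") -> dendropy.Tree:
    """Random rooted binary tree by sequential random attachment.

    Each new leaf is attached at a uniformly chosen existing branch
    (including a virtual branch above the root), giving a uniform
    distribution over labelled rooted topologies. Branch lengths are i.i.d.
    uniform on ``bl_range``.
    """
    if n_taxa < 2:
        raise SimulationError("need at least 2 taxa")
    lo, hi = bl_range
    if not (0 <= lo <= hi):
        raise SimulationError(f"invalid branch-length range {bl_range}")
    rng = _as_rng(seed)

    # nested-list topology: leaves are ints, internal nodes are [left, right]
    root: list = [0, 1]
    edges: list[tuple[list, int]] = [(root, 0), (root, 1)]  # (parent, slot)
    for leaf in range(2, n_taxa):
        k = int(rng.integers(0, len(edges) + 1))
        if k == len(edges):  # attach above the root
            root = [root, leaf]
            edges.append((root, 0))
            edges.append((root, 1))
        else:
            parent, slot = edges[k]
            node = [parent[slot], leaf]
            parent[slot] = node
            edges[k] = (node, 0)
            edges.append((node, 1))
            edges.append((parent, slot))
    # re-enumerate edges by serialization, drawing lengths in a fixed order
    def newick(node) -> str:
        if isinstance(node, int):
            return f"{taxon_prefix}{node}:{rng.uniform(lo, hi):.10f}"
        return (f"({newick(node[0])},{newick(node[1])})"
                f":{rng.uniform(lo, hi):.10f}")

    text = f"({newick(root[0])},{newick(root[1])});"
    return dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True)


def scale_tree(tree: dendropy.Tree, factor: float) -> dendropy.Tree:
    """Return a copy with every branch length multiplied by ``factor``."""
    if factor <= 0:
        raise SimulationError(f"scale factor must be positive: {factor}")
    out = clone(tree)
    for edge in out.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * factor
    return out


def _draw_children(P: np.ndarray, parent_states: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per site from the parent state's row of P."""
    cum = np.cumsum(P, axis=1)
    u = rng.random(parent_states.shape[0])
    rows = cum[parent_states]
    return (u[:, None] < rows).argmax(axis=1).astype(np.int16)


def simulate_alignment(tree, model: RateModel, n_sites: int, seed=None,
                       record_internal: bool = True,
                       rates: GammaRates | None = None,
                       site_rates: np.ndarray | None = None):
    """Simulate a rotasequence alignment along a tree under ``model``.

    Returns ``(leaf_alignment, internal_alignment)``; the second entry is
    ``None`` unless ``record_internal``. With ``rates`` given, each site is
    assigned an equal-probability gamma rate category; explicit per-site rate
    multipliers can be supplied via ``site_rates`` instead.
    """
    if n_sites < 1:
        raise SimulationError("need at least one site")
    rng = _as_rng(seed)
    itree = as_indexed(tree)
    if site_rates is not None:
        r = np.asarray(site_rates, dtype=float)
        if r.shape != (n_sites,):
            raise SimulationError("site_rates must have length n_sites")
    elif rates is not None:
        r = np.array(rates.rates)[rng.integers(0, rates.k, size=n_sites)]
    else:
        r = None

    states = np.empty((itree.n_nodes, n_sites), dtype=np.int16)
    states[0] = rng.choice(model.n_states, size=n_sites, p=model.pi)
    for v in itree.preorder:
        if v == 0:
            continue
        t = itree.edge_length[v]
        if t == 0:
            states[v] = states[itree.parent[v]]
        elif r is None:
            P = model.transition_matrix(t)
            states[v] = _draw_children(P, states[itree.parent[v]], rng)
        else:
            parent = states[itree.parent[v]]
            out = np.empty(n_sites, dtype=np.int16)
            for cat in np.unique(r):
                idx = np.flatnonzero(r == cat)
                P = model.transition_matrix(t * cat)
                out[idx] = _draw_children(P, parent[idx], rng)
            states[v] = out
    leaf_aln = RotasequenceAlignment(
        [itree.labels[v] for v in itree.leaves], states[itree.leaves],
        model.alphabet)
    internal_aln = None
    if record_internal:
        internal = np.flatnonzero(~itree.is_leaf)
        internal_aln = RotasequenceAlignment(
            [itree.labels[v] for v in internal], states[internal],
            model.alphabet)
    return leaf_aln, internal_aln
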