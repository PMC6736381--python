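"""Joint and marginal ancestral state reconstruction on expanded state spaces.

Marginal reconstruction computes, per site and node, the posterior
distribution over states given all tip data (the normalized product of the
partial likelihoods of every subtree incident to the node). Joint
reconstruction finds the single assignment of states to all internal nodes
that maximizes the joint probability of tips and ancestors per site
(max-product dynamic programming with backtracking; ties broken toward the
lowest state index).

The leave-leaves-out (LLO) protocol removes a pair of terminal sibling taxa
(their characters become missing data), reconstructs states on the intact
tree, and reads off the sequence at one of the removed leaves — a proxy for
ancestral reconstruction accuracy when no true ancestor is available.
"""

from __future__ import annotations

import numpy as np

from .alphabet_io import UNKNOWN, RotasequenceAlignment
from .likelihood import (LikelihoodError, _check_taxa, _down_pass,
                         _leaf_partial, _up_pass)
from .model_build import RateModel
from .trees import IndexedTree, as_indexed


class AncestralError(ValueError):
    pass


def _tip_partials(itree: IndexedTree, alignment: RotasequenceAlignment,
                  model: RateModel, missing: set[str] = frozenset()):
    row = _check_taxa(itree, alignment)
    tips = {}
    for v in itree.leaves:
        label = itree.labels[v]
        if label in missing:
            tips[v] = np.ones((model.n_states, alignment.n_sites))
        else:
            tips[v] = _leaf_partial(alignment.codes[row[label]], model.n_states)
    return tips


def marginal_reconstruct(tree, alignment: RotasequenceAlignment,
                         model: RateModel, node: str,
                         missing: set[str] = frozenset()) -> np.ndarray:
    """Per-site posterior state distributions at ``node`` (n_sites, n_states).

    ``node`` may be an internal node label or — in LLO mode — a leaf whose
    characters were removed via ``missing``.
    """
    itree = as_indexed(tree)
    if node not in itree.by_label:
        raise AncestralError(f"node {node!r} not found in tree")
    v = itree.by_label[node]
    if itree.is_leaf[v] and itree.labels[v] not in missing:
        raise AncestralError(
            f"node {node!r} is an observed leaf; marginal reconstruction "
            f"applies to internal nodes or pruned terminals")
    tips = _tip_partials(itree, alignment, model, missing)
    down, dlogs = _down_pass(itree, model, tips)
    G, Glogs = _up_pass(itree, model, down, dlogs)
    post = (down[v] * G[v]).T            # (n_sites, n_states), G includes pi
    norm = post.sum(axis=1, keepdims=True)
    if (norm <= 0).any():
        raise AncestralError("zero posterior mass at some site")
    return post / norm


def joint_reconstruct(tree, alignment: RotasequenceAlignment,
                      model: RateModel,
                      missing: set[str] = frozenset()) -> dict[str, np.ndarray]:
    """Most probable joint assignment of states at all internal nodes.

    Returns ``{node_label: codes}``. Missing leaves (LLO) are also assigned,
    by maximizing over their states. Tips observed as gap/unknown at a site
    are marginalized (summed), matching the pruning likelihood.
    """
    itree = as_indexed(tree)
    tips = _tip_partials(itree, alignment, model, missing)
    n = model.n_states
    n_sites = alignment.n_sites
    # C[v][x, s]: max over states below v of log prob of subtree given the
    # PARENT of v in state x; B[v][x, s]: argmax state of v achieving it.
    C: list[np.ndarray | None] = [None] * itree.n_nodes
    B: list[np.ndarray | None] = [None] * itree.n_nodes
    with np.errstate(divide="ignore"):
        for v in itree.postorder:
            if v == 0:
                break
            logP = np.log(model.transition_matrix(itree.edge_length[v]))
            if itree.is_leaf[v]:
                tip = tips[v]
                if itree.labels[v] in missing:
                    # latent terminal: maximize over its state
                    C[v] = logP.max(axis=1)[:, None] * np.ones((1, n_sites))
                    B[v] = np.argmax(logP, axis=1)[:, None] \
                        * np.ones((1, n_sites), dtype=int)
                else:
                    observed = tip.argmax(axis=0)
                    ambiguous = tip.min(axis=0) > 0
                    # observed tip: term log P[x, obs]; ambiguous: log sum_y P = 0
                    C[v] = np.where(ambiguous[None, :], 0.0,
                                    logP[:, observed])
                    B[v] = np.where(ambiguous[None, :], UNKNOWN,
                                    observed[None, :])
                continue
            below = np.zeros((n, n_sites))
            for c in itree.children[v]:
                below += C[c]
            score = logP[:, :, None] + below[None, :, :]   # (x_par, x_v, s)
            B[v] = score.argmax(axis=1)
            C[v] = np.take_along_axis(score, B[v][:, None, :], axis=1)[:, 0, :]
    # root: maximize pi * product of children
    with np.errstate(divide="ignore"):
        root_score = np.log(model.pi)[:, None] * np.ones((1, n_sites)) \
            + sum(C[c] for c in itree.children[0])
    assignment = np.empty((itree.n_nodes, n_sites), dtype=np.int16)
    assignment[0] = root_score.argmax(axis=0)
    for v in itree.preorder:
        if v == 0:
            continue
        if itree.is_leaf[v] and itree.labels[v] not in missing:
            row = alignment.codes[alignment.taxa.index(itree.labels[v])]
            assignment[v] = row
            continue
        parent_states = assignment[itree.parent[v]]
        assignment[v] = np.take_along_axis(
            B[v], parent_states[None, :].astype(int), axis=0)[0]
    out = {}
    for v in range(itree.n_nodes):
        if not itree.is_leaf[v] or itree.labels[v] in missing:
            out[itree.labels[v]] = assignment[v].astype(np.int16)
    return out


def leave_leaves_out(tree, alignment: RotasequenceAlignment, model: RateModel,
                     sibling_pair: tuple[str, str], target: str | None = None,
                     algorithm: str = "joint") -> np.ndarray:
    """Reconstruct one removed terminal taxon from the rest of the alignment.

    ``sibling_pair`` must name two terminal sibling leaves; both are treated
    as unobserved and ``target`` (default: the first of the pair) is
    reconstructed on the intact tree with its original pendant branch length.
    Sites where every remaining taxon is gap/unknown come back as UNKNOWN.
    """
    a, b = sibling_pair
    itree = as_indexed(tree)
    for name in (a, b):
        if name not in itree.by_label or not itree.is_leaf[itree.by_label[name]]:
            raise AncestralError(f"{name!r} is not a terminal node")
    va, vb = itree.by_label[a], itree.by_label[b]
    if itree.parent[va] != itree.parent[vb]:
        raise AncestralError(f"{a!r} and {b!r} are not siblings")
    target = target or a
    if target not in (a, b):
        raise AncestralError("target must be one of the removed pair")
    missing = {a, b}
    row = _check_taxa(itree, alignment)
    others = [alignment.taxa.index(t) for t in alignment.taxa
              if t not in missing]
    uninformative = (alignment.codes[others] < 0).all(axis=0)
    if algorithm == "joint":
        states = joint_reconstruct(itree, alignment, model, missing)[target]
    elif algorithm == "marginal":
        post = marginal_reconstruct(itree, alignment, model, target, missing)
        states = post.argmax(axis=1).astype(np.int16)
    else:
        raise AncestralError(f"unknown algorithm {algorithm!r}")
    states = states.copy()
    states[uninformative] = UNKNOWN
    return states


def reconstruction_accuracy(inferred: np.ndarray, reference: np.ndarray,
                            alphabet=None) -> dict[str, float]:
    """Percent identity of a reconstruction against its reference.

    Positions where the reference is gap/unknown or the inference is UNKNOWN
    are excluded from the denominator. With an alphabet given, the masked
    (amino-acid) accuracy is reported alongside the full-state accuracy.
    """
    inferred = np.asarray(inferred)
    reference = np.asarray(reference)
    if inferred.shape != reference.shape:
        raise AncestralError("length mismatch between inference and reference")
    ok = (reference >= 0) & (inferred >= 0)
    n = int(ok.sum())
    out = {"n_compared": float(n)}
    if n == 0:
        out["state_percent"] = float("nan")
        if alphabet is not None:
            out["masked_percent"] = float("nan")
        return out
    out["state_percent"] = 100.0 * float(
        (inferred[ok] == reference[ok]).sum()) / n
    if alphabet is not None:
        gi = alphabet.group_of[inferred[ok]]
        gr = alphabet.group_of[reference[ok]]
        out["masked_percent"] = 100.0 * float((gi == gr).sum()) / n
    return out
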