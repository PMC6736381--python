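"""Synthetic generators: toy alphabets/models, coordinate sets with
prescribed chi1 angles, planted substitution families, and torsion samples.

Everything is reproducible bit-for-bit from an explicit seed. Toy expanded
alphabets mirror the amino-acid x rotamer structure at reduced size (default
four pseudo-residues with multiplicities 3, 3, 2, 1 — nine states) so that
brute-force oracles stay affordable. The generators make no attempt to mimic
real protein-structure statistics.
"""

from __future__ import annotations

import string

import numpy as np

from .alphabet_io import (SINGLE_CHARS_55, Alphabet, RotamerState,
                          RotasequenceAlignment)
from .counting import mask_counts
from .likelihood import GammaRates
from .model_build import RateModel, model_from_counts
from .rotamer_assignment import (CHI1_FOURTH_ATOM, ROTAMER_MULTIPLICITY,
                                 ResidueRecord)
from .simulate import simulate_alignment
from .trees import as_indexed


class FixtureError(ValueError):
    pass


DEFAULT_MULTIPLICITIES = (3, 3, 2, 1)


def toy_alphabet(multiplicities=DEFAULT_MULTIPLICITIES,
                 name: str = "toy") -> Alphabet:
    """A reduced expanded alphabet of pseudo-residues."""
    if not multiplicities or any(m not in (1, 2, 3) for m in multiplicities):
        raise FixtureError("multiplicities must be drawn from {1, 2, 3}")
    if len(multiplicities) > 20:
        raise FixtureError("at most 20 pseudo-residues")
    states = []
    for k, m in enumerate(multiplicities):
        letter = string.ascii_uppercase[k]
        group = f"X{letter}"
        if m == 1:
            states.append(RotamerState(group, letter, None))
        else:
            states.extend(RotamerState(group, letter, r)
                          for r in range(1, m + 1))
    chars = SINGLE_CHARS_55[: len(states)]
    return Alphabet(states, chars, name=name)


def toy_counts(alphabet: Alphabet, seed=None, low: int = 5,
               high: int = 60, within_boost: float = 20.0) -> np.ndarray:
    """Random symmetric counts with heavy diagonal (conservation) and boosted
    within-amino-acid rotamer exchange.

    The boost makes pure chi1 flips a substantial fraction of all events, as
    in empirical rotamer data where roughly 0.8 rotamer-only changes
    accompany each amino-acid substitution at equilibrium.
    """
    rng = np.random.default_rng(seed)
    n = alphabet.n_states
    N = rng.integers(low, high, size=(n, n)).astype(float)
    N = (N + N.T) / 2.0
    g = alphabet.group_of
    within = g[:, None] == g[None, :]
    N[within] *= within_boost
    N[np.diag_indices(n)] = rng.integers(10 * high, 20 * high, size=n)
    return N


def toy_model(multiplicities=DEFAULT_MULTIPLICITIES, seed=0,
              scaling: str = "superscaled"):
    """A random reversible expanded model plus its correctly lumped coarse
    counterpart (built from the merged counts).

    Returns ``(fine_model, coarse_model, fine_counts)``.
    """
    alphabet = toy_alphabet(multiplicities)
    counts = toy_counts(alphabet, seed=seed)
    fine = model_from_counts(counts, alphabet, scaling=scaling,
                             name="toy-fine")
    coarse = model_from_counts(mask_counts(counts, alphabet),
                               alphabet.masked(), scaling=scaling,
                               name="toy-coarse")
    return fine, coarse, counts


# ---------------------------------------------------------------------------
# coordinates realizing prescribed chi1 angles
# ---------------------------------------------------------------------------

_BOND_CA_CB = 1.53
_ANGLE_N_CA_CB = 110.5
_BOND_CB_X = 1.52
_ANGLE_CA_CB_X = 114.0


def place_atom(a, b, c, bond: float, angle_deg: float,
               dihedral_deg: float) -> np.ndarray:
    """Internal-to-Cartesian (NeRF) placement of atom d.

    d is at distance ``bond`` from c, with bond angle b-c-d ``angle_deg`` and
    dihedral a-b-c-d ``dihedral_deg`` (IUPAC sign convention).
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    chi = np.radians(dihedral_deg)
    d_local = np.array([-bond * np.cos(ang),
                        bond * np.sin(ang) * np.cos(chi),
                        bond * np.sin(ang) * np.sin(chi)])
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def toy_structure(sequence: list[str], chi1_targets: list[float | None],
                  b_factor: float = 15.0,
                  b_factor_overrides: dict[int, float] | None = None,
                  bond_length: float = 1.33,
                  bond_overrides: dict[int, float] | None = None
                  ) -> list[ResidueRecord]:
    """Residue records with side-chain atoms realizing prescribed chi1 angles.

    ``chi1_targets`` must give an angle for every chi1-bearing residue and
    ``None`` for ALA/GLY. Per-residue B-factor and peptide-bond overrides
    exercise the quality filters.
    """
    if len(sequence) != len(chi1_targets):
        raise FixtureError("one chi1 target (or None) per residue required")
    b_factor_overrides = b_factor_overrides or {}
    bond_overrides = bond_overrides or {}
    records = []
    for i, (name, chi1) in enumerate(zip(sequence, chi1_targets)):
        name = name.upper()
        mult = ROTAMER_MULTIPLICITY.get(name)
        if mult == 0 and chi1 is not None:
            raise FixtureError(f"{name} admits no chi1 target")
        if mult not in (None, 0) and chi1 is None:
            raise FixtureError(f"{name} requires a chi1 target")
        offset = np.array([0.0, 0.0, 5.0 * i])
        N = offset
        CA = offset + np.array([1.458, 0.0, 0.0])
        # carbonyl C placed exactly bond_length from the next residue's N so
        # a serialized chain is continuous unless an override says otherwise
        next_N = np.array([0.0, 0.0, 5.0 * (i + 1)])
        C = next_N - np.array([0.0, 0.0,
                               bond_overrides.get(i, bond_length)])
        coords = {"N": N, "CA": CA, "C": C}
        if chi1 is not None:
            theta = np.radians(180.0 - _ANGLE_N_CA_CB)
            CB = CA + _BOND_CA_CB * np.array([np.cos(theta), np.sin(theta),
                                              0.0])
            coords["CB"] = CB
            fourth = CHI1_FOURTH_ATOM[name]
            coords[fourth] = place_atom(N, CA, CB, _BOND_CB_X,
                                        _ANGLE_CA_CB_X, chi1)
        b = b_factor_overrides.get(i, b_factor)
        records.append(ResidueRecord(
            name=name, chain="A", position=i + 1, coords=coords,
            b_factors={atom: b for atom in coords},
            next_bond_length=(bond_overrides.get(i, bond_length)
                              if i + 1 < len(sequence) else None)))
    return records


def write_toy_pdb(path, records: list[ResidueRecord]) -> None:
    """Serialize toy records as a minimal PDB file (for reader round-trips)."""
    with open(path, "w") as fh:
        serial = 1
        for res in records:
            for atom, xyz in res.coords.items():
                b = res.b_factors.get(atom, 0.0)
                elem = atom[0]
                fh.write(
                    f"ATOM  {serial:5d} {atom:<4s} {res.name:>3s} "
                    f"{res.chain}{res.position:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{res.occupancy:6.2f}{b:6.2f}          {elem:>2s}\n")
                serial += 1
        fh.write("END\n")


# ---------------------------------------------------------------------------
# planted families and torsion samples
# ---------------------------------------------------------------------------

def planted_family(tree, model: RateModel, n_sites: int, seed=0,
                   rates: GammaRates | None = None):
    """Simulation with event bookkeeping for counting/reconstruction truth.

    Returns a dict with the leaf alignment, the internal-node alignment, and
    ``branch_pair_counts`` — a symmetric matrix tallying (parent state,
    child state) pairs over all branches and sites, the planted analogue of
    a substitution count matrix.
    """
    itree = as_indexed(tree)
    leaf_aln, internal_aln = simulate_alignment(
        itree, model, n_sites, seed=seed, record_internal=True, rates=rates)
    label_to_row = {}
    all_states = np.empty((itree.n_nodes, n_sites), dtype=np.int16)
    for aln in (leaf_aln, internal_aln):
        for i, t in enumerate(aln.taxa):
            label_to_row[t] = aln.codes[i]
    for v in range(itree.n_nodes):
        all_states[v] = label_to_row[itree.labels[v]]
    n = model.n_states
    events = np.zeros((n, n))
    for v in range(1, itree.n_nodes):
        p = all_states[itree.parent[v]]
        c = all_states[v]
        np.add.at(events, (p, c), 1.0)
        np.add.at(events, (c, p), 1.0)
    return {"leaves": leaf_aln, "internal": internal_aln,
            "branch_pair_counts": events, "tree": itree}


def torsion_samples(component_means, concentrations, weights, n: int,
                    seed=0) -> tuple[np.ndarray, np.ndarray]:
    """(phi, psi) samples from a mixture of independent von Mises components.

    ``component_means`` is a sequence of (phi, psi) centers in degrees;
    ``concentrations`` the per-component kappa; ``weights`` must sum to 1.
    """
    means = np.atleast_2d(np.asarray(component_means, dtype=float))
    kappas = np.atleast_1d(np.asarray(concentrations, dtype=float))
    w = np.atleast_1d(np.asarray(weights, dtype=float))
    if len(means) != len(kappas) or len(means) != len(w):
        raise FixtureError("component arrays must have equal length")
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-8:
        raise FixtureError("weights must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(w), size=n, p=w)
    phi = np.degrees(rng.vonmises(np.radians(means[comp, 0]), kappas[comp]))
    psi = np.degrees(rng.vonmises(np.radians(means[comp, 1]), kappas[comp]))
    return phi, psi


def random_alignment(alphabet: Alphabet, taxa: list[str], n_sites: int,
                     seed=0, gap_fraction: float = 0.0
                     ) -> RotasequenceAlignment:
    """I.i.d. uniform random alignment (no phylogenetic signal)."""
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, alphabet.n_states,
                         size=(len(taxa), n_sites)).astype(np.int16)
    if gap_fraction > 0:
        gaps = rng.random(codes.shape) < gap_fraction
        codes[gaps] = -1
    return RotasequenceAlignment(taxa, codes, alphabet)
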