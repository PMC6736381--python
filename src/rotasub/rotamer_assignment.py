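"""chi1 rotamer assignment from atomic coordinates.

The chi1 dihedral is defined by N, C-alpha, C-beta and the first side-chain
atom beyond C-beta (C-gamma for most residues; O-gamma for SER, O-gamma-1
for THR, C-gamma-1 for ILE/VAL, S-gamma for CYS). Angles fall into three
wells (~60deg, ~-180deg, ~-60deg; two for proline at ~27deg/~-25deg) and are
binned by equidistant boundaries between the wells:

    [0, 120) -> 1 (gauche+), [120, 180] u [-180, -120) -> 2 (trans),
    [-120, 0) -> 3 (gauche-);  proline: chi1 >= 0 -> 1, else -> 2.

Quality filters mirror a structure-harvest pipeline: residues are masked
(emitted as UNKNOWN, keeping the sequence frame) when the mean B-factor of
the four chi1 atoms exceeds 30, when the peptide bond to the next residue
exceeds 1.8 A (chain break), or when the residue is nonstandard or
disordered (missing chi1 atoms / zero occupancy). Resolution filtering is a
structure-level metadata predicate and is not re-derived here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alphabet_io import (AMINO_ACIDS_3, ROTAMER_MULTIPLICITY, UNKNOWN,
                          Alphabet, RotamerState, Rotasequence,
                          build_alphabet)

DEFAULT_B_MAX = 30.0
DEFAULT_BOND_MAX = 1.8

#: fourth chi1-defining atom per residue (N, CA, CB are the first three)
CHI1_FOURTH_ATOM = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG",
    "GLU": "CG", "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG",
    "MET": "CG", "PHE": "CG", "PRO": "CG", "SER": "OG", "THR": "OG1",
    "TRP": "CG", "TYR": "CG", "VAL": "CG1",
}


class GeometryError(ValueError):
    pass


class AssignmentError(ValueError):
    pass


def chi1_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in degrees, IUPAC convention, in (-180, 180].

    The angle of p4 relative to p1 viewed along the p2->p3 axis; the
    eclipsed (cis) arrangement is 0.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm2 = np.linalg.norm(b2)
    if norm2 == 0 or np.linalg.norm(n1) < 1e-10 * max(1, np.linalg.norm(b1)) \
            or np.linalg.norm(n2) < 1e-10 * max(1, np.linalg.norm(b3)):
        raise GeometryError("degenerate geometry: collinear chi1 atoms")
    x = float(n1 @ n2)
    y = float(np.cross(n1, n2) @ (b2 / norm2))
    angle = np.degrees(np.arctan2(y, x))
    return 180.0 if angle <= -180.0 else float(angle)


def wrap_angle(angle: float) -> float:
    """Map any angle in degrees to (-180, 180]."""
    a = (float(angle) + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def assign_rotamer(residue_name: str, chi1_degrees: float) -> int:
    """Nearest-well rotamer index for a chi1 angle (1, 2, or 3; 1-2 for PRO)."""
    name = residue_name.upper()
    if name not in AMINO_ACIDS_3:
        raise AssignmentError(f"unknown residue {residue_name!r}")
    if ROTAMER_MULTIPLICITY[name] == 0:
        raise AssignmentError(f"{name} has no chi1 rotamer")
    a = wrap_angle(chi1_degrees)
    if name == "PRO":
        return 1 if a >= 0 else 2
    if 0 <= a < 120:
        return 1
    if a >= 120 or a < -120:
        return 2
    return 3


@dataclass
class ResidueRecord:
    """One residue's chi1-relevant structural data."""

    name: str                     # 3-letter residue name
    chain: str = "A"
    position: int = 0
    coords: dict = field(default_factory=dict)      # atom -> (3,) array, A
    b_factors: dict = field(default_factory=dict)   # atom -> B, A^2
    next_bond_length: float | None = None           # C(i)-N(i+1) distance, A
    occupancy: float = 1.0
    standard: bool = True

    def chi1_atoms(self) -> list[str] | None:
        fourth = CHI1_FOURTH_ATOM.get(self.name.upper())
        if fourth is None:
            return None
        return ["N", "CA", "CB", fourth]


def filter_residue(rec: ResidueRecord, b_max: float = DEFAULT_B_MAX,
                   bond_max: float = DEFAULT_BOND_MAX) -> tuple[bool, str | None]:
    """Keep/drop decision with a reason code (always returns a decision)."""
    name = rec.name.upper()
    if not rec.standard or name not in AMINO_ACIDS_3:
        return False, "nonstandard"
    if rec.occupancy <= 0:
        return False, "disordered"
    if rec.next_bond_length is not None and rec.next_bond_length > bond_max:
        return False, "chain_break"
    atoms = rec.chi1_atoms()
    if atoms is None:          # ALA/GLY: no chi1, no B-factor filter
        return True, None
    if any(a not in rec.coords for a in atoms):
        return False, "disordered"
    if any(a not in rec.b_factors for a in atoms):
        return False, "missing_b_factor"
    mean_b = float(np.mean([rec.b_factors[a] for a in atoms]))
    if mean_b > b_max:
        return False, "b_factor"
    if any(not np.isfinite(rec.coords[a]).all() for a in atoms):
        return False, "disordered"
    return True, None


def structure_to_rotasequence(records: list[ResidueRecord],
                              alphabet: Alphabet | None = None,
                              b_max: float = DEFAULT_B_MAX,
                              bond_max: float = DEFAULT_BOND_MAX,
                              label: str = "chain") -> Rotasequence:
    """Convert one polypeptide chain into a rotasequence.

    Filtered residues emit UNKNOWN (the sequence frame is preserved);
    alanine and glycine emit their single state.
    """
    if not records:
        raise AssignmentError("empty chain")
    alphabet = alphabet or build_alphabet()
    codes = np.full(len(records), UNKNOWN, dtype=np.int16)
    for i, rec in enumerate(records):
        keep, _ = filter_residue(rec, b_max=b_max, bond_max=bond_max)
        if not keep:
            continue
        name = rec.name.upper()
        one = {s.amino_acid: s.one_letter for s in alphabet.states}[name] \
            if name in {s.amino_acid for s in alphabet.states} else None
        if one is None:
            continue
        if ROTAMER_MULTIPLICITY[name] == 0:
            codes[i] = alphabet.index(RotamerState(name, one, None))
            continue
        atoms = rec.chi1_atoms()
        try:
            chi1 = chi1_dihedral(*(rec.coords[a] for a in atoms))
        except GeometryError:
            continue
        rot = assign_rotamer(name, chi1)
        codes[i] = alphabet.index(RotamerState(name, one, rot))
    return Rotasequence(label, codes, alphabet)


# ---------------------------------------------------------------------------
# structure file reading (PDB / mmCIF via Biopython)
# ---------------------------------------------------------------------------

def read_structure_records(path, chain: str | None = None,
                           model_index: int = 0) -> list[ResidueRecord]:
    """Extract chi1-relevant residue records from a PDB or mmCIF file.

    Takes the highest-occupancy conformer for disordered atoms (Biopython's
    default altloc selection). Heteroatoms and waters are skipped.
    """
    from Bio.PDB import MMCIFParser, PDBParser

    path = str(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tolerate sparse toy files
        if path.endswith((".cif", ".mmcif")):
            structure = MMCIFParser(QUIET=True).get_structure("s", path)
        else:
            structure = PDBParser(QUIET=True).get_structure("s", path)
    model = list(structure)[model_index]
    chains = [c for c in model if chain is None or c.id == chain]
    if not chains:
        raise AssignmentError(f"chain {chain!r} not found")
    records: list[ResidueRecord] = []
    residues = [r for c in chains[:1] for r in c
                if r.id[0] == " "]        # polypeptide residues only
    for i, res in enumerate(residues):
        name = res.get_resname().upper()
        coords, bfac = {}, {}
        for atom in res.get_atoms():
            coords[atom.get_name()] = np.array(atom.get_coord(), dtype=float)
            bfac[atom.get_name()] = float(atom.get_bfactor())
        occ = min((a.get_occupancy() or 1.0 for a in res.get_atoms()),
                  default=0.0)
        bond = None
        if i + 1 < len(residues) and "C" in coords:
            nxt = residues[i + 1]
            if "N" in nxt:
                bond = float(np.linalg.norm(coords["C"]
                                            - np.array(nxt["N"].get_coord())))
        records.append(ResidueRecord(
            name=name, chain=chains[0].id, position=res.id[1], coords=coords,
            b_factors=bfac, next_bond_length=bond, occupancy=occ,
            standard=name in AMINO_ACIDS_3))
    if not records:
        raise AssignmentError("empty chain")
    return records
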