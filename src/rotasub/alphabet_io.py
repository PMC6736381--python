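"""Expanded amino-acid x chi1-rotamer alphabets, sequence containers, and file formats.

The expanded state set pairs each amino acid with a discrete chi1 rotamer
configuration: most residues have three chi1 wells (~60deg, ~-180deg, ~-60deg,
labelled 1/2/3), proline has two (~27deg, ~-25deg), and alanine/glycine have no
side-chain chi1 and contribute a single state each, for 55 states in total.
Sequences over this alphabet are called *rotasequences*.

Two text encodings are defined:

* single-character: states in canonical row order map onto the 55-symbol
  string ``0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnops`` (gap ``-``,
  unknown ``?``), so rotasequence alignments can be stored as plain FASTA;
* two-token: amino-acid one-letter code plus rotamer digit (``F1``, ``R2``),
  with ``A-``/``G-`` for alanine/glycine, whitespace separated.

Model files follow a PAML-dat-like layout generalized to any state count:
lower-triangle exchangeabilities followed by equilibrium frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

GAP = -1
UNKNOWN = -2
GAP_CHAR = "-"
UNKNOWN_CHAR = "?"

#: canonical single-character code table for the 55-state alphabet
SINGLE_CHARS_55 = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrs"

#: Table-1 row order: alphabetical by three-letter residue name
AMINO_ACIDS_3 = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: number of chi1 rotamer configurations per residue (0 = no chi1)
ROTAMER_MULTIPLICITY = {aa: 3 for aa in AMINO_ACIDS_3}
ROTAMER_MULTIPLICITY["ALA"] = 0
ROTAMER_MULTIPLICITY["GLY"] = 0
ROTAMER_MULTIPLICITY["PRO"] = 2


class AlphabetError(ValueError):
    """Invalid state, symbol, or alphabet construction."""


@dataclass(frozen=True)
class RotamerState:
    """One expanded state: an amino acid plus an optional chi1 rotamer index."""

    amino_acid: str          # group label, e.g. "PHE" (or a toy pseudo-residue)
    one_letter: str          # single-letter group code, e.g. "F"
    rotamer_index: int | None

    def __post_init__(self) -> None:
        if self.rotamer_index is not None and self.rotamer_index < 1:
            raise AlphabetError(f"rotamer index must be >= 1: {self.rotamer_index}")

    @property
    def two_token(self) -> str:
        idx = "-" if self.rotamer_index is None else str(self.rotamer_index)
        return f"{self.one_letter}{idx}"

    def __str__(self) -> str:  # e.g. PHE1, ALA
        idx = "" if self.rotamer_index is None else str(self.rotamer_index)
        return f"{self.amino_acid}{idx}"


class Alphabet:
    """An ordered expanded state set with its encodings.

    Supports the canonical 55-state alphabet, plain residue alphabets
    (multiplicity 1 everywhere), and reduced toy alphabets used in testing.
    """

    def __init__(self, states: Sequence[RotamerState], single_chars: str,
                 name: str = ""):
        if len(states) != len(single_chars):
            raise AlphabetError("one single-character code required per state")
        if len(set(single_chars)) != len(single_chars):
            raise AlphabetError("single-character codes must be unique")
        if GAP_CHAR in single_chars or UNKNOWN_CHAR in single_chars:
            raise AlphabetError("'-' and '?' are reserved for gap/unknown")
        self.states: tuple[RotamerState, ...] = tuple(states)
        self.single_chars = single_chars
        self.name = name

        self._index = {s: i for i, s in enumerate(self.states)}
        if len(self._index) != len(self.states):
            raise AlphabetError("duplicate states")
        self._by_two_token = {s.two_token: i for i, s in enumerate(self.states)}
        self._by_char = {c: i for i, c in enumerate(single_chars)}

        # group (amino-acid) structure, in order of first appearance
        groups: list[str] = []
        letters: list[str] = []
        for s in self.states:
            if s.amino_acid not in groups:
                groups.append(s.amino_acid)
                letters.append(s.one_letter)
        self.groups: tuple[str, ...] = tuple(groups)
        self.group_letters: tuple[str, ...] = tuple(letters)
        gidx = {g: i for i, g in enumerate(groups)}
        self.group_of = np.array([gidx[s.amino_acid] for s in self.states])
        self.group_sizes = np.bincount(self.group_of, minlength=len(groups))

    # -- basics -----------------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def index(self, state: RotamerState) -> int:
        try:
            return self._index[state]
        except KeyError:
            raise AlphabetError(f"state not in alphabet: {state}") from None

    def states_of_group(self, group: str | int) -> list[int]:
        g = group if isinstance(group, int) else self.groups.index(group)
        return list(np.flatnonzero(self.group_of == g))

    # -- encodings --------------------------------------------------------
    def encode_char(self, c: str) -> int:
        if c == GAP_CHAR:
            return GAP
        if c == UNKNOWN_CHAR:
            return UNKNOWN
        try:
            return self._by_char[c]
        except KeyError:
            raise AlphabetError(f"invalid symbol {c!r}") from None

    def decode_char(self, code: int) -> str:
        if code == GAP:
            return GAP_CHAR
        if code == UNKNOWN:
            return UNKNOWN_CHAR
        return self.single_chars[code]

    def encode_token(self, tok: str) -> int:
        if tok == GAP_CHAR:
            return GAP
        if tok == UNKNOWN_CHAR:
            return UNKNOWN
        try:
            return self._by_two_token[tok]
        except KeyError:
            raise AlphabetError(f"invalid state token {tok!r}") from None

    def decode_token(self, code: int) -> str:
        if code == GAP:
            return GAP_CHAR
        if code == UNKNOWN:
            return UNKNOWN_CHAR
        return self.states[code].two_token

    def encode(self, text: str) -> np.ndarray:
        return np.array([self.encode_char(c) for c in text], dtype=np.int16)

    def decode(self, codes: Iterable[int]) -> str:
        return "".join(self.decode_char(int(c)) for c in codes)

    # -- masking ----------------------------------------------------------
    def masked(self) -> "Alphabet":
        """The coarse alphabet obtained by dropping rotamer indices."""
        states = [RotamerState(g, l, None)
                  for g, l in zip(self.groups, self.group_letters)]
        return Alphabet(states, "".join(self.group_letters),
                        name=f"{self.name}-masked" if self.name else "masked")

    def mask_codes(self, codes: np.ndarray) -> np.ndarray:
        """Map fine state codes to coarse group codes; GAP/UNKNOWN preserved."""
        codes = np.asarray(codes)
        out = np.where(codes >= 0, self.group_of[np.clip(codes, 0, None)], codes)
        return out.astype(np.int16)

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, Alphabet) and self.states == other.states
                and self.single_chars == other.single_chars)

    def __hash__(self) -> int:
        return hash((self.states, self.single_chars))

    def __repr__(self) -> str:
        return f"Alphabet({self.name or 'anonymous'}, {self.n_states} states)"


def build_alphabet() -> Alphabet:
    """The canonical 55-state amino-acid x chi1-rotamer alphabet."""
    states = []
    for aa in AMINO_ACIDS_3:
        mult = ROTAMER_MULTIPLICITY[aa]
        one = THREE_TO_ONE[aa]
        if mult == 0:
            states.append(RotamerState(aa, one, None))
        else:
            states.extend(RotamerState(aa, one, r) for r in range(1, mult + 1))
    return Alphabet(states, SINGLE_CHARS_55, name="rotamer55")


def build_amino_acid_alphabet() -> Alphabet:
    """The plain 20-state amino-acid alphabet (one-letter codes as symbols)."""
    return build_alphabet().masked()


def mask(codes: np.ndarray, alphabet: Alphabet) -> np.ndarray:
    """Mask rotamer information, (A,R) -> A, preserving gap/unknown."""
    return alphabet.mask_codes(codes)


# ---------------------------------------------------------------------------
# sequence containers
# ---------------------------------------------------------------------------

class Rotasequence:
    """A single labelled sequence of expanded-state codes."""

    def __init__(self, label: str, codes: np.ndarray, alphabet: Alphabet):
        self.label = label
        self.codes = np.asarray(codes, dtype=np.int16)
        self.alphabet = alphabet
        bad = (self.codes >= alphabet.n_states) | (self.codes < UNKNOWN)
        if bad.any():
            pos = int(np.flatnonzero(bad)[0])
            raise AlphabetError(
                f"sequence {label!r}: invalid state code {self.codes[pos]} "
                f"at position {pos}")

    def __len__(self) -> int:
        return len(self.codes)

    def mask(self) -> "Rotasequence":
        return Rotasequence(self.label, self.alphabet.mask_codes(self.codes),
                            self.alphabet.masked())

    def __str__(self) -> str:
        return self.alphabet.decode(self.codes)


class RotasequenceAlignment:
    """A rectangular multiple alignment of rotasequences."""

    def __init__(self, taxa: Sequence[str], codes: np.ndarray,
                 alphabet: Alphabet):
        codes = np.asarray(codes, dtype=np.int16)
        if codes.ndim != 2:
            raise AlphabetError("alignment codes must be 2-D (taxa x sites)")
        if len(taxa) != codes.shape[0]:
            raise AlphabetError("one taxon label per row required")
        if len(set(taxa)) != len(taxa):
            dupes = sorted({t for t in taxa if list(taxa).count(t) > 1})
            raise AlphabetError(f"duplicate taxon labels: {dupes}")
        self.taxa = list(taxa)
        self.codes = codes
        self.alphabet = alphabet

    @classmethod
    def from_sequences(cls, seqs: Sequence[Rotasequence]) -> "RotasequenceAlignment":
        if not seqs:
            raise AlphabetError("empty alignment")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise AlphabetError(f"ragged alignment: lengths {sorted(lengths)}")
        return cls([s.label for s in seqs], np.vstack([s.codes for s in seqs]),
                   seqs[0].alphabet)

    @property
    def n_taxa(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.codes[self.taxa.index(taxon)]

    def sequence(self, taxon: str) -> Rotasequence:
        return Rotasequence(taxon, self.row(taxon), self.alphabet)

    def mask(self) -> "RotasequenceAlignment":
        return RotasequenceAlignment(self.taxa,
                                     self.alphabet.mask_codes(self.codes),
                                     self.alphabet.masked())

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, RotasequenceAlignment)
                and self.taxa == other.taxa
                and self.alphabet == other.alphabet
                and np.array_equal(self.codes, other.codes))


# ---------------------------------------------------------------------------
# rotasequence FASTA (single-character and two-token dialects)
# ---------------------------------------------------------------------------

class ParseError(ValueError):
    """File does not follow the expected dialect; message carries a line number."""


def _parse_fasta_blocks(lines: Iterable[str]):
    """Yield (label, header_lineno, [(lineno, line), ...]) per FASTA record."""
    label, lineno0, body = None, 0, []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if line.startswith(">"):
            if label is not None:
                yield label, lineno0, body
            label, lineno0, body = line[1:].strip(), lineno, []
            if not label:
                raise ParseError(f"line {lineno}: empty sequence label")
        elif line.strip():
            if label is None:
                raise ParseError(f"line {lineno}: sequence data before header")
            body.append((lineno, line.strip()))
    if label is not None:
        yield label, lineno0, body


def read_rotasequence_fasta(path, alphabet: Alphabet,
                            dialect: str = "single") -> RotasequenceAlignment:
    """Read a rotasequence alignment in the ``single`` or ``two-token`` dialect."""
    if dialect not in ("single", "two-token"):
        raise ValueError(f"unknown dialect {dialect!r}")
    seqs: list[Rotasequence] = []
    labels: set[str] = set()
    with open(path) as fh:
        for label, hline, body in _parse_fasta_blocks(fh):
            if label in labels:
                raise ParseError(f"line {hline}: duplicate taxon label {label!r}")
            labels.add(label)
            codes: list[int] = []
            for lineno, line in body:
                symbols = line.replace(" ", "").replace("\t", "") \
                    if dialect == "single" else line.split()
                for sym in symbols:
                    try:
                        codes.append(alphabet.encode_char(sym)
                                     if dialect == "single"
                                     else alphabet.encode_token(sym))
                    except AlphabetError as exc:
                        raise ParseError(f"line {lineno}: {exc}") from None
            seqs.append(Rotasequence(label, np.array(codes, dtype=np.int16),
                                     alphabet))
    if not seqs:
        raise ParseError("no sequences found")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ParseError(f"ragged alignment: row lengths {sorted(lengths)}")
    return RotasequenceAlignment.from_sequences(seqs)


def write_rotasequence_fasta(path, alignment: RotasequenceAlignment,
                             dialect: str = "single", width: int = 60) -> None:
    with open(path, "w") as fh:
        for taxon, row in zip(alignment.taxa, alignment.codes):
            fh.write(f">{taxon}\n")
            if dialect == "single":
                text = alignment.alphabet.decode(row)
                for i in range(0, len(text), width):
                    fh.write(text[i:i + width] + "\n")
            elif dialect == "two-token":
                toks = [alignment.alphabet.decode_token(int(c)) for c in row]
                for i in range(0, len(toks), 20):
                    fh.write(" ".join(toks[i:i + 20]) + "\n")
            else:
                raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# PAML-dat-like model files (lower-triangle exchangeabilities + frequencies)
# ---------------------------------------------------------------------------

FREQ_SUM_TOLERANCE = 1e-3


def read_model_file(path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read (S, pi, header) from a PAML-dat-like file of any state count.

    The file holds the strict lower triangle of the symmetric exchangeability
    matrix (row 2 has 1 entry ... row n has n-1 entries) followed by the n
    equilibrium frequencies. ``#``-prefixed header lines are collected into a
    metadata dict (``key=value`` pairs, e.g. the scaling convention).
    """
    header: dict = {}
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                for part in line[1:].replace(";", " ").split():
                    if "=" in part:
                        k, v = part.split("=", 1)
                        header[k.strip()] = v.strip()
                continue
            for tok in line.split():
                try:
                    values.append(float(tok))
                except ValueError:
                    raise ParseError(f"line {lineno}: not a number: {tok!r}") \
                        from None
    # total tokens = n(n-1)/2 + n = n(n+1)/2
    total = len(values)
    n = int(round((np.sqrt(8 * total + 1) - 1) / 2))
    if n * (n - 1) // 2 + n != total:
        raise ParseError(
            f"{total} numbers do not form a lower triangle plus frequencies "
            f"for any state count")
    tri = values[: n * (n - 1) // 2]
    freqs = np.array(values[n * (n - 1) // 2:])
    S = np.zeros((n, n))
    k = 0
    for i in range(1, n):
        for j in range(i):
            S[i, j] = S[j, i] = tri[k]
            k += 1
    if (S < 0).any():
        raise ParseError("negative exchangeability entries")
    if (freqs < 0).any():
        raise ParseError("negative frequencies")
    if abs(freqs.sum() - 1.0) > FREQ_SUM_TOLERANCE + 1e-12:
        raise ParseError(
            f"frequencies sum to {freqs.sum():.6f}, outside tolerance "
            f"{FREQ_SUM_TOLERANCE} of 1")
    freqs = freqs / freqs.sum()
    return S, freqs, header


def write_model_file(path, S: np.ndarray, freqs: np.ndarray,
                     name: str = "", scaling: str = "superscaled",
                     alphabet: Alphabet | None = None,
                     precision: int = 10) -> None:
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if S.shape != (n, n) or len(freqs) != n:
        raise ValueError("S must be square and match the frequency vector")
    if not np.allclose(S, S.T):
        raise ValueError("exchangeabilities must be symmetric")
    with open(path, "w") as fh:
        fh.write(f"# rotasub model; states={n}; scaling={scaling}")
        if name:
            fh.write(f"; name={name}")
        fh.write("\n")
        if alphabet is not None and alphabet.n_states == n:
            fh.write("# order: " + " ".join(s.two_token for s in alphabet.states)
                     + "\n")
        fmt = f"%.{precision}g"
        for i in range(1, n):
            fh.write(" ".join(fmt % S[i, j] for j in range(i)) + "\n")
        fh.write("\n" + " ".join(fmt % f for f in freqs) + "\n")


# ---------------------------------------------------------------------------
# labelled TSV matrices (counts etc.) and the alphabet map
# ---------------------------------------------------------------------------

def write_matrix_tsv(path, matrix: np.ndarray, alphabet: Alphabet) -> None:
    import pandas as pd

    labels = [s.two_token for s in alphabet.states]
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(path, sep="\t")


def read_matrix_tsv(path, alphabet: Alphabet) -> np.ndarray:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = [s.two_token for s in alphabet.states]
    if list(df.index) != labels or list(df.columns) != labels:
        raise ParseError("matrix labels do not match the alphabet ordering")
    return df.to_numpy(dtype=float)


def write_alphabet_map(path, alphabet: Alphabet) -> None:
    """TSV mapping state <-> single char <-> two-token."""
    with open(path, "w") as fh:
        fh.write("index\tstate\tsingle\ttwo_token\n")
        for i, s in enumerate(alphabet.states):
            fh.write(f"{i}\t{s}\t{alphabet.single_chars[i]}\t{s.two_token}\n")
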