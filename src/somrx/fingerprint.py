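"""Layered topological atom-environment count fingerprints.

Every heavy atom of a molecule is described by a small count matrix: one row
per topological layer (bond-graph shortest-path distance from the root atom,
six layers by default) and one column per atom type.  Atom types follow the
SYBYL/Tripos mol2 vocabulary (C.3, C.ar, N.am, O.co2, ...), extended with a
handful of elements that occur in metabolic reaction corpora, plus one
reserved padding pseudo-type used to mark layers that lie beyond the
molecule's radius.  Hydrogens are implicit and never counted.

The matrices are the common currency of the whole package: they key the
substrate and reaction-center databases, and the similarity model compares
them row by row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

N_LAYERS = 6  # λ_total: layers 0..5, root atom is layer 0

#: The 33 base Tripos/SYBYL mol2 atom types, in fixed column order.
BASE_TYPES: tuple[str, ...] = (
    "C.3", "C.2", "C.1", "C.ar", "C.cat",
    "N.3", "N.2", "N.1", "N.ar", "N.am", "N.pl3", "N.4",
    "O.3", "O.2", "O.co2",
    "S.3", "S.2", "S.O", "S.O2",
    "P.3",
    "F", "Cl", "Br", "I",
    "Li", "Na", "Mg", "Al", "Si", "K", "Ca", "Fe", "Cu",
)

#: Extra elements seen in metabolic reaction data, typed by bare element name.
EXTRA_TYPES: tuple[str, ...] = ("As", "Pt", "Co", "Mn", "Zn", "Se", "Ge", "Sn", "Gd", "B")

#: Reserved pseudo-type marking layers beyond the molecule's radius.
PAD_TYPE = "A"


class UnknownAtomTypeError(ValueError):
    """Raised when an element falls outside the fingerprint alphabet."""


@dataclass(frozen=True)
class AtomTypeAlphabet:
    """Fixed, versioned column order of the fingerprint count matrices."""

    base_types: tuple[str, ...] = BASE_TYPES
    extra_types: tuple[str, ...] = EXTRA_TYPES
    pad_type: str = PAD_TYPE
    version: str = "sybyl33+10+pad/1"

    def __post_init__(self) -> None:
        names = self.columns
        if len(set(names)) != len(names):
            raise ValueError("alphabet column names must be unique")

    @property
    def columns(self) -> tuple[str, ...]:
        return self.base_types + self.extra_types + (self.pad_type,)

    @property
    def width(self) -> int:
        return len(self.columns)

    @property
    def pad_index(self) -> int:
        return self.width - 1

    def index(self, name: str) -> int:
        try:
            return self.columns.index(name)
        except ValueError:
            raise UnknownAtomTypeError(f"atom type {name!r} not in alphabet") from None


DEFAULT_ALPHABET = AtomTypeAlphabet()

# elements typed purely by element symbol
_ELEMENT_TYPES = frozenset(
    ("F", "Cl", "Br", "I", "Li", "Na", "Mg", "Al", "Si", "K", "Ca", "Fe", "Cu")
    + EXTRA_TYPES
)


def assign_atom_type(mol: Chem.Mol, atom_index: int) -> str:
    """SYBYL/Tripos mol2 atom type of one heavy atom.

    Follows the conventions mol2 writers use: aromatic ring atoms get the
    aromatic types, carboxylic-acid/carboxylate and terminal phosphate
    oxygens are O.co2, amide nitrogens N.am, sulfoxide/sulfone sulfurs
    S.O/S.O2.  Raises :class:`UnknownAtomTypeError` for elements outside
    the alphabet.
    """
    atom = mol.GetAtomWithIdx(atom_index)
    sym = atom.GetSymbol()
    if sym == "H":
        raise UnknownAtomTypeError("hydrogens are implicit and never typed")
    if sym in _ELEMENT_TYPES:
        return sym

    if sym == "C":
        if atom.GetIsAromatic():
            return "C.ar"
        n_nbrs = _n_neighbors_of(atom, "N")
        charged = atom.GetFormalCharge() == 1 or any(
            nb.GetSymbol() == "N" and nb.GetFormalCharge() == 1
            for nb in atom.GetNeighbors())
        if charged and n_nbrs >= 2 and _has_multiple_bond(atom):
            return "C.cat"  # guanidinium-type carbon
        return {
            Chem.HybridizationType.SP: "C.1",
            Chem.HybridizationType.SP2: "C.2",
        }.get(atom.GetHybridization(), "C.3")

    if sym == "N":
        if atom.GetIsAromatic():
            return "N.ar"
        if _is_amide_nitrogen(atom):
            return "N.am"
        if atom.GetTotalDegree() == 4:
            return "N.4"
        hyb = atom.GetHybridization()
        if hyb == Chem.HybridizationType.SP:
            return "N.1"
        if _has_multiple_bond(atom):
            return "N.2"
        if any(nb.GetIsAromatic() or nb.GetHybridization() == Chem.HybridizationType.SP2
               for nb in atom.GetNeighbors()):
            return "N.pl3"  # trigonal-planar amine (anilines, enamines)
        return "N.3"

    if sym == "O":
        if _is_carboxylate_like_oxygen(atom):
            return "O.co2"
        if _has_multiple_bond(atom):
            return "O.2"
        return "O.3"

    if sym == "S":
        terminal_o = sum(
            1 for nb in atom.GetNeighbors()
            if nb.GetSymbol() == "O" and nb.GetDegree() == 1
        )
        if terminal_o >= 2:
            return "S.O2"
        if terminal_o == 1 and atom.GetTotalDegree() >= 3:
            return "S.O"
        if _has_multiple_bond(atom) and not atom.GetIsAromatic():
            return "S.2"
        return "S.3"

    if sym == "P":
        return "P.3"

    raise UnknownAtomTypeError(f"element {sym!r} is outside the fingerprint alphabet")


def _n_neighbors_of(atom: Chem.Atom, symbol: str) -> int:
    return sum(1 for nb in atom.GetNeighbors() if nb.GetSymbol() == symbol)


def _has_multiple_bond(atom: Chem.Atom) -> bool:
    return any(b.GetBondType() in (Chem.BondType.DOUBLE, Chem.BondType.TRIPLE)
               for b in atom.GetBonds())


def _is_amide_nitrogen(atom: Chem.Atom) -> bool:
    for nb in atom.GetNeighbors():
        if nb.GetSymbol() != "C":
            continue
        bond = atom.GetOwningMol().GetBondBetweenAtoms(atom.GetIdx(), nb.GetIdx())
        if bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        for b in nb.GetBonds():
            if b.GetBondType() == Chem.BondType.DOUBLE and \
                    b.GetOtherAtom(nb).GetSymbol() in ("O", "S"):
                return True
    return False


def _is_carboxylate_like_oxygen(atom: Chem.Atom) -> bool:
    # terminal O on a carboxyl(ate) carbon or on phosphorus
    if atom.GetDegree() != 1:
        return False
    nb = atom.GetNeighbors()[0]
    if nb.GetSymbol() == "P":
        return True
    if nb.GetSymbol() == "C":
        terminal_o = sum(
            1 for o in nb.GetNeighbors()
            if o.GetSymbol() == "O" and o.GetDegree() == 1
        )
        return terminal_o >= 2
    return False


@dataclass
class FingerprintMatrix:
    """Per-atom layered count matrix (``n_layers`` x alphabet width).

    Row ``j`` counts, per atom type, the heavy atoms at shortest-path
    distance exactly ``j`` from the root.  Rows beyond the molecule's
    radius hold a single count of 1 in the padding column, so no row is
    ever all-zero.
    """

    counts: np.ndarray
    root_atom: int
    molecule_id: str = ""
    alphabet: AtomTypeAlphabet = field(default=DEFAULT_ALPHABET, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != self.alphabet.width:
            raise ValueError(
                f"count matrix must be (layers, {self.alphabet.width}), "
                f"got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValueError("fingerprint counts must be non-negative")

    @property
    def n_layers(self) -> int:
        return self.counts.shape[0]

    def key(self) -> str:
        """Serialize to the canonical sparse text key (bit-exact)."""
        return serialize_counts(self.counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FingerprintMatrix):
            return NotImplemented
        return np.array_equal(self.counts, other.counts)


def serialize_counts(counts: np.ndarray) -> str:
    """``layer:col=count;...`` per layer, layers joined with ``|``."""
    layers = []
    for j, row in enumerate(counts):
        nz = ";".join(f"{n}={int(c)}" for n, c in enumerate(row) if c)
        layers.append(f"{j}:{nz}")
    return "|".join(layers)


def deserialize_counts(key: str, n_layers: int = N_LAYERS,
                       width: int = DEFAULT_ALPHABET.width) -> np.ndarray:
    """Inverse of :func:`serialize_counts`."""
    counts = np.zeros((n_layers, width), dtype=np.int64)
    for part in key.split("|"):
        head, _, body = part.partition(":")
        j = int(head)
        if body:
            for item in body.split(";"):
                n, _, c = item.partition("=")
                counts[j, int(n)] = int(c)
    return counts


def atom_fingerprint(mol: Chem.Mol, atom_index: int, n_layers: int = N_LAYERS,
                     alphabet: AtomTypeAlphabet = DEFAULT_ALPHABET,
                     molecule_id: str = "",
                     _dist: np.ndarray | None = None,
                     _types: list[str] | None = None) -> FingerprintMatrix:
    """Layered count fingerprint rooted at one heavy atom."""
    if not 0 <= atom_index < mol.GetNumAtoms():
        raise IndexError(f"atom index {atom_index} out of range")
    dist = Chem.GetDistanceMatrix(mol) if _dist is None else _dist
    types = (_types if _types is not None
             else [assign_atom_type(mol, i) for i in range(mol.GetNumAtoms())])
    counts = np.zeros((n_layers, alphabet.width), dtype=np.int64)
    for i in range(mol.GetNumAtoms()):
        d = dist[atom_index, i]
        if d < n_layers:  # disconnected fragments are at "infinite" distance
            counts[int(d), alphabet.index(types[i])] += 1
    for j in range(n_layers):  # pad layers beyond the radius
        if not counts[j].any():
            counts[j, alphabet.pad_index] = 1
    return FingerprintMatrix(counts, root_atom=atom_index,
                             molecule_id=molecule_id, alphabet=alphabet)


def molecule_fingerprints(mol: Chem.Mol, n_layers: int = N_LAYERS,
                          alphabet: AtomTypeAlphabet = DEFAULT_ALPHABET,
                          molecule_id: str = "") -> list[FingerprintMatrix]:
    """One fingerprint per heavy atom, in atom-index order."""
    if mol.GetNumAtoms() == 0:
        return []
    dist = Chem.GetDistanceMatrix(mol)
    types = [assign_atom_type(mol, i) for i in range(mol.GetNumAtoms())]
    return [
        atom_fingerprint(mol, i, n_layers, alphabet, molecule_id,
                         _dist=dist, _types=types)
        for i in range(mol.GetNumAtoms())
    ]
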