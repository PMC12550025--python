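"""Atom/bond vocabularies for the one-hot catalyst matrix representation.

The matrix codec needs a fixed, ordered alphabet of atom types (index 0
reserved for "no atom") and bond types (index 0 reserved for "no bond").
Defaults follow the representation's standard sizing: up to 100 nodes,
68 atom channels and 6 bond channels, i.e. a flattened dimensionality of
S + S*At + S*S*Bt = 66 900.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

from rdkit import Chem

NO_ATOM = "*"
NO_BOND = "none"

#: bond categories: "other" absorbs dative/unspecified bonds so that
#: organometallic inputs encode without growing the channel count.
DEFAULT_BOND_TYPES = (NO_BOND, "single", "double", "triple", "aromatic", "other")

_BOND_TO_NAME = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}

_NAME_TO_BOND = {
    "single": Chem.BondType.SINGLE,
    "double": Chem.BondType.DOUBLE,
    "triple": Chem.BondType.TRIPLE,
    "aromatic": Chem.BondType.AROMATIC,
    "other": Chem.BondType.SINGLE,
}

# 67 elements + the no-atom slot = 68 channels: the organic subset first,
# then metals and metalloids common in homogeneous catalysis.
DEFAULT_ELEMENTS = (
    "C", "N", "O", "P", "S", "F", "Cl", "Br", "I", "B", "Si", "H",
    "Pd", "Pt", "Ni", "Cu", "Fe", "Ru", "Rh", "Ir", "Co", "Mn", "Zn",
    "Ag", "Au", "Li", "Na", "K", "Mg", "Ca", "Al", "Sn", "Ti", "Zr",
    "W", "Mo", "Cr", "V", "Sc", "Y", "La", "Ce", "Os", "Re", "Ta",
    "Nb", "Hf", "Cd", "Hg", "Pb", "Bi", "Sb", "As", "Se", "Te", "Ge",
    "Ga", "In", "Tl", "Ba", "Sr", "Cs", "Rb", "Be", "Sm", "Eu", "Yb",
)


class VocabularyError(ValueError):
    """An element or bond category is not representable in the vocabulary."""


class CapacityError(ValueError):
    """More distinct element types than the vocabulary can hold."""


@dataclass(frozen=True)
class AtomBondVocabulary:
    """Ordered atom and bond alphabets plus the node budget S.

    ``atom_types[0]`` is the reserved no-atom entry and ``bond_types[0]``
    the reserved no-bond entry. Unused trailing atom slots are padding
    (named ``<unusedK>``) so the channel count stays fixed.
    """

    atom_types: tuple = field(default=None)
    bond_types: tuple = DEFAULT_BOND_TYPES
    max_nodes: int = 100

    def __post_init__(self):
        if self.atom_types is None:
            object.__setattr__(self, "atom_types", (NO_ATOM,) + DEFAULT_ELEMENTS)
        object.__setattr__(self, "atom_types", tuple(self.atom_types))
        object.__setattr__(self, "bond_types", tuple(self.bond_types))
        if self.atom_types[0] != NO_ATOM:
            raise ValueError("atom_types[0] must be the reserved no-atom entry")
        if self.bond_types[0] != NO_BOND:
            raise ValueError("bond_types[0] must be the reserved no-bond entry")

    @property
    def n_atom_types(self) -> int:
        return len(self.atom_types)

    @property
    def n_bond_types(self) -> int:
        return len(self.bond_types)

    @property
    def flat_dim(self) -> int:
        """S + S*At + S*S*Bt: length of the flattened (T, A, B) triple."""
        s, at, bt = self.max_nodes, self.n_atom_types, self.n_bond_types
        return s + s * at + s * s * bt

    def atom_index(self, symbol: str) -> int:
        try:
            return self.atom_types.index(symbol)
        except ValueError:
            raise VocabularyError(f"element {symbol!r} not in vocabulary") from None

    def bond_index(self, bond: Chem.Bond) -> int:
        name = _BOND_TO_NAME.get(bond.GetBondType(), "other")
        return self.bond_types.index(name)

    def bond_from_index(self, idx: int) -> Chem.BondType:
        return _NAME_TO_BOND[self.bond_types[idx]]

    def covers(self, mol: Chem.Mol) -> bool:
        return all(a.GetSymbol() in self.atom_types for a in mol.GetAtoms())

    # -- persistence ----------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "atom_types": list(self.atom_types),
            "bond_types": list(self.bond_types),
            "max_nodes": self.max_nodes,
        })

    @classmethod
    def from_json(cls, text: str) -> "AtomBondVocabulary":
        d = json.loads(text)
        return cls(tuple(d["atom_types"]), tuple(d["bond_types"]), d["max_nodes"])


def default_vocabulary() -> AtomBondVocabulary:
    """The full-size default: S=100, 68 atom channels, 6 bond channels."""
    return AtomBondVocabulary()


def build_vocabulary(molecules, max_atom_types: int = 68,
                     bond_type_policy: str = "default",
                     max_nodes: int = 100) -> AtomBondVocabulary:
    """Derive an atom vocabulary from observed molecules.

    Elements are ordered by frequency (descending), ties alphabetical, and
    the list is padded to ``max_atom_types`` with unused slots so the channel
    count is stable across datasets.
    """
    if bond_type_policy != "default":
        raise ValueError(f"unknown bond_type_policy {bond_type_policy!r}")
    counts = Counter()
    for mol in molecules:
        mol = as_mol(mol)
        for atom in mol.GetAtoms():
            counts[atom.GetSymbol()] += 1
    if len(counts) > max_atom_types - 1:
        raise CapacityError(
            f"{len(counts)} distinct elements exceed capacity {max_atom_types - 1}")
    ordered = sorted(counts, key=lambda s: (-counts[s], s))
    padding = [f"<unused{i}>" for i in range(max_atom_types - 1 - len(ordered))]
    return AtomBondVocabulary(
        atom_types=(NO_ATOM,) + tuple(ordered) + tuple(padding),
        bond_types=DEFAULT_BOND_TYPES,
        max_nodes=max_nodes,
    )


def as_mol(molecule) -> Chem.Mol:
    """Accept an RDKit Mol or a SMILES string; raise on parse failure."""
    if isinstance(molecule, Chem.Mol):
        return molecule
    mol = Chem.MolFromSmiles(molecule)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {molecule!r}")
    return mol
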