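"""Catalyst matrix codec and molecular graph featurization.

A catalyst is encoded as the one-hot triple M = (T, A, B): T marks the
number of occupied nodes, A the atom type at each node and B the bond type
for every node pair. Node order is the toolkit's canonical order, with
disconnected fragments occupying consecutive index blocks; node-order
shuffling provides training-time augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .vocab import NO_ATOM, AtomBondVocabulary, VocabularyError, as_mol

__all__ = [
    "CatalystMatrix", "MatrixLogits", "MoleculeGraph", "FeatureScheme",
    "encode_catalyst", "shuffle_augment", "featurize_molecule_graph",
    "mw_cluster_onehot", "SizeError",
]


class SizeError(ValueError):
    """Molecule exceeds the node budget of the vocabulary."""


@dataclass
class CatalystMatrix:
    """One-hot (T, A, B) triple. T[k] = 1 means k occupied nodes."""

    T: np.ndarray  # (S,)
    A: np.ndarray  # (S, At)
    B: np.ndarray  # (S, S, Bt)

    @property
    def n_atoms(self) -> int:
        return int(np.argmax(self.T))

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.T.ravel(), self.A.ravel(), self.B.ravel()])

    def validate(self) -> None:
        """Assert the one-hot invariants; raises AssertionError on violation."""
        assert self.T.sum() == 1
        assert np.all(self.A.sum(axis=-1) == 1)
        assert np.all(self.B.sum(axis=-1) == 1)
        assert np.array_equal(self.B, self.B.transpose(1, 0, 2)), "B not symmetric"
        assert np.all(self.B[np.arange(len(self.T)), np.arange(len(self.T)), 0] == 1)
        n = self.n_atoms
        assert np.all(self.A[n:, 0] == 1), "padding nodes must be no-atom"
        assert np.all(self.B[n:, :, 0] == 1) and np.all(self.B[:, n:, 0] == 1)

    def permuted(self, perm: np.ndarray) -> "CatalystMatrix":
        """Apply a permutation of the occupied nodes to A and B (T fixed)."""
        n = self.n_atoms
        full = np.concatenate([perm, np.arange(n, len(self.T))])
        return CatalystMatrix(
            T=self.T.copy(),
            A=self.A[full],
            B=self.B[np.ix_(full, full)],
        )


@dataclass
class MatrixLogits:
    """Real-valued scores with the same shapes as a CatalystMatrix."""

    T: np.ndarray
    A: np.ndarray
    B: np.ndarray

    @classmethod
    def from_matrix(cls, m: CatalystMatrix) -> "MatrixLogits":
        return cls(m.T.astype(float), m.A.astype(float), m.B.astype(float))

    def probabilities(self) -> "MatrixLogits":
        """Softmax-normalize each categorical fiber."""
        def soft(x):
            e = np.exp(x - x.max(axis=-1, keepdims=True))
            return e / e.sum(axis=-1, keepdims=True)
        return MatrixLogits(soft(self.T), soft(self.A), soft(self.B))


def _canonical_mol(molecule) -> Chem.Mol:
    """Re-parse the canonical SMILES so atom order is the canonical order
    and fragments occupy consecutive blocks."""
    mol = as_mol(molecule)
    return Chem.MolFromSmiles(Chem.MolToSmiles(mol))


def encode_catalyst(molecule, vocab: AtomBondVocabulary) -> CatalystMatrix:
    """Encode a molecule (SMILES or Mol, possibly multi-fragment) as (T, A, B).

    Raises SizeError when the atom count exceeds S-1 (index 0 of T is the
    reserved empty state) and VocabularyError on unknown elements.
    """
    mol = _canonical_mol(molecule)
    s = vocab.max_nodes
    n = mol.GetNumAtoms()
    if n > s - 1:
        raise SizeError(f"molecule has {n} atoms; budget is {s - 1}")
    T = np.zeros(s)
    T[n] = 1.0
    A = np.zeros((s, vocab.n_atom_types))
    A[:, 0] = 1.0
    B = np.zeros((s, s, vocab.n_bond_types))
    B[:, :, 0] = 1.0
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        A[i, 0] = 0.0
        A[i, vocab.atom_index(atom.GetSymbol())] = 1.0
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        k = vocab.bond_index(bond)
        for a, b in ((i, j), (j, i)):
            B[a, b, 0] = 0.0
            B[a, b, k] = 1.0
    return CatalystMatrix(T, A, B)


def shuffle_augment(matrix: CatalystMatrix, n_orders: int, seed: int):
    """Return ``n_orders`` node-order-shuffled copies of a catalyst matrix.

    Only the occupied nodes are permuted (rows of A, rows/columns of B);
    T is unchanged, so every copy decodes to the same canonical structure.
    """
    if n_orders < 1:
        raise ValueError("n_orders must be >= 1")
    rng = np.random.default_rng(seed)
    n = matrix.n_atoms
    out = []
    for _ in range(n_orders):
        perm = rng.permutation(n) if n > 1 else np.arange(n)
        out.append(matrix.permuted(perm))
    return out


# ---------------------------------------------------------------------------
# graph featurization for the condition encoder
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureScheme:
    name: str
    node_width: int
    edge_width: int


#: node features: Z/100, degree/6, formal charge, aromatic flag, in-ring
#: flag, total H count / 4. Edge features: bond-order one-hot
#: (single/double/triple/aromatic), conjugated flag, in-ring flag.
DEFAULT_SCHEME = FeatureScheme("default", node_width=6, edge_width=6)

_SCHEMES = {"default": DEFAULT_SCHEME}


@dataclass
class MoleculeGraph:
    node_features: np.ndarray          # (N, node_width)
    edges: list                        # [(i, j, feature_vector)], each bond once
    scheme: FeatureScheme

    @property
    def n_nodes(self) -> int:
        return len(self.node_features)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self, self_loops: bool = True) -> np.ndarray:
        adj = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for i, j, _ in self.edges:
            adj[i, j] = adj[j, i] = True
        if self_loops:
            np.fill_diagonal(adj, True)
        return adj


_EDGE_ORDER = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}


def featurize_molecule_graph(molecule, feature_scheme="default") -> MoleculeGraph:
    """Attributed graph of a molecule under a named feature scheme."""
    scheme = _SCHEMES[feature_scheme] if isinstance(feature_scheme, str) else feature_scheme
    mol = _canonical_mol(molecule)
    nodes = np.zeros((mol.GetNumAtoms(), scheme.node_width))
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        nodes[i] = [
            atom.GetAtomicNum() / 100.0,
            atom.GetDegree() / 6.0,
            float(atom.GetFormalCharge()),
            float(atom.GetIsAromatic()),
            float(atom.IsInRing()),
            atom.GetTotalNumHs() / 4.0,
        ]
    edges = []
    for bond in mol.GetBonds():
        feat = np.zeros(scheme.edge_width)
        idx = _EDGE_ORDER.get(bond.GetBondType())
        if idx is not None:
            feat[idx] = 1.0
        feat[4] = float(bond.GetIsConjugated())
        feat[5] = float(bond.IsInRing())
        edges.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), feat))
    return MoleculeGraph(nodes, edges, scheme)


def mw_cluster_onehot(molecular_weight: float, bin_edges) -> np.ndarray:
    """One-hot over len(bin_edges)+1 half-open, left-closed weight bins."""
    if molecular_weight < 0:
        raise ValueError("molecular weight must be non-negative")
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size == 0 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be non-empty and strictly ascending")
    out = np.zeros(edges.size + 1)
    out[int(np.searchsorted(edges, molecular_weight, side="right"))] = 1.0
    return out
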