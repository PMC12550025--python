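"""Rule-based reconstruction of molecules from decoded matrix logits.

The decoder emits real-valued scores for (T, A, B). Reconstruction reads
the molecule size from T, atom types from A, then assigns bonds in
descending order of probability, checking valence after each addition:
a bond that would violate the valence rules is rejected, except where a
formal charge renders the local valence legal (quaternary nitrogen and
the usual +/-1 adjustments on O/N/P/B; carbon is never charged). A final
pass runs aromatic clearance, sanitization and removal of unconnected
carbon atoms. With correction switched off the raw argmax structure is
returned, possibly invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger

from .representation import MatrixLogits
from .vocab import NO_ATOM, AtomBondVocabulary

RDLogger.DisableLog("rdApp.*")

__all__ = ["ReconstructionReport", "reconstruct", "strip_isolated_carbons",
           "to_smiles", "MAX_NEUTRAL_VALENCE", "CHARGED_VALENCE"]

#: maximum explicit valence of a neutral atom (highest common valence state).
MAX_NEUTRAL_VALENCE = {
    "C": 4, "N": 3, "O": 2, "F": 1, "Cl": 1, "Br": 1, "I": 1,
    "P": 5, "S": 6, "B": 3, "Si": 4, "H": 1, "As": 5, "Se": 6, "Te": 6,
    "Ge": 4, "Sn": 4, "Pb": 4,
}
#: valence reachable by adding one formal charge; carbon deliberately absent.
CHARGED_VALENCE = {"N": 4, "O": 3, "P": 4, "B": 4}

_METAL_VALENCE_CAP = 6  # permissive cap for metals / unlisted elements

_BOND_ORDER = {"single": 1.0, "double": 2.0, "triple": 3.0,
               "aromatic": 1.5, "other": 1.0}


@dataclass
class ReconstructionReport:
    proposed_bonds: int = 0
    rejected_bonds: int = 0
    charged_atoms_added: int = 0
    atoms_removed: int = 0
    sanitization_passed: bool = False
    empty_output: bool = False

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def max_valence(symbol: str, allow_charge: bool) -> float:
    base = MAX_NEUTRAL_VALENCE.get(symbol)
    if base is None:
        return _METAL_VALENCE_CAP
    if allow_charge and symbol in CHARGED_VALENCE:
        return max(base, CHARGED_VALENCE[symbol])
    return base


def _candidate_bonds(probs: MatrixLogits, present: list, vocab: AtomBondVocabulary):
    """All non-no-bond argmax pairs (i<j), sorted by probability descending,
    ties broken lexicographically on (i, j, channel)."""
    cands = []
    for a in range(len(present)):
        for b in range(a + 1, len(present)):
            i, j = present[a], present[b]
            fiber = 0.5 * (probs.B[i, j] + probs.B[j, i])
            ch = int(np.argmax(fiber))
            if ch == 0:
                continue
            cands.append((float(fiber[ch]), a, b, ch))
    cands.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
    return cands


def reconstruct(logits: MatrixLogits, vocab: AtomBondVocabulary,
                correction: bool = True):
    """Convert matrix logits to a molecule; returns (mol_or_None, report)."""
    report = ReconstructionReport()
    probs = logits.probabilities()
    size = int(np.argmax(probs.T))
    if size == 0:
        report.empty_output = True
        return None, report

    symbols, present = [], []
    for i in range(size):
        ch = int(np.argmax(probs.A[i]))
        sym = vocab.atom_types[ch]
        if ch == 0 or sym == NO_ATOM or sym.startswith("<unused"):
            continue  # untypable node: treated as absent
        present.append(i)
        symbols.append(sym)
    if not present:
        report.empty_output = True
        return None, report

    cands = _candidate_bonds(probs, present, vocab)
    report.proposed_bonds = len(cands)

    order_sum = np.zeros(len(present))
    accepted = []
    for prob, a, b, ch in cands:
        order = _BOND_ORDER[vocab.bond_types[ch]]
        if correction:
            ok = all(
                order_sum[x] + order <= max_valence(symbols[x], allow_charge=True)
                for x in (a, b)
            )
            if not ok:
                report.rejected_bonds += 1
                continue
        order_sum[a] += order
        order_sum[b] += order
        accepted.append((a, b, ch))

    mol = _assemble(symbols, accepted, order_sum, vocab, report,
                    assign_charges=correction)
    if not correction:
        return _finalize_raw(mol, report)
    return _finalize_corrected(mol, report)


def _assemble(symbols, accepted, order_sum, vocab, report, assign_charges):
    rw = Chem.RWMol()
    for k, sym in enumerate(symbols):
        atom = Chem.Atom(sym)
        if assign_charges and order_sum[k] > max_valence(sym, allow_charge=False):
            # charge renders the local valence legal (e.g. quaternary N)
            atom.SetFormalCharge(-1 if sym == "B" else 1)
            report.charged_atoms_added += 1
        rw.AddAtom(atom)
    aromatic_bonds = []
    for a, b, ch in accepted:
        bt = vocab.bond_from_index(ch)
        rw.AddBond(a, b, bt)
        if bt == Chem.BondType.AROMATIC:
            aromatic_bonds.append((a, b))
            rw.GetAtomWithIdx(a).SetIsAromatic(True)
            rw.GetAtomWithIdx(b).SetIsAromatic(True)
    return rw.GetMol()


def _try_sanitize(mol):
    m = Chem.Mol(mol)
    try:
        Chem.SanitizeMol(m)
        return m
    except Exception:
        return None


def _clear_aromatic(mol):
    rw = Chem.RWMol(mol)
    for bond in rw.GetBonds():
        if bond.GetBondType() == Chem.BondType.AROMATIC:
            bond.SetBondType(Chem.BondType.SINGLE)
    for atom in rw.GetAtoms():
        atom.SetIsAromatic(False)
    return rw.GetMol()


def _finalize_raw(mol, report):
    clean = _try_sanitize(mol)
    if clean is not None:
        report.sanitization_passed = True
        return clean, report
    report.sanitization_passed = False
    return mol, report


def _finalize_corrected(mol, report):
    # aromatic clearance: kekulize if possible, else fall back to single bonds
    clean = _try_sanitize(mol)
    if clean is None:
        clean = _try_sanitize(_clear_aromatic(mol))
    if clean is None:
        report.empty_output = True
        return None, report
    clean, removed = _strip_isolated_carbons_impl(clean)
    report.atoms_removed = removed
    if clean.GetNumAtoms() == 0:
        report.empty_output = True
        return None, report
    final = _try_sanitize(clean)
    if final is None:
        report.empty_output = True
        return None, report
    report.sanitization_passed = True
    return final, report


def _strip_isolated_carbons_impl(mol):
    frags = Chem.GetMolFrags(mol, asMols=False)
    drop = set()
    removed = 0
    for frag in frags:
        if len(frag) == 1:
            atom = mol.GetAtomWithIdx(frag[0])
            if atom.GetSymbol() == "C" and atom.GetFormalCharge() == 0:
                drop.add(frag[0])
                removed += 1
    if not drop:
        return mol, 0
    rw = Chem.RWMol(mol)
    for idx in sorted(drop, reverse=True):
        rw.RemoveAtom(idx)
    return rw.GetMol(), removed


def strip_isolated_carbons(molecule):
    """Delete fragments that are exactly one uncharged carbon atom; single
    heteroatoms and metals are retained. Accepts SMILES or Mol."""
    from .vocab import as_mol
    mol, _ = _strip_isolated_carbons_impl(as_mol(molecule))
    return mol


def to_smiles(mol) -> str | None:
    if mol is None or mol.GetNumAtoms() == 0:
        return None
    try:
        return Chem.MolToSmiles(mol)
    except Exception:
        return None
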