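"""Desk-scale synthetic reaction data with known statistical structure.

Molecules are assembled from a fixed library of chemically safe fragments
(alkyl, aryl, amine, phosphine, carbonyl pieces) joined by single bonds,
which guarantees sanitizable structures and yields plausible phosphine
test cases for the ligand filters. The catalytic target is a declared
deterministic function of molecular descriptors plus Gaussian noise:

    y = 100 * sigmoid(w . [MW/100, n_hetero, n_rings, log(t)] + b) + N(0, s)

clipped to [0, 100], with (w, b) drawn from the seed and returned with the
dataset so recovery experiments have a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

from .data import ReactionRecord

RDLogger.DisableLog("rdApp.*")

__all__ = ["FixtureSpec", "FixtureDataset", "make_reaction_dataset",
           "make_planted_duplicates", "random_molecule", "descriptor_vector"]

#: assembly pieces; every fragment sanitizes and has at least one open valence.
FRAGMENTS = (
    "C", "CC", "CCC", "CC(C)C", "CO", "CN", "CCO", "CCN", "C=O", "C#N",
    "CF", "CCl", "CS", "c1ccccc1", "c1ccncc1", "C1CCCCC1", "C1CCNC1",
    "CP(C)C", "P(C)C", "CC(=O)O",
)

METAL_FRAGMENTS = ("[Pd]", "[Ni]", "[Pt]")


@dataclass(frozen=True)
class FixtureSpec:
    n_records: int = 200
    seed: int = 0
    max_atoms: int = 12
    include_metal: bool = True
    multi_fragment_fraction: float = 0.2
    noise_sigma: float = 5.0
    time_range: tuple = (0.25, 48.0)
    target_kind: str = "yield"

    def __post_init__(self):
        if self.max_atoms < 1:
            raise ValueError("max_atoms must be >= 1")
        if self.n_records < 0:
            raise ValueError("n_records must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class FixtureDataset:
    records: list
    weights: np.ndarray   # w of the target function
    bias: float           # b of the target function
    spec: FixtureSpec


def _attachable(mol):
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() >= 1]


def random_molecule(rng: np.random.Generator, max_atoms: int = 12) -> Chem.Mol:
    """Assemble a valid molecule from the fragment library within an atom
    budget; always sanitizes."""
    for _ in range(50):
        base = Chem.MolFromSmiles(FRAGMENTS[rng.integers(len(FRAGMENTS))])
        if base.GetNumAtoms() > max_atoms:
            continue
        mol = base
        while True:
            cand = [f for f in FRAGMENTS
                    if Chem.MolFromSmiles(f).GetNumAtoms()
                    + mol.GetNumAtoms() <= max_atoms]
            if not cand or rng.random() < 0.35:
                break
            frag = Chem.MolFromSmiles(cand[rng.integers(len(cand))])
            combo = Chem.RWMol(Chem.CombineMols(mol, frag))
            left = _attachable(mol)
            right = [i + mol.GetNumAtoms() for i in _attachable(frag)]
            if not left or not right:
                break
            combo.AddBond(int(left[rng.integers(len(left))]),
                          int(right[rng.integers(len(right))]),
                          Chem.BondType.SINGLE)
            trial = combo.GetMol()
            try:
                Chem.SanitizeMol(trial)
            except Exception:
                break
            mol = trial
        if mol.GetNumAtoms() < 2:
            continue  # a lone carbon is not a plausible reagent/catalyst
        try:
            Chem.SanitizeMol(mol)
            return mol
        except Exception:
            continue
    return Chem.MolFromSmiles("CC")


def descriptor_vector(catalyst_smiles: str, reaction_time: float) -> np.ndarray:
    """The declared descriptor basis of the synthetic target function."""
    mol = Chem.MolFromSmiles(catalyst_smiles)
    n_hetero = sum(1 for a in mol.GetAtoms() if a.GetSymbol() not in ("C", "H"))
    n_rings = mol.GetRingInfo().NumRings()
    return np.array([Descriptors.MolWt(mol) / 100.0, float(n_hetero),
                     float(n_rings), np.log(reaction_time)])


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def make_reaction_dataset(spec: FixtureSpec) -> FixtureDataset:
    """Generate a reproducible synthetic reaction dataset."""
    rng = np.random.default_rng(spec.seed)
    # weights scaled so the sigmoid argument spans a few units across the set
    w = rng.normal(0.0, 1.0, size=4) * np.array([0.8, 0.4, 0.6, 0.5])
    b = float(rng.normal(0.0, 0.5))
    records = []
    for _ in range(spec.n_records):
        catalyst = Chem.MolToSmiles(random_molecule(rng, spec.max_atoms))
        if spec.include_metal and rng.random() < spec.multi_fragment_fraction:
            metal = METAL_FRAGMENTS[rng.integers(len(METAL_FRAGMENTS))]
            catalyst = Chem.CanonSmiles(catalyst + "." + metal)
        n_reactants = int(rng.integers(1, 3))
        reactants = tuple(Chem.MolToSmiles(random_molecule(rng, 8))
                          for _ in range(n_reactants))
        product = Chem.MolToSmiles(random_molecule(rng, 8))
        reagents = ((Chem.MolToSmiles(random_molecule(rng, 6)),)
                    if rng.random() < 0.5 else ())
        lo, hi = spec.time_range
        time = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        x = descriptor_vector(catalyst, time)
        y = 100.0 * _sigmoid(float(w @ x) + b)
        if spec.noise_sigma > 0:
            y += float(rng.normal(0.0, spec.noise_sigma))
        y = float(min(max(y, 0.0), 100.0))
        mol = Chem.MolFromSmiles(catalyst)
        records.append(ReactionRecord(
            reactants=reactants, product=product, catalyst=catalyst,
            reagents=reagents, reaction_time=time, target=y,
            target_kind=spec.target_kind,
            catalyst_mw=float(Descriptors.MolWt(mol)),
        ))
    return FixtureDataset(records, w, b, spec)


def make_planted_duplicates(spec: FixtureSpec, k_groups: int = 5,
                            n_outliers: int = 2):
    """Dataset with planted duplicate groups and gross MW outliers, plus a
    manifest describing the expected post-curation content."""
    if k_groups > spec.n_records // 2:
        raise ValueError("k_groups must be <= n_records / 2")
    base = make_reaction_dataset(spec)
    rng = np.random.default_rng(spec.seed + 1)
    records = list(base.records)
    duplicate_keys = []
    dup_targets = {}
    originals = rng.choice(len(records), size=k_groups, replace=False)
    for i in originals:
        orig = records[i]
        shifted = replace(orig, target=float(min(max(
            orig.target + rng.uniform(-20, 20), 0.0), 100.0)))
        records.append(shifted)
        duplicate_keys.append(orig.key())
        dup_targets[orig.key()] = float(np.mean([orig.target, shifted.target]))
    # gross outliers: a catalyst chain far beyond the MW distribution
    outlier = Chem.CanonSmiles("C" * 120)
    outlier_records = []
    for _ in range(n_outliers):
        tmpl = records[rng.integers(len(base.records))]
        out_rec = replace(tmpl, catalyst=outlier,
                          catalyst_mw=float(Descriptors.MolWt(
                              Chem.MolFromSmiles(outlier))))
        records.append(out_rec)
        outlier_records.append(out_rec)
    manifest = {
        "n_input": len(records),
        "duplicate_keys": duplicate_keys,
        "expected_dedup_targets": dup_targets,
        "n_after_dedup": len(base.records) + n_outliers,
        "outlier_catalyst": outlier,
    }
    return records, manifest
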