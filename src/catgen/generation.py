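"""Latent-space sampling, catalyst generation and set-level metrics.

Three sampling schemes are supported: a random latent inside the integer
bounding box of the training latent means with a random training condition;
a Gaussian perturbation around an existing catalyst's latent mean with a
random condition; and the same perturbation with the anchor's own
condition. Generated sets are scored with Valid, Valid(Task), Unique,
Novel, IntDiv and SNN over ECFP4 (2048-bit) Tanimoto similarities; all
fractions share the generated-count denominator so the chain
Novel <= Unique <= Valid always holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import DataStructs, rdFingerprintGenerator

from .reconstruction import reconstruct, to_smiles
from .vocab import as_mol

__all__ = [
    "SamplingScheme", "GenerationReport", "GenerationOutput",
    "sample_latent", "generate", "evaluate_generation",
    "task_validity", "register_task_rule", "ligand_filter",
    "tanimoto_similarity", "fingerprint", "METALS",
]

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)

METALS = frozenset({
    "Pd", "Pt", "Ni", "Cu", "Fe", "Ru", "Rh", "Ir", "Co", "Mn", "Zn", "Ag",
    "Au", "Li", "Na", "K", "Mg", "Ca", "Al", "Sn", "Ti", "Zr", "W", "Mo",
    "Cr", "V", "Sc", "Y", "La", "Ce", "Os", "Re", "Ta", "Nb", "Hf", "Cd",
    "Hg", "Pb", "Bi",
})


def fingerprint(mol):
    return _MORGAN.GetFingerprint(as_mol(mol))


def tanimoto_similarity(a, b) -> float:
    return DataStructs.TanimotoSimilarity(fingerprint(a), fingerprint(b))


@dataclass(frozen=True)
class SamplingScheme:
    """How latents and conditions are drawn for generation."""

    kind: str = "random_latent_random_condition"
    noise_scale: float = 0.5
    bounds_mode: bool = True
    seed: int = 0

    KINDS = ("random_latent_random_condition",
             "around_sample_random_condition",
             "around_sample_sample_condition")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown sampling scheme {self.kind!r}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


@dataclass
class GenerationReport:
    n_requested: int
    n_decoded: int
    valid: float
    valid_task: float | None
    unique: float
    novel: float
    intdiv: float
    snn: float
    fcd: float | None = None

    def __post_init__(self):
        assert self.novel <= self.unique + 1e-12 <= self.valid + 2e-12, \
            "metric chain inequality violated"

    def as_dict(self):
        return dict(self.__dict__)


@dataclass
class GenerationOutput:
    smiles: list          # canonical SMILES or None per attempt
    reports: list         # ReconstructionReport per attempt

    @property
    def valid_smiles(self):
        return [s for s in self.smiles if s is not None]


def latent_box(training_means: np.ndarray) -> np.ndarray:
    """Per-dimension integer bounding box [floor(min), ceil(max)]."""
    lo = np.floor(training_means.min(axis=0))
    hi = np.ceil(training_means.max(axis=0))
    return np.stack([lo, hi])


def sample_latent(scheme: SamplingScheme, results, anchor=None,
                  training_latents=None, rng=None):
    """Draw one (latent, condition) pair under a sampling scheme.

    ``results`` is a fitted :class:`catgen.model.CVAEResults`. ``anchor``
    is a ReactionRecord for the around-sample schemes. Returns
    (z, condition_vector).
    """
    rng = rng or np.random.default_rng(scheme.seed)
    if training_latents is None:
        training_latents = results.training_latents()
    means, conds = training_latents
    if scheme.kind == "random_latent_random_condition":
        box = latent_box(means)
        z = rng.uniform(box[0], box[1]) if scheme.bounds_mode else \
            rng.normal(size=means.shape[1])
        c = conds[rng.integers(len(conds))]
        return z, c
    if anchor is None:
        raise ValueError("around-sample schemes require an anchor record")
    a_mean, a_cond = results.encode_records([anchor])
    z = a_mean[0] + rng.normal(0.0, 1.0, size=a_mean.shape[1]) \
        * scheme.noise_scale
    if scheme.kind == "around_sample_sample_condition":
        return z, a_cond[0]
    return z, conds[rng.integers(len(conds))]


def generate(n: int, scheme: SamplingScheme, results,
             post_processing: bool = True, anchor=None) -> GenerationOutput:
    """Decode ``n`` sampled latents into molecules; empty decodes are kept
    as invalid entries. Reproducible under the scheme seed."""
    rng = np.random.default_rng(scheme.seed)
    training_latents = results.training_latents()
    smiles, reports = [], []
    for _ in range(n):
        z, c = sample_latent(scheme, results, anchor=anchor,
                             training_latents=training_latents, rng=rng)
        logits = results.decode_latent(z, c)
        mol, rep = reconstruct(logits, results.vocab,
                               correction=post_processing)
        smi = to_smiles(mol) if (post_processing or rep.sanitization_passed) \
            else None
        smiles.append(smi)
        reports.append(rep)
    return GenerationOutput(smiles, reports)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _sanitizable(smi) -> bool:
    if smi is None:
        return False
    return Chem.MolFromSmiles(smi) is not None


def evaluate_generation(generated, training_set, task_rule=None,
                        n_requested=None) -> GenerationReport:
    """Score a generated set against the training set.

    ``generated`` is a list of SMILES (None for failed decodes);
    ``training_set`` a list of SMILES. ``task_rule`` is a rule name or a
    predicate on an RDKit Mol. All fractions are relative to the number of
    generation attempts; SNN averages over valid molecules.
    """
    if not training_set:
        raise ValueError("training set must be non-empty")
    if isinstance(generated, GenerationOutput):
        generated = generated.smiles
    n = n_requested or len(generated)
    valid = [Chem.CanonSmiles(s) for s in generated if _sanitizable(s)]
    distinct = list(dict.fromkeys(valid))
    train_canon = {Chem.CanonSmiles(s) for s in training_set}
    novel = [s for s in distinct if s not in train_canon]

    train_fps = [fingerprint(s) for s in train_canon]
    valid_fps = [fingerprint(s) for s in valid]
    distinct_fps = [fingerprint(s) for s in distinct]

    if len(distinct_fps) >= 2:
        dists = []
        for i in range(len(distinct_fps)):
            sims = DataStructs.BulkTanimotoSimilarity(
                distinct_fps[i], distinct_fps[i + 1:])
            dists.extend(1.0 - np.asarray(sims))
        intdiv = float(np.mean(dists))
    else:
        intdiv = 0.0
    if valid_fps:
        snn = float(np.mean([
            max(DataStructs.BulkTanimotoSimilarity(fp, train_fps))
            for fp in valid_fps]))
    else:
        snn = 0.0
    if task_rule is not None:
        ok = sum(task_validity(s, task_rule) for s in valid)
        valid_task = ok / n
    else:
        valid_task = None
    return GenerationReport(
        n_requested=n, n_decoded=len(valid),
        valid=len(valid) / n, valid_task=valid_task,
        unique=len(distinct) / n, novel=len(novel) / n,
        intdiv=intdiv, snn=snn)


# ---------------------------------------------------------------------------
# task-specific validity rules
# ---------------------------------------------------------------------------

def _single_fragment(mol) -> bool:
    return len(Chem.GetMolFrags(mol)) == 1


_PD_OAC2_COVALENT = Chem.MolFromSmarts("CC(=O)O[Pd]OC(C)=O")


def _contains_pd_acetate(mol) -> bool:
    """Pd(OAc)2 present either covalently or as an ionic fragment set."""
    if mol.HasSubstructMatch(_PD_OAC2_COVALENT):
        return True
    frags = [Chem.MolToSmiles(f) for f in
             Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)]
    has_pd = any(f in ("[Pd]", "[Pd+2]") for f in frags)
    n_oac = sum(f in ("CC(=O)[O-]", "CC(=O)O") for f in frags)
    return has_pd and n_oac >= 2


def _three_fragment_metal(mol) -> bool:
    """L1-M-L2 motif: exactly 3 fragments, exactly one a lone metal atom."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) != 3:
        return False
    lone_metals = sum(
        1 for f in frags
        if f.GetNumAtoms() == 1 and f.GetAtomWithIdx(0).GetSymbol() in METALS)
    return lone_metals == 1


_TASK_RULES = {
    "single_fragment": _single_fragment,     # L-SM and PS datasets
    "pd_acetate": _contains_pd_acetate,      # SM (Random) dataset
    "three_fragment_metal": _three_fragment_metal,  # CC dataset
}


def register_task_rule(name: str, predicate):
    _TASK_RULES[name] = predicate


def task_validity(molecule, rule) -> bool:
    """Evaluate a named (or callable) task-specific validity rule."""
    mol = as_mol(molecule)
    if mol.GetNumAtoms() == 0:
        raise ValueError("molecule must be non-empty")
    if callable(rule):
        return bool(rule(mol))
    try:
        fn = _TASK_RULES[rule]
    except KeyError:
        raise KeyError(f"unknown task rule {rule!r}; registered: "
                       f"{sorted(_TASK_RULES)}") from None
    return bool(fn(mol))


# ---------------------------------------------------------------------------
# ligand filtering (phosphine/amine ligand plausibility)
# ---------------------------------------------------------------------------

def ligand_filter(molecule, ruleset: str = "l_sm"):
    """Ligand plausibility filter; returns (passes, violated rule names).

    Rules: the molecule must contain N or P (metal-coordinating elements);
    every phosphorus must have exactly three covalent bonds; no P-H bonds
    (too reactive to serve as ligands); no phosphorus inside a
    three-membered ring (synthetically challenging).
    """
    if ruleset != "l_sm":
        raise ValueError(f"unknown ruleset {ruleset!r}")
    mol = as_mol(molecule)
    violations = []
    p_atoms = [a for a in mol.GetAtoms() if a.GetSymbol() == "P"]
    n_atoms = [a for a in mol.GetAtoms() if a.GetSymbol() == "N"]
    if not p_atoms and not n_atoms:
        violations.append("missing_n_or_p")
    if any(a.GetTotalDegree() != 3 for a in p_atoms):
        violations.append("phosphine_not_three_bonds")
    if any(a.GetTotalNumHs() > 0 for a in p_atoms):
        violations.append("p_h_bond")
    if any(a.IsInRingSize(3) for a in p_atoms):
        violations.append("p_in_three_membered_ring")
    return (not violations, violations)
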