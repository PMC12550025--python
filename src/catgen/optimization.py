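"""Inverse design: Bayesian optimization over the latent space.

The objective for a latent point is built from the full
decode -> re-embed -> re-encode -> predict loop: the decoded catalyst is
embedded and re-encoded, the predictor scores the (re-encoded mean,
condition) pair, and structural penalties/rewards plus an optional
similarity term adjust the base score. Failed decodes receive a finite
worst-case score so the optimizer can continue.

The search runs either inside the integer bounding box of the training
latent means ("search from random space") or inside a ball around a
starting molecule's latent ("search around a starting molecule"),
using a Gaussian-process surrogate with expected improvement (random
exploration until 10 points are available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from scipy.stats import norm

from .generation import METALS, latent_box, tanimoto_similarity
from .vocab import as_mol

__all__ = ["ObjectiveSpec", "OptimizationRun", "OptimizationResult",
           "objective_evaluate", "bayes_optimize", "STRUCTURAL_PREDICATES",
           "CC_BINDING_ENERGY_RANGE", "cc_objective_target", "cc_protocol"]

#: appropriate substrate binding-energy window (kcal/mol) for effective
#: Suzuki-Miyaura cross-coupling catalysts in the C-C cross-coupling case.
CC_BINDING_ENERGY_RANGE = (-32.1, -23.0)


def cc_objective_target() -> float:
    """Objective target for the CC case: the mean of the desired
    binding-energy range (kcal/mol)."""
    return float(np.mean(CC_BINDING_ENERGY_RANGE))


def cc_protocol(**overrides) -> "OptimizationRun":
    """CC case-study search budget: 50 rounds, top 10 kept per round."""
    base = dict(rounds=50, top_k=10, calls_per_round=12)
    base.update(overrides)
    return OptimizationRun(**base)


# ---------------------------------------------------------------------------
# structural predicates (True = condition violated / satisfied, used for
# penalties and rewards respectively)
# ---------------------------------------------------------------------------

def _too_many_fragments(mol, max_frags=3):
    return len(Chem.GetMolFrags(mol)) > max_frags


def _missing_key_atom(mol):
    symbols = {a.GetSymbol() for a in mol.GetAtoms()}
    return not (symbols & {"P", "N", "O"})


def _illegal_key_atom_bonding(mol):
    for a in mol.GetAtoms():
        if a.GetSymbol() == "P" and a.GetTotalDegree() > 4:
            return True
        if a.GetSymbol() == "N" and a.GetTotalDegree() > 4:
            return True
        if a.GetSymbol() == "O" and a.GetTotalDegree() > 3:
            return True
    return False


def _small_ring(mol):
    return any(len(r) in (3, 4) for r in mol.GetRingInfo().AtomRings())


#: CC-case structural penalties: fragment-count restriction, absence of key
#: atoms (P/N/O), illegal bonding on those atoms, 3-/4-membered rings.
STRUCTURAL_PREDICATES = {
    "too_many_fragments": _too_many_fragments,
    "missing_key_atom": _missing_key_atom,
    "illegal_key_atom_bonding": _illegal_key_atom_bonding,
    "small_ring": _small_ring,
}


def _resolve(predicate):
    return STRUCTURAL_PREDICATES[predicate] if isinstance(predicate, str) \
        else predicate


@dataclass
class ObjectiveSpec:
    """Target mode, penalties/rewards and similarity terms for inverse design.

    ``match_value`` mode scores -|prediction - target| before adjustments;
    ``maximize`` scores the prediction itself.
    """

    target_mode: str = "maximize"          # maximize | match_value
    target: float | None = None
    penalties: list = field(default_factory=list)   # [(predicate, magnitude)]
    rewards: list = field(default_factory=list)
    similarity_ref: list | None = None     # reference SMILES
    similarity_weight: float = 0.0
    condition: np.ndarray | None = None

    def __post_init__(self):
        if self.target_mode not in ("maximize", "match_value"):
            raise ValueError(f"unknown target_mode {self.target_mode!r}")
        if self.target_mode == "match_value" and self.target is None:
            raise ValueError("match_value mode requires a target")
        for _, mag in list(self.penalties) + list(self.rewards):
            if mag < 0:
                raise ValueError("penalty/reward magnitudes must be >= 0")

    def base_score(self, prediction: float) -> float:
        if self.target_mode == "match_value":
            return -abs(prediction - self.target)
        return prediction

    def adjust(self, mol, base: float) -> float:
        score = base
        for predicate, mag in self.rewards:
            if _resolve(predicate)(mol):
                score += mag
        for predicate, mag in self.penalties:
            if _resolve(predicate)(mol):
                score -= mag
        if self.similarity_ref and self.similarity_weight > 0:
            best = max(tanimoto_similarity(mol, ref)
                       for ref in self.similarity_ref)
            score -= self.similarity_weight * (1.0 - best)
        return score


@dataclass
class OptimizationRun:
    """Search strategy and budget for one optimization campaign."""

    strategy: str = "random_space"        # random_space | around_molecule
    anchor: object = None                 # ReactionRecord for around_molecule
    radius: float = 2.0                   # ball radius around the anchor
    rounds: int = 50
    calls_per_round: int = 12
    top_k: int = 10
    seed: int = 0
    gp_candidates: int = 256
    gp_max_points: int = 256

    def __post_init__(self):
        if self.strategy not in ("random_space", "around_molecule"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "around_molecule" and self.anchor is None:
            raise ValueError("around_molecule strategy requires an anchor")


@dataclass
class OptimizationResult:
    candidates: list      # (smiles, score, prediction, round) best-per-round
    trace: list           # dicts: round, call, latent, smiles, score
    best_so_far: np.ndarray

    @property
    def best(self):
        return max(self.candidates, key=lambda c: c[1]) if self.candidates \
            else None


def objective_evaluate(z: np.ndarray, spec: ObjectiveSpec, results,
                       failure_score: float = None):
    """Score one latent point; returns (score, smiles_or_None, prediction).

    The decoded catalyst is re-embedded and re-encoded before prediction,
    so the score reflects the molecule the decoder actually produced.
    """
    from .reconstruction import reconstruct, to_smiles
    c = spec.condition
    if c is None:
        raise ValueError("ObjectiveSpec.condition must be set")
    logits = results.decode_latent(np.asarray(z, dtype=float), c)
    mol, _ = reconstruct(logits, results.vocab, correction=True)
    smi = to_smiles(mol)
    if smi is None:
        return (failure_score if failure_score is not None else -1e6,
                None, None)
    mean = results.reencode(smi, c)
    prediction = results.predict_latent(mean, c)
    score = spec.adjust(as_mol(smi), spec.base_score(prediction))
    return score, smi, prediction


def _dynamic_failure_score(scores):
    """Worst-case score for empty decodes: min - 3*IQR so far, floored."""
    finite = [s for s in scores if s > -1e5]
    if not finite:
        return -1e3
    q1, q3 = np.percentile(finite, [25, 75])
    return max(min(finite) - 3.0 * (q3 - q1), min(finite) - 1e3)


def bayes_optimize(spec: ObjectiveSpec, results=None,
                   run: OptimizationRun | None = None,
                   objective=None) -> OptimizationResult:
    """Sequential model-based optimization of the latent objective.

    ``objective`` may override the default decode/re-encode/predict loop
    (it must map a latent vector to (score, molecule_key, prediction)),
    which keeps the search loop testable with cheap mock objectives.
    """
    run = run or OptimizationRun()
    rng = np.random.default_rng(run.seed)

    if run.strategy == "around_molecule":
        if results is None:
            raise ValueError("around_molecule requires fitted results")
        center = results.encode_records([run.anchor])[0][0]
        dim = center.shape[0]
        sample_point = lambda: _sample_ball(rng, center, run.radius)
        clip_point = lambda z: _clip_ball(z, center, run.radius)
    else:
        if results is not None:
            means, _ = results.training_latents()
            box = latent_box(means)
        else:
            box = np.stack([-np.ones(4), np.ones(4)])
        if np.any(box[1] - box[0] <= 0):
            raise ValueError("degenerate search box (zero volume)")
        dim = box.shape[1]
        sample_point = lambda: rng.uniform(box[0], box[1])
        clip_point = lambda z: np.clip(z, box[0], box[1])

    if objective is None:
        if results is None:
            raise ValueError("either results or an objective is required")
        def objective(z):
            return objective_evaluate(z, spec, results,
                                      failure_score=_dynamic_failure_score(ys))

    xs, ys = [], []
    trace, candidates, best_so_far = [], [], []
    best = -np.inf
    for rnd in range(run.rounds):
        round_pool = {}
        for call in range(run.calls_per_round):
            if len(xs) < 10:
                z = sample_point()
            else:
                z = clip_point(_propose_ei(np.array(xs), np.array(ys), rng,
                                           sample_point, run))
            score, key, prediction = objective(np.asarray(z, dtype=float))
            xs.append(np.asarray(z, dtype=float))
            ys.append(score)
            best = max(best, score)
            best_so_far.append(best)
            trace.append({"round": rnd, "call": call,
                          "latent": np.asarray(z, dtype=float),
                          "smiles": key, "score": score,
                          "prediction": prediction})
            if key is not None:
                # duplicates within a round collapse to their best score
                if key not in round_pool or score > round_pool[key][0]:
                    round_pool[key] = (score, prediction)
        top = sorted(round_pool.items(), key=lambda kv: -kv[1][0])[:run.top_k]
        candidates.extend((k, s, p, rnd) for k, (s, p) in top)
    return OptimizationResult(candidates, trace, np.asarray(best_so_far))


def _sample_ball(rng, center, radius):
    d = center.shape[0]
    v = rng.normal(size=d)
    v /= np.linalg.norm(v)
    r = radius * rng.random() ** (1.0 / d)
    return center + r * v


def _clip_ball(z, center, radius):
    d = z - center
    n = np.linalg.norm(d)
    return z if n <= radius else center + d * (radius / n)


def _propose_ei(xs, ys, rng, sample_point, run):
    """Expected-improvement proposal from a GP with a fixed Matern kernel."""
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern, WhiteKernel
    if len(xs) > run.gp_max_points:
        idx = rng.choice(len(xs), size=run.gp_max_points, replace=False)
        xs, ys = xs[idx], ys[idx]
    y_mean, y_std = ys.mean(), ys.std() or 1.0
    gp = GaussianProcessRegressor(
        kernel=Matern(length_scale=1.0, nu=2.5) + WhiteKernel(1e-4),
        optimizer=None, normalize_y=False)
    gp.fit(xs, (ys - y_mean) / y_std)
    cands = np.array([sample_point() for _ in range(run.gp_candidates)])
    mu, sigma = gp.predict(cands, return_std=True)
    best = ((ys - y_mean) / y_std).max()
    imp = mu - best
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = np.where(sigma > 0, imp / sigma, 0.0)
        ei = np.where(sigma > 0,
                      imp * norm.cdf(zval) + sigma * norm.pdf(zval), 0.0)
    return cands[int(np.argmax(ei))]
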