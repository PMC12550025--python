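"""Reaction-conditioned CVAE for catalyst generation and performance
prediction.

The model follows the statsmodels convention: :class:`CatalystCVAE` is
built from curated reaction records, ``fit()`` returns a
:class:`CVAEResults` carrying the trained network, training history,
held-out metrics and a ``summary()`` table; generation and latent-space
optimization hang off the results object.

Architecture
------------
* catalyst embedding: three sub-networks for (T, A, B), outputs summed;
* condition embedding: a shared graph-attention encoder pools each
  reactant/reagent/product to a fixed vector (mean over multiple molecules
  per role, a learned default token when no reagent is present),
  concatenated with the log reaction time and the catalyst molecular-weight
  cluster one-hot;
* encoder Q(z|x, c) with mean/log-variance heads and reparameterized
  sampling;
* sequential decoder P(M|z, c): length head, annotation head conditioned on
  (z || c || length block), then a per-node linear map whose outer
  (bilinear) products form the initial adjacency, refined per pair into
  bond-type logits. During training each stage consumes the true upstream
  block with probability ``teacher_forcing_ratio``;
* predictor f(z, c) from the mean latent vector;
* loss  L_total = alpha * L_recons + beta * L_KL + L_prediction, where
  L_recons sums categorical cross-entropies over the T, A and B fibers
  (no-bond fibers down-weighted by their observed frequency), L_KL is the
  closed-form Gaussian KL to N(0, I), and L_prediction the squared error
  on the standardized target.
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from ._autodiff import Tensor, no_grad
from ._nn import MLP, Adam, Linear, Module, Parameter, concat
from .data import DatasetSplit, ReactionRecord, split_dataset
from .representation import (CatalystMatrix, MatrixLogits, encode_catalyst,
                             featurize_molecule_graph, mw_cluster_onehot,
                             shuffle_augment)
from .vocab import AtomBondVocabulary, build_vocabulary

__all__ = ["TrainingConfig", "CatalystCVAE", "CVAEResults",
           "SurrogatePredictor", "fit_surrogate", "loss_total"]


@dataclass
class TrainingConfig:
    """Loss weights, schedule and architecture sizes.

    ``teacher_forcing_ratio`` is the per-stage probability that a decoder
    stage starts from the true upstream block during training.
    """

    alpha: float = 1.0
    beta: float = 0.01
    teacher_forcing_ratio: float = 0.25
    seeds: tuple = (0, 1, 2)
    epochs: int = 60
    batch_size: int = 16
    learning_rate: float = 2e-3
    surrogate: str = "none"          # none | random_forest | gradient_boosting
    augment_orders: int = 5          # shuffled node orderings per record
    split_ratios: tuple = (90, 5, 5)
    # architecture
    d_x: int = 256
    d_latent: int = 64
    graph_dim: int = 64
    hidden: int = 128
    node_dim: int = 32
    mw_bins: int = 8
    gat_layers: int = 2

    def __post_init__(self):
        if not (0.0 <= self.teacher_forcing_ratio <= 1.0):
            raise ValueError("teacher_forcing_ratio must be in [0, 1]")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")

    @classmethod
    def desk(cls, **overrides):
        """Small sizes for CPU-scale experiments and tests."""
        base = dict(d_x=64, d_latent=16, graph_dim=16, hidden=64,
                    node_dim=16, epochs=40, seeds=(0,))
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# network modules
# ---------------------------------------------------------------------------

class _GraphAttentionLayer(Module):
    def __init__(self, f_in, f_out, rng):
        self.lin = Linear(f_in, f_out, rng)
        self.a_src = Parameter(rng.normal(0, 0.2, size=(f_out, 1)))
        self.a_dst = Parameter(rng.normal(0, 0.2, size=(f_out, 1)))

    def __call__(self, h: Tensor, adj: np.ndarray) -> Tensor:
        hw = self.lin(h)                              # (N, f_out)
        e = (hw @ self.a_src) + (hw @ self.a_dst).transpose()
        e = e.leaky_relu(0.2) + np.where(adj, 0.0, -1e9)
        att = e.log_softmax(axis=-1).exp()
        return (att @ hw).tanh()


class _GraphEncoder(Module):
    """Attention layers + mean pooling to a fixed-width molecule vector."""

    def __init__(self, f_in, dim, n_layers, rng):
        dims = [f_in] + [dim] * n_layers
        self.layers = [_GraphAttentionLayer(a, b, rng)
                       for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, graph) -> Tensor:
        h = Tensor(graph.node_features)
        adj = graph.adjacency(self_loops=True)
        for layer in self.layers:
            h = layer(h, adj)
        return h.mean(axis=0, keepdims=True)          # (1, dim)


class _Network(Module):
    def __init__(self, vocab: AtomBondVocabulary, config: TrainingConfig,
                 node_feature_width: int, rng: np.random.Generator,
                 n_mw_clusters: int | None = None):
        s, at, bt = vocab.max_nodes, vocab.n_atom_types, vocab.n_bond_types
        cfg = config
        self.S, self.At, self.Bt = s, at, bt
        if n_mw_clusters is None:
            n_mw_clusters = cfg.mw_bins + 1
        d_c = 3 * cfg.graph_dim + 1 + n_mw_clusters
        self.d_c, self.d_x, self.d_z = d_c, cfg.d_x, cfg.d_latent
        # catalyst embedding: one sub-network per matrix component, summed
        self.embed_T = MLP([s, cfg.hidden, cfg.d_x], rng)
        self.embed_A = MLP([s * at, cfg.hidden, cfg.d_x], rng)
        self.embed_B = MLP([s * s * bt, cfg.hidden, cfg.d_x], rng)
        # condition embedding
        self.graph_enc = _GraphEncoder(node_feature_width, cfg.graph_dim,
                                       cfg.gat_layers, rng)
        self.no_reagent = Parameter(rng.normal(0, 0.1, size=(1, cfg.graph_dim)))
        # encoder
        self.enc = MLP([cfg.d_x + d_c, cfg.hidden, cfg.hidden], rng)
        self.enc_mean = Linear(cfg.hidden, cfg.d_latent, rng)
        self.enc_logvar = Linear(cfg.hidden, cfg.d_latent, rng)
        # sequential decoder
        zc = cfg.d_latent + d_c
        self.dec_T = MLP([zc, cfg.hidden, s], rng)
        self.dec_A = MLP([zc + s, cfg.hidden, s * at], rng)
        self.node_map = Linear(at + zc, cfg.node_dim, rng)
        self.bilinear = Parameter(rng.normal(0, 0.2, size=(bt, cfg.node_dim,
                                                           cfg.node_dim)))
        self.refine = MLP([bt, cfg.hidden // 2, bt], rng)
        # predictor
        self.pred = MLP([cfg.d_latent + d_c, cfg.hidden, 1], rng)

    # -- pieces ---------------------------------------------------------------
    def embed_catalyst(self, matrix: CatalystMatrix) -> Tensor:
        s = self.S
        t = Tensor(matrix.T.reshape(1, s))
        a = Tensor(matrix.A.reshape(1, -1))
        b = Tensor(matrix.B.reshape(1, -1))
        return self.embed_T(t) + self.embed_A(a) + self.embed_B(b)

    def embed_condition(self, record: ReactionRecord, mw_edges) -> Tensor:
        reac = [self.graph_enc(featurize_molecule_graph(s))
                for s in record.reactants]
        reac_emb = reac[0] if len(reac) == 1 else (
            sum(reac[1:], reac[0]) / float(len(reac)))
        if record.reagents:
            regs = [self.graph_enc(featurize_molecule_graph(s))
                    for s in record.reagents]
            reg_emb = regs[0] if len(regs) == 1 else (
                sum(regs[1:], regs[0]) / float(len(regs)))
        else:
            reg_emb = self.no_reagent
        prod_emb = self.graph_enc(featurize_molecule_graph(record.product))
        extras = Tensor(np.concatenate([
            [np.log(record.reaction_time)],
            mw_cluster_onehot(record.catalyst_mw, mw_edges),
        ]).reshape(1, -1))
        return concat([reac_emb, reg_emb, prod_emb, extras], axis=1)

    def encode(self, x: Tensor, c: Tensor, eps: np.ndarray | None = None):
        h = self.enc(concat([x, c], axis=1)).tanh()
        mean = self.enc_mean(h)
        logvar = self.enc_logvar(h)
        if eps is None:
            eps = np.zeros((1, self.d_z))
        z = mean + (logvar * 0.5).exp() * Tensor(eps)
        return mean, logvar, z

    def decode(self, z: Tensor, c: Tensor, teacher: CatalystMatrix = None,
               tf_ratio: float = 0.0, rng: np.random.Generator = None):
        if tf_ratio > 0 and teacher is None:
            raise ValueError("teacher matrix required when tf_ratio > 0")
        s, at, bt = self.S, self.At, self.Bt
        zc = concat([z, c], axis=1)
        t_logits = self.dec_T(zc)                     # (1, S)
        use_true = lambda: (tf_ratio > 0 and rng is not None
                            and rng.random() < tf_ratio)
        t_block = (Tensor(teacher.T.reshape(1, s)) if use_true()
                   else t_logits.softmax(axis=-1))
        a_logits = self.dec_A(concat([zc, t_block], axis=1)).reshape(s, at)
        a_block = (Tensor(teacher.A) if use_true()
                   else a_logits.softmax(axis=-1))
        ones = Tensor(np.ones((s, 1)))
        zc_rows = ones @ zc                           # broadcast (S, zc)
        u = self.node_map(concat([a_block, zc_rows], axis=1)).tanh()  # (S, k)
        chans = []
        for t_ch in range(bt):
            w = self.bilinear[t_ch]                   # (k, k)
            chans.append((u @ w @ u.transpose()).reshape(s, s, 1))
        b_init = concat(chans, axis=2)
        b_logits = self.refine(b_init.reshape(s * s, bt)).reshape(s, s, bt)
        b_logits = (b_logits + b_logits.transpose(1, 0, 2)) * 0.5
        return t_logits.reshape(s), a_logits, b_logits

    def predict_head(self, mean: Tensor, c: Tensor) -> Tensor:
        return self.pred(concat([mean, c], axis=1))


def loss_total(logits: MatrixLogits, truth: CatalystMatrix,
               latent, y_hat: float, y: float,
               alpha: float, beta: float, no_bond_weight: float = 1.0):
    """Numpy reference of the training loss (no autodiff).

    ``latent`` is (mean, log_variance). Returns (total, components dict).
    Components: categorical cross-entropies over the T, A, B fibers
    (no-bond-true fibers weighted by ``no_bond_weight``), the closed-form
    Gaussian KL and the squared prediction error.
    """
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be non-negative")

    def lsm(x):
        m = x.max(axis=-1, keepdims=True)
        return x - m - np.log(np.exp(x - m).sum(axis=-1, keepdims=True))

    ce_t = -(truth.T * lsm(logits.T)).sum()
    ce_a = -(truth.A * lsm(logits.A)).sum()
    fiber_ce = -(truth.B * lsm(logits.B)).sum(axis=-1)
    w = np.where(truth.B[..., 0] == 1, no_bond_weight, 1.0)
    ce_b = (w * fiber_ce).sum()
    recons = ce_t + ce_a + ce_b
    mean, logvar = latent
    kl = -0.5 * np.sum(1.0 + logvar - mean ** 2 - np.exp(logvar))
    pred = (y_hat - y) ** 2
    total = alpha * recons + beta * kl + pred
    return total, {"recons": recons, "kl": kl, "prediction": pred,
                   "ce_T": ce_t, "ce_A": ce_a, "ce_B": ce_b}


# ---------------------------------------------------------------------------
# surrogate predictors
# ---------------------------------------------------------------------------

class SurrogatePredictor:
    """Ensemble of fitted regressors; prediction is the member average."""

    def __init__(self, members, kind):
        self.members = members
        self.kind = kind

    def predict(self, features) -> np.ndarray:
        features = np.asarray(features)
        return np.mean([m.predict(features) for m in self.members], axis=0)


def fit_surrogate(features, targets, model_kind: str = "random_forest",
                  n_members: int = 1, seed: int = 0) -> SurrogatePredictor:
    """Fit a tree-ensemble surrogate on (latent || condition) or descriptor
    features. Requires at least 10 samples."""
    from sklearn.ensemble import (GradientBoostingRegressor,
                                  RandomForestRegressor)
    features = np.asarray(features, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if len(features) < 10:
        raise ValueError("surrogate fitting requires at least 10 samples")
    members = []
    for k in range(n_members):
        if model_kind == "random_forest":
            m = RandomForestRegressor(n_estimators=300, random_state=seed + k)
        elif model_kind == "gradient_boosting":
            m = GradientBoostingRegressor(n_estimators=600, learning_rate=0.05,
                                          max_depth=3, subsample=0.9,
                                          random_state=seed + k)
        else:
            raise ValueError(f"unsupported surrogate kind {model_kind!r}")
        members.append(m.fit(features, targets))
    return SurrogatePredictor(members, model_kind)


# ---------------------------------------------------------------------------
# the model / results pair
# ---------------------------------------------------------------------------

class CatalystCVAE:
    """Reaction-conditioned CVAE over curated :class:`ReactionRecord` lists.

    Parameters
    ----------
    records : list of ReactionRecord
        Curated reactions (see :mod:`catgen.data`).
    vocab : AtomBondVocabulary, optional
        Derived from the records when omitted.
    config : TrainingConfig, optional
    mw_bin_edges : sequence, optional
        Molecular-weight cluster edges; default: training-set quantiles
        (``config.mw_bins`` bins).
    """

    def __init__(self, records, vocab=None, config=None, mw_bin_edges=None):
        from rdkit import Chem
        self.records = list(records)
        self.config = config or TrainingConfig()
        if vocab is None:
            mols = [r.catalyst for r in self.records]
            max_atoms = max((r.catalyst_atom_count for r in self.records),
                            default=1)
            elements = {a.GetSymbol() for s in mols
                        for a in Chem.MolFromSmiles(s).GetAtoms()}
            vocab = build_vocabulary(mols,
                                     max_atom_types=max(8, len(elements) + 2),
                                     max_nodes=max_atoms + 3)
        self.vocab = vocab
        if mw_bin_edges is None:
            mws = sorted(set(r.catalyst_mw for r in self.records)) or [100.0]
            qs = np.linspace(0, 100, self.config.mw_bins + 1)[1:-1]
            edges = np.unique(np.percentile(mws, qs)) if len(mws) > 2 else \
                np.array([float(np.mean(mws))])
            mw_bin_edges = edges
        self.mw_bin_edges = np.asarray(mw_bin_edges, dtype=float)
        self._check_coverage()
        self.target_kind = (self.records[0].target_kind
                            if self.records else "yield")

    @classmethod
    def from_table(cls, path, dialect=None, **kwargs):
        from .data import parse_reaction_table
        return cls(parse_reaction_table(path, dialect=dialect), **kwargs)

    def _check_coverage(self):
        from rdkit import Chem
        for r in self.records:
            mol = Chem.MolFromSmiles(r.catalyst)
            if mol.GetNumAtoms() > self.vocab.max_nodes - 1:
                raise ValueError(
                    f"catalyst {r.catalyst!r} exceeds node budget "
                    f"{self.vocab.max_nodes - 1}")
            if not self.vocab.covers(mol):
                raise ValueError(
                    f"catalyst {r.catalyst!r} contains elements outside the "
                    f"vocabulary")

    # -- fitting --------------------------------------------------------------
    def fit(self, seed: int | None = None, progress: bool = False,
            split: DatasetSplit | None = None,
            initial_state: dict | None = None) -> "CVAEResults":
        """Train one network (one seed) and return a results object."""
        cfg = self.config
        seed = cfg.seeds[0] if seed is None else seed
        rng = np.random.default_rng(seed)
        net = _Network(self.vocab, cfg,
                       featurize_molecule_graph("C").scheme.node_width,
                       np.random.default_rng(seed),
                       n_mw_clusters=len(self.mw_bin_edges) + 1)
        if initial_state is not None:
            net.load_state_dict(initial_state)
        if split is None:
            split = split_dataset(self.records, ratios=cfg.split_ratios,
                                  seed=seed)
        matrices = {id(r): encode_catalyst(r.catalyst, self.vocab)
                    for part in (split.train, split.validation, split.test)
                    for r in part}
        # target standardization on the training split
        ys = np.array([r.target for r in split.train], dtype=float)
        y_mean = float(ys.mean()) if len(ys) else 0.0
        y_std = float(ys.std()) or 1.0
        # observed no-bond frequency -> down-weighting of no-bond fibers
        nb, tot = 0, 0
        for r in split.train:
            b = matrices[id(r)].B
            nb += int(b[..., 0].sum())
            tot += b.shape[0] * b.shape[1]
        no_bond_weight = max((tot - nb) / max(nb, 1), 0.02)

        train_items = []
        for r in split.train:
            variants = shuffle_augment(matrices[id(r)], cfg.augment_orders,
                                       seed=int(rng.integers(2 ** 31)))
            train_items.extend((v, r) for v in variants)

        opt = Adam(net.parameters(), lr=cfg.learning_rate)
        history = {"total": [], "recons": [], "kl": [], "prediction": [],
                   "rmse": []}
        t_start = _time.time()
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(train_items))
            sums = {k: 0.0 for k in history}
            sq_err, n_seen = 0.0, 0
            for start in range(0, len(order), cfg.batch_size):
                batch = order[start:start + cfg.batch_size]
                opt.zero_grad()
                batch_loss = None
                for idx in batch:
                    matrix, rec = train_items[idx]
                    loss, comps, y_hat = self._forward(
                        net, matrix, rec, rng, y_mean, y_std,
                        no_bond_weight, training=True)
                    batch_loss = loss if batch_loss is None else batch_loss + loss
                    for k in ("total", "recons", "kl", "prediction"):
                        sums[k] += comps[k]
                    sq_err += (y_hat - rec.target) ** 2
                    n_seen += 1
                (batch_loss * (1.0 / len(batch))).backward()
                opt.step()
            for k in ("total", "recons", "kl", "prediction"):
                history[k].append(sums[k] / max(n_seen, 1))
            history["rmse"].append(float(np.sqrt(sq_err / max(n_seen, 1))))
            if progress:
                print(f"epoch {epoch + 1}/{cfg.epochs} "
                      f"total={history['total'][-1]:.2f} "
                      f"rmse={history['rmse'][-1]:.2f}")
        return CVAEResults(self, net, split, history, seed,
                           y_mean=y_mean, y_std=y_std,
                           no_bond_weight=no_bond_weight,
                           train_seconds=_time.time() - t_start)

    def fit_multiseed(self, seeds=None, **kwargs):
        """Fit once per seed; returns (results list, aggregate metric report
        with per-seed values, mean and standard deviation)."""
        seeds = tuple(seeds if seeds is not None else self.config.seeds)
        results = [self.fit(seed=s, **kwargs) for s in seeds]
        per_seed = {s: r.evaluate("test") for s, r in zip(seeds, results)}
        keys = ("rmse", "mae", "r2")
        report = {"seeds": {str(s): per_seed[s] for s in seeds},
                  "mean": {k: float(np.mean([per_seed[s][k] for s in seeds]))
                           for k in keys},
                  "sd": {k: float(np.std([per_seed[s][k] for s in seeds]))
                         for k in keys}}
        return results, report

    def _forward(self, net, matrix, rec, rng, y_mean, y_std,
                 no_bond_weight, training):
        cfg = self.config
        c = net.embed_condition(rec, self.mw_bin_edges)
        x = net.embed_catalyst(matrix)
        eps = rng.normal(size=(1, net.d_z)) if training else None
        mean, logvar, z = net.encode(x, c, eps)
        t_log, a_log, b_log = net.decode(
            z, c, teacher=matrix,
            tf_ratio=cfg.teacher_forcing_ratio if training else 0.0,
            rng=rng)
        y_hat_t = net.predict_head(mean, c)
        y_standard = (rec.target - y_mean) / y_std

        ce_t = -(Tensor(matrix.T) * t_log.log_softmax(axis=-1)).sum()
        ce_a = -(Tensor(matrix.A) * a_log.log_softmax(axis=-1)).sum()
        fiber = -(Tensor(matrix.B) * b_log.log_softmax(axis=-1)).sum(axis=-1)
        w = np.where(matrix.B[..., 0] == 1, no_bond_weight, 1.0)
        ce_b = (fiber * w).sum()
        recons = ce_t + ce_a + ce_b
        kl = ((mean ** 2 + logvar.exp() - logvar - 1.0).sum()) * 0.5
        pred = (y_hat_t - y_standard) ** 2
        loss = recons * cfg.alpha + kl * cfg.beta + pred.sum()
        comps = {"total": loss.item(), "recons": recons.item(),
                 "kl": kl.item(), "prediction": pred.item()}
        y_hat = y_hat_t.item() * y_std + y_mean
        return loss, comps, y_hat


class CVAEResults:
    """Fitted model state: network weights, split, history, scalers."""

    def __init__(self, model: CatalystCVAE, network: _Network,
                 split: DatasetSplit, history: dict, seed: int,
                 y_mean: float, y_std: float, no_bond_weight: float,
                 train_seconds: float = 0.0, surrogate=None):
        self.model = model
        self.network = network
        self.split = split
        self.history = history
        self.seed = seed
        self.y_mean, self.y_std = y_mean, y_std
        self.no_bond_weight = no_bond_weight
        self.train_seconds = train_seconds
        self.surrogate = surrogate
        self._latent_cache = None

    @property
    def vocab(self) -> AtomBondVocabulary:
        return self.model.vocab

    @property
    def config(self) -> TrainingConfig:
        return self.model.config

    # -- inference ------------------------------------------------------------
    def encode_records(self, records):
        """Mean latent vectors and condition vectors for records."""
        means, conds = [], []
        with no_grad():
            for rec in records:
                matrix = encode_catalyst(rec.catalyst, self.vocab)
                c = self.network.embed_condition(rec, self.model.mw_bin_edges)
                x = self.network.embed_catalyst(matrix)
                mean, _, _ = self.network.encode(x, c)
                means.append(mean.data[0])
                conds.append(c.data[0])
        return np.array(means), np.array(conds)

    def training_latents(self):
        if self._latent_cache is None:
            self._latent_cache = self.encode_records(self.split.train)
        return self._latent_cache

    def predict(self, records) -> np.ndarray:
        """Predicted targets on the original scale (percent for yield)."""
        if self.surrogate is not None:
            means, conds = self.encode_records(records)
            return self.surrogate.predict(np.hstack([means, conds]))
        out = []
        with no_grad():
            for rec in records:
                matrix = encode_catalyst(rec.catalyst, self.vocab)
                c = self.network.embed_condition(rec, self.model.mw_bin_edges)
                x = self.network.embed_catalyst(matrix)
                mean, _, _ = self.network.encode(x, c)
                y = self.network.predict_head(mean, c).item() \
                    * self.y_std + self.y_mean
                out.append(y)
        out = np.array(out)
        if self.model.target_kind == "yield":
            out = np.clip(out, 0.0, 100.0)
        return out

    def decode_latent(self, z: np.ndarray, c: np.ndarray) -> MatrixLogits:
        """Decode a latent/condition pair to matrix logits (evaluation mode)."""
        with no_grad():
            t, a, b = self.network.decode(Tensor(z.reshape(1, -1)),
                                          Tensor(c.reshape(1, -1)))
        return MatrixLogits(t.data, a.data, b.data)

    def reencode(self, catalyst_smiles: str, c: np.ndarray) -> np.ndarray:
        """Embed + re-encode a catalyst under a condition; returns the mean."""
        matrix = encode_catalyst(catalyst_smiles, self.vocab)
        with no_grad():
            x = self.network.embed_catalyst(matrix)
            mean, _, _ = self.network.encode(x, Tensor(c.reshape(1, -1)))
        return mean.data[0]

    def predict_latent(self, mean: np.ndarray, c: np.ndarray) -> float:
        if self.surrogate is not None:
            return float(self.surrogate.predict(
                np.hstack([mean, c]).reshape(1, -1))[0])
        with no_grad():
            y = self.network.predict_head(
                Tensor(mean.reshape(1, -1)), Tensor(c.reshape(1, -1))).item()
        y = y * self.y_std + self.y_mean
        if self.model.target_kind == "yield":
            y = float(np.clip(y, 0.0, 100.0))
        return y

    def reconstruct_records(self, records, correction: bool = True):
        """Decode each record's own latent mean back to a molecule."""
        from .reconstruction import reconstruct, to_smiles
        out = []
        means, conds = self.encode_records(records)
        for mean, c in zip(means, conds):
            logits = self.decode_latent(mean, c)
            mol, rep = reconstruct(logits, self.vocab, correction=correction)
            out.append((to_smiles(mol), rep))
        return out

    def evaluate(self, which: str = "test") -> dict:
        from sklearn.metrics import (mean_absolute_error, mean_squared_error,
                                     r2_score)
        part = {"train": self.split.train, "validation": self.split.validation,
                "test": self.split.test}[which]
        if not part:
            return {"rmse": float("nan"), "mae": float("nan"),
                    "r2": float("nan"), "n": 0}
        y = np.array([r.target for r in part])
        y_hat = self.predict(part)
        return {"rmse": float(np.sqrt(mean_squared_error(y, y_hat))),
                "mae": float(mean_absolute_error(y, y_hat)),
                "r2": float(r2_score(y, y_hat)) if len(part) > 1 else float("nan"),
                "n": len(part)}

    # -- fine-tuning ----------------------------------------------------------
    def finetune(self, records, epochs: int | None = None,
                 surrogate: str | None = None, seed: int | None = None,
                 **config_overrides) -> "CVAEResults":
        """Continue training on a downstream dataset, loading the whole
        pre-trained model (encoder, decoder and predictor).

        For yield-kind targets the original predictor head is updated; for
        other target kinds (or on request) a surrogate regressor is fitted
        on (mean latent || condition) features.
        """
        cfg = replace(self.config, **config_overrides)
        if epochs is not None:
            cfg = replace(cfg, epochs=epochs)
        sub = CatalystCVAE(records, vocab=self.vocab, config=cfg,
                           mw_bin_edges=self.model.mw_bin_edges)
        res = sub.fit(seed=self.seed if seed is None else seed,
                      initial_state=self.network.state_dict())
        kind = records[0].target_kind if records else "yield"
        want = surrogate if surrogate is not None else (
            cfg.surrogate if kind != "yield" else "none")
        if want not in (None, "none"):
            means, conds = res.encode_records(res.split.train)
            y = [r.target for r in res.split.train]
            res.surrogate = fit_surrogate(np.hstack([means, conds]), y,
                                          model_kind=want, n_members=3,
                                          seed=res.seed)
        return res

    # -- generation / optimization delegates ----------------------------------
    def generate(self, n, scheme=None, post_processing: bool = True,
                 seed: int = 0, anchor=None):
        from .generation import SamplingScheme, generate
        scheme = scheme or SamplingScheme(seed=seed)
        return generate(n, scheme, self, post_processing=post_processing,
                        anchor=anchor)

    def optimize(self, spec, run=None, **kwargs):
        from .optimization import bayes_optimize
        return bayes_optimize(spec, self, run=run, **kwargs)

    # -- reporting ------------------------------------------------------------
    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Catalyst CVAE results",
            "=" * 54,
            f"records (train/val/test): {len(self.split.train)}/"
            f"{len(self.split.validation)}/{len(self.split.test)}",
            f"vocabulary: S={self.vocab.max_nodes}, "
            f"At={self.vocab.n_atom_types}, Bt={self.vocab.n_bond_types} "
            f"(flat dim {self.vocab.flat_dim})",
            f"latent dim: {cfg.d_latent}   seed: {self.seed}",
            f"loss weights: alpha={cfg.alpha} beta={cfg.beta} "
            f"teacher forcing={cfg.teacher_forcing_ratio}",
            f"epochs: {cfg.epochs} (augment x{cfg.augment_orders}), "
            f"{self.train_seconds:.0f} s",
        ]
        if self.history["total"]:
            lines.append(f"final losses: total={self.history['total'][-1]:.2f} "
                         f"recons={self.history['recons'][-1]:.2f} "
                         f"KL={self.history['kl'][-1]:.3f} "
                         f"pred={self.history['prediction'][-1]:.3f}")
        for part in ("train", "test"):
            if getattr(self.split, part if part != "test" else "test"):
                m = self.evaluate(part)
                lines.append(f"{part:5s}: RMSE={m['rmse']:.2f} "
                             f"MAE={m['mae']:.2f} R2={m['r2']:.3f} (n={m['n']})")
        if self.surrogate is not None:
            lines.append(f"surrogate: {self.surrogate.kind} "
                         f"({len(self.surrogate.members)} members)")
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------------
    def save(self, directory):
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "weights.npz",
                 **{k: v for k, v in self.network.state_dict().items()})
        (d / "vocabulary.json").write_text(self.vocab.to_json())
        cfg = asdict(self.config)
        cfg["seed"] = self.seed
        cfg["y_mean"], cfg["y_std"] = self.y_mean, self.y_std
        cfg["no_bond_weight"] = self.no_bond_weight
        cfg["mw_bin_edges"] = list(map(float, self.model.mw_bin_edges))
        (d / "config.json").write_text(json.dumps(cfg, indent=2))
        (d / "metrics.json").write_text(json.dumps(
            {"history_final": {k: (v[-1] if v else None)
                               for k, v in self.history.items()}}, indent=2))
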