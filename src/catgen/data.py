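"""Reaction-record ingestion and curation.

The curation pipeline mirrors standard practice for tabular reaction data
(SURF-like CSV/TSV): SMILES normalization, duplicate averaging over the
full reaction key, IQR outlier removal on catalyst molecular weight,
catalyst atom count and yield, clipping of percent yield to [0, 100],
downsampling of overrepresented catalysts, and a 90:5:5 train/val/test
split. Every dropped row carries a machine-readable reason.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

__all__ = [
    "ReactionRecord", "DatasetSplit", "SchemaError", "DEFAULT_DIALECT",
    "parse_reaction_table", "deduplicate_average", "iqr_filter",
    "clip_target", "downsample_overrepresented", "split_dataset", "curate",
]


class SchemaError(ValueError):
    """A mandatory column is missing from the reaction table."""


@dataclass(frozen=True)
class ReactionRecord:
    """One curated reaction. Ligands and metal fragments are part of the
    (possibly multi-fragment, dot-separated) catalyst SMILES."""

    reactants: tuple
    product: str
    catalyst: str
    reagents: tuple
    reaction_time: float      # hours, > 0
    target: float             # percent yield, or another catalytic metric
    target_kind: str = "yield"   # yield | binding_energy | ddG | other
    catalyst_mw: float = 0.0  # g/mol

    @property
    def catalyst_atom_count(self) -> int:
        mol = Chem.MolFromSmiles(self.catalyst)
        return mol.GetNumAtoms() if mol is not None else 0

    def key(self):
        """Duplicate key: order-insensitive in reactants and reagents."""
        return (tuple(sorted(self.reactants)), self.product, self.catalyst,
                tuple(sorted(self.reagents)), self.reaction_time)


@dataclass
class DatasetSplit:
    train: list
    validation: list
    test: list
    ratios: tuple = (90, 5, 5)
    seed: int = 0


#: column map for the SURF-like dialect: reactant_1..n, product, catalyst,
#: reagent_1..n, time_h, yield (or a `target`/`target_kind` pair).
DEFAULT_DIALECT = {
    "reactant_prefix": "reactant",
    "product": "product",
    "catalyst": "catalyst",
    "reagent_prefix": "reagent",
    "time": "time_h",
    "target": "yield",
    "target_kind": "yield",
}


def _canon(smiles: str):
    if not isinstance(smiles, str) or not smiles.strip():
        return None
    mol = Chem.MolFromSmiles(smiles.strip())
    return None if mol is None else Chem.MolToSmiles(mol)


def parse_reaction_table(path, dialect=None, drop_log=None):
    """Read a delimited reaction table into normalized ReactionRecords.

    Rows missing a mandatory role, with non-positive time, or with
    unparseable SMILES are dropped; reasons are appended to ``drop_log``
    (a list of dicts) when provided.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    for col in (dialect["product"], dialect["catalyst"], dialect["time"]):
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    r_cols = [c for c in df.columns if c.startswith(dialect["reactant_prefix"])]
    g_cols = [c for c in df.columns if c.startswith(dialect["reagent_prefix"])]
    if not r_cols:
        raise SchemaError("no reactant columns found")
    t_col = dialect["target"]
    if t_col not in df.columns:
        raise SchemaError(f"missing target column {t_col!r}")

    records = []
    for idx, row in df.iterrows():
        reason = None
        reactants = tuple(c for c in (_canon(row.get(c)) for c in r_cols
                                      if pd.notna(row.get(c))) if c)
        raw_reactants = [row.get(c) for c in r_cols if pd.notna(row.get(c))]
        if not raw_reactants:
            reason = "missing_reactant"
        elif len(reactants) != len(raw_reactants):
            reason = "unparseable_reactant"
        product = _canon(row.get(dialect["product"])) if reason is None else None
        if reason is None and product is None:
            reason = ("missing_product" if pd.isna(row.get(dialect["product"]))
                      else "unparseable_product")
        catalyst = _canon(row.get(dialect["catalyst"])) if reason is None else None
        if reason is None and catalyst is None:
            reason = ("missing_catalyst" if pd.isna(row.get(dialect["catalyst"]))
                      else "unparseable_catalyst")
        if reason is None:
            raw_reagents = [row.get(c) for c in g_cols if pd.notna(row.get(c))]
            reagents = tuple(c for c in (_canon(s) for s in raw_reagents) if c)
            if len(reagents) != len(raw_reagents):
                reason = "unparseable_reagent"
        if reason is None:
            time = row.get(dialect["time"])
            if pd.isna(time) or float(time) <= 0:
                reason = "nonpositive_time"
        if reason is None:
            target = row.get(t_col)
            if pd.isna(target):
                reason = "missing_target"
        if reason is not None:
            if drop_log is not None:
                drop_log.append({"row": int(idx), "reason": reason})
            continue
        mol = Chem.MolFromSmiles(catalyst)
        records.append(ReactionRecord(
            reactants=reactants, product=product, catalyst=catalyst,
            reagents=reagents, reaction_time=float(time),
            target=float(target), target_kind=dialect["target_kind"],
            catalyst_mw=float(Descriptors.MolWt(mol)),
        ))
    return records


def deduplicate_average(records):
    """Merge records sharing (reactants, product, catalyst, reagents, time);
    the target becomes the arithmetic mean of the group."""
    groups: dict = {}
    order = []
    for rec in records:
        k = rec.key()
        if k not in groups:
            groups[k] = []
            order.append(k)
        groups[k].append(rec)
    out = []
    for k in order:
        grp = groups[k]
        mean_t = float(np.mean([r.target for r in grp]))
        out.append(replace(grp[0], target=mean_t))
    return out


_FIELD_GETTERS = {
    "catalyst_mw": lambda r: r.catalyst_mw,
    "catalyst_atom_count": lambda r: r.catalyst_atom_count,
    "target": lambda r: r.target,
}


def iqr_filter(records, fields=("catalyst_mw", "catalyst_atom_count", "target"),
               k: float = 1.5):
    """Keep records inside [Q1 - k*IQR, Q3 + k*IQR] on every selected field.

    Quartiles use linear interpolation (numpy default). Fewer than 4
    records: no-op with a warning.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    records = list(records)
    if len(records) < 4:
        warnings.warn("fewer than 4 records: IQR filter is a no-op")
        return records
    keep = np.ones(len(records), dtype=bool)
    for f in fields:
        get = _FIELD_GETTERS[f]
        vals = np.array([get(r) for r in records], dtype=float)
        q1, q3 = np.percentile(vals, [25, 75])
        iqr = q3 - q1
        keep &= (vals >= q1 - k * iqr) & (vals <= q3 + k * iqr)
    return [r for r, ok in zip(records, keep) if ok]


def clip_target(records, low: float = 0.0, high: float = 100.0):
    """Clip yield-kind targets to [low, high]; other target kinds untouched."""
    out = []
    for rec in records:
        if rec.target_kind == "yield":
            out.append(replace(rec, target=float(min(max(rec.target, low), high))))
        else:
            out.append(rec)
    return out


def downsample_overrepresented(records, max_per_catalyst=None, seed: int = 0):
    """Cap the number of records per canonical catalyst, sampling uniformly.

    Default cap: large enough that no catalyst exceeds 1% of the input
    (never below 1).
    """
    records = list(records)
    if max_per_catalyst is None:
        max_per_catalyst = max(1, len(records) // 100)
    if max_per_catalyst < 1:
        raise ValueError("max_per_catalyst must be >= 1")
    rng = np.random.default_rng(seed)
    by_cat: dict = {}
    for i, rec in enumerate(records):
        by_cat.setdefault(rec.catalyst, []).append(i)
    keep = set()
    for idxs in by_cat.values():
        if len(idxs) <= max_per_catalyst:
            keep.update(idxs)
        else:
            keep.update(rng.choice(idxs, size=max_per_catalyst, replace=False))
    return [rec for i, rec in enumerate(records) if i in keep]


def split_dataset(records, ratios=(90, 5, 5), seed: int = 0) -> DatasetSplit:
    """Disjoint, exhaustive train/validation/test partition."""
    if sum(ratios) != 100:
        raise ValueError(f"split ratios must sum to 100, got {ratios}")
    records = list(records)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(records))
    n = len(records)
    n_train = int(round(n * ratios[0] / 100))
    n_val = int(round(n * ratios[1] / 100))
    n_val = min(n_val, n - n_train)
    idx_train = perm[:n_train]
    idx_val = perm[n_train:n_train + n_val]
    idx_test = perm[n_train + n_val:]
    pick = lambda idx: [records[i] for i in idx]
    return DatasetSplit(pick(idx_train), pick(idx_val), pick(idx_test),
                        ratios=tuple(ratios), seed=seed)


def curate(records, iqr_fields=("catalyst_mw", "catalyst_atom_count", "target"),
           iqr_k: float = 1.5, clip=(0.0, 100.0), max_per_catalyst=None,
           seed: int = 0):
    """Full pipeline: dedup -> IQR -> clip -> downsample (normalization is
    done at parse time). Returns the curated record list."""
    out = deduplicate_average(records)
    out = iqr_filter(out, fields=iqr_fields, k=iqr_k)
    out = clip_target(out, *clip)
    out = downsample_overrepresented(out, max_per_catalyst=max_per_catalyst,
                                     seed=seed)
    return out
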