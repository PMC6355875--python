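"""Core records and file I/O for molecules, descriptor tables, and filter models.

The in-memory containers used throughout the package live here:

* :class:`MoleculeRecord` — one compound with an id, a canonical SMILES, an
  optional named descriptor vector and an activity label.
* :class:`DescriptorTable` — a molecule × descriptor matrix (pandas-backed)
  with an aligned label vector; the unit of data every learning and
  screening operation consumes.
* :class:`ConfusionCounts` — TP/FP/TN/FN with derived rates.
* :class:`RangeFilter` / :class:`ISEModel` / :class:`ISEConfig` — a learned
  conjunction of descriptor ranges, the assembled multi-filter model, and
  the training configuration snapshot.

File formats: SMILES (one per line, optional id after whitespace), SDF
V2000, CSV descriptor tables (first column id, header row of descriptor
names, optional ``label`` column), and a versioned JSON model format.
Structure parsing and canonicalization are delegated to RDKit.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

#: Allowed activity labels.
LABELS = ("active", "inactive", "unknown")

#: Current model file format version.
MODEL_FORMAT_VERSION = 1

_LABEL_ALIASES = {
    "active": "active", "1": "active", "a": "active", "true": "active",
    "inactive": "inactive", "0": "inactive", "i": "inactive", "false": "inactive",
    "unknown": "unknown", "": "unknown", "nan": "unknown",
}


class ModelFormatError(ValueError):
    """Raised when a model file is truncated, malformed, or from an
    incompatible format version."""


def canonical_smiles(smiles: str) -> str:
    """Return RDKit's canonical SMILES, or raise ``ValueError`` if unparsable."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def normalize_label(label: object) -> str:
    key = str(label).strip().lower()
    if key not in _LABEL_ALIASES:
        raise ValueError(f"unrecognized activity label {label!r}; expected one of {LABELS}")
    return _LABEL_ALIASES[key]


@dataclass
class MoleculeRecord:
    """One compound: id, canonical SMILES, named descriptors, activity label."""

    id: str
    smiles: str | None = None
    descriptors: dict[str, float] = field(default_factory=dict)
    label: str = "unknown"

    def __post_init__(self) -> None:
        self.label = normalize_label(self.label)

    def mol(self) -> Chem.Mol:
        if self.smiles is None:
            raise ValueError(f"molecule {self.id} has no structure")
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:  # pragma: no cover - canonical SMILES always reparse
            raise ValueError(f"molecule {self.id}: stored SMILES no longer parses")
        return m


@dataclass
class ReadReport:
    """Summary of a molecule-file read: counts and per-record failures."""

    n_read: int = 0
    n_failed: int = 0
    failures: list[str] = field(default_factory=list)

    def warn_if_failures(self) -> None:
        if self.n_failed:
            logger.warning("%d of %d entries failed to parse: %s",
                           self.n_failed, self.n_read + self.n_failed,
                           "; ".join(self.failures[:10]))


class DescriptorTable:
    """Molecule × descriptor matrix with aligned activity labels.

    Backed by a ``pandas.DataFrame`` (index = molecule ids, columns =
    descriptor names, float values) and a label ``Series`` drawn from
    :data:`LABELS`.
    """

    def __init__(self, values: pd.DataFrame, labels: pd.Series | None = None):
        if values.index.has_duplicates:
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate molecule ids: {dupes[:5]}")
        if labels is None:
            labels = pd.Series("unknown", index=values.index)
        if not labels.index.equals(values.index):
            labels = labels.reindex(values.index)
        labels = labels.map(normalize_label)
        self.values = values.astype(float)
        self.labels = labels

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DescriptorTable):
            return NotImplemented
        return self.values.equals(other.values) and self.labels.equals(other.labels)

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_actives(self) -> int:
        return int((self.labels == "active").sum())

    @property
    def n_inactives(self) -> int:
        return int((self.labels == "inactive").sum())

    def active_mask(self) -> np.ndarray:
        return (self.labels == "active").to_numpy()

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset(self, ids: Sequence[str]) -> "DescriptorTable":
        return DescriptorTable(self.values.loc[list(ids)], self.labels.loc[list(ids)])

    def drop_incomplete(self) -> "DescriptorTable":
        """Drop molecules with any NaN descriptor, with a warning."""
        bad = self.values.isna().any(axis=1)
        if bad.any():
            logger.warning("dropping %d molecules with undefined descriptors", int(bad.sum()))
            return DescriptorTable(self.values.loc[~bad], self.labels.loc[~bad])
        return self

    def validate(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("descriptor table contains NaN; call drop_incomplete() first")

    # -- CSV round trip ----------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(len(out.columns), "label", self.labels)
        out.to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DescriptorTable":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        if "label" in df.columns:
            labels = df.pop("label").astype(str)
        else:
            labels = None
        return cls(df, labels)

    @classmethod
    def from_records(cls, records: Iterable[MoleculeRecord]) -> "DescriptorTable":
        records = list(records)
        if not records:
            raise ValueError("no records")
        names = list(records[0].descriptors)
        for r in records:
            if list(r.descriptors) != names:
                raise ValueError(f"molecule {r.id}: descriptor names differ across the dataset")
        values = pd.DataFrame([r.descriptors for r in records],
                              index=[r.id for r in records], columns=names)
        labels = pd.Series([r.label for r in records], index=values.index)
        return cls(values, labels)


# ---------------------------------------------------------------------------
# confusion counts / filters / model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN of a binary classifier on a labeled set."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_actives(self) -> int:
        return self.tp + self.fn

    @property
    def n_inactives(self) -> int:
        return self.fp + self.tn

    @property
    def tpr(self) -> float:
        return self.tp / self.n_actives if self.n_actives else math.nan

    @property
    def fpr(self) -> float:
        return self.fp / self.n_inactives if self.n_inactives else math.nan


@dataclass(frozen=True)
class RangeClause:
    """One closed interval constraint ``low <= value <= high`` on a descriptor."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.high):
            raise ValueError(f"clause on {self.name}: low {self.low} > high {self.high}")


@dataclass(frozen=True)
class RangeFilter:
    """A conjunction of 4–5 descriptor range clauses plus its training score.

    A molecule *passes* the filter iff every clause is satisfied (closed
    intervals: boundary values pass).
    """

    clauses: tuple[RangeClause, ...]
    counts: ConfusionCounts | None = None
    mcc: float | None = None

    def __post_init__(self) -> None:
        names = [c.name for c in self.clauses]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate descriptors within a filter: {names}")

    @property
    def descriptor_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.clauses)


@dataclass
class ISEConfig:
    """Training configuration for the iterative stochastic elimination loop.

    Parameters
    ----------
    k : clauses per filter (the paper's models use 4, occasionally 5).
    filters_per_iteration : random filters sampled and scored per iteration.
    elimination_fraction : fraction of the descriptor pool removed each
        iteration (those with the worst mean filter MCC).
    exhaustive_threshold : once C(|pool|, k) falls to this many k-subsets,
        sampling stops and every remaining subset is enumerated.
    band_fraction : the final model keeps filters with
        MCC >= (1 - band_fraction) * max MCC ("about 20% less than the top").
    dedup_overlap : two filters whose per-molecule pass/fail vectors agree on
        more than this fraction are considered duplicates; the lower-MCC one
        is dropped.
    quantile_grid : number of equal-probability quantile steps of the
        actives' values used as candidate range bounds (10 = deciles).
    seed : master seed for all randomness.
    """

    k: int = 4
    filters_per_iteration: int = 1000
    elimination_fraction: float = 0.2
    exhaustive_threshold: int = 100_000
    band_fraction: float = 0.20
    dedup_overlap: float = 0.99
    quantile_grid: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for name in ("elimination_fraction", "band_fraction", "dedup_overlap"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.exhaustive_threshold < 1:
            raise ValueError("exhaustive_threshold must be positive")
        if self.filters_per_iteration < 1:
            raise ValueError("filters_per_iteration must be positive")
        if self.quantile_grid < 1:
            raise ValueError("quantile_grid must be >= 1")

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "filters_per_iteration": self.filters_per_iteration,
            "elimination_fraction": self.elimination_fraction,
            "exhaustive_threshold": self.exhaustive_threshold,
            "band_fraction": self.band_fraction,
            "dedup_overlap": self.dedup_overlap,
            "quantile_grid": self.quantile_grid,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ISEConfig":
        return cls(**{k: d[k] for k in cls().to_dict() if k in d})


@dataclass
class ISEModel:
    """A deduplicated, MCC-sorted set of range filters with MBI weights.

    ``weights[i]`` is the i-th filter's TPR/FPR ratio on the training set
    (FPR floored at ``1 / (2 * n_inactives)`` when FP = 0), the per-filter
    increment/decrement of the molecular bioactivity index.
    """

    filters: list[RangeFilter]
    n_actives: int
    n_inactives: int
    weights: list[float]
    config: ISEConfig = field(default_factory=ISEConfig)

    def __post_init__(self) -> None:
        if len(self.filters) != len(self.weights):
            raise ValueError("one weight per filter required")

    @property
    def descriptor_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.filters:
            for c in f.clauses:
                seen.setdefault(c.name, None)
        return list(seen)

    def validate(self) -> None:
        if not self.filters:
            raise ValueError("model has no filters")
        for f in self.filters:
            if f.counts is None or f.mcc is None:
                raise ValueError("every model filter must carry counts and MCC")
            if f.counts.n_actives != self.n_actives or f.counts.n_inactives != self.n_inactives:
                raise ValueError("filter counts inconsistent with model class sizes")


# ---------------------------------------------------------------------------
# molecule file I/O
# ---------------------------------------------------------------------------

def _auto_id(i: int) -> str:
    return f"M{i + 1:06d}"


def read_molecules(path: str | Path, format: str | None = None,
                   ) -> tuple[list[MoleculeRecord], ReadReport]:
    """Read molecules from a SMILES, SDF, or descriptor-CSV file.

    Invalid structures are reported in the returned :class:`ReadReport`
    (and logged), never silently dropped. Ids missing from the input are
    generated as sequential ``M000001``-style ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".smi": "smiles", ".smiles": "smiles", ".sdf": "sdf",
                  ".csv": "csv"}.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format from {path.name}; pass format=")
    if format not in ("smiles", "sdf", "csv"):
        raise ValueError(f"unknown format {format!r}")

    report = ReadReport()
    records: list[MoleculeRecord] = []
    seen_ids: set[str] = set()

    def add(mol_id: str | None, smiles: str, label: str = "unknown",
            descriptors: dict[str, float] | None = None) -> None:
        try:
            canon = canonical_smiles(smiles)
        except ValueError:
            report.n_failed += 1
            report.failures.append(f"entry {report.n_read + report.n_failed}: bad structure {smiles!r}")
            return
        if mol_id is None:
            mol_id = _auto_id(len(records))
        if mol_id in seen_ids:
            raise ValueError(f"duplicate molecule id {mol_id!r} in {path.name}")
        seen_ids.add(mol_id)
        records.append(MoleculeRecord(mol_id, canon, descriptors or {}, label))
        report.n_read += 1

    RDLogger.DisableLog("rdApp.error")
    try:
        if format == "smiles":
            for line in path.read_text().splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                add(parts[1].strip() if len(parts) > 1 else None, parts[0])
        elif format == "sdf":
            supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
            for i, mol in enumerate(supplier):
                if mol is None:
                    report.n_failed += 1
                    report.failures.append(f"SDF record {i + 1}: unparsable structure")
                    continue
                name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
                label = mol.GetProp("label") if mol.HasProp("label") else "unknown"
                add(name or None, Chem.MolToSmiles(mol), label)
        else:  # csv descriptor table; structures optional via a "smiles" column
            table = pd.read_csv(path, index_col=0)
            table.index = table.index.astype(str)
            labels = table.pop("label").astype(str) if "label" in table.columns else None
            smiles_col = table.pop("smiles") if "smiles" in table.columns else None
            for i, mol_id in enumerate(table.index):
                desc = {k: float(v) for k, v in table.loc[mol_id].items()}
                label = labels.loc[mol_id] if labels is not None else "unknown"
                if smiles_col is not None:
                    add(mol_id, smiles_col.loc[mol_id], label, desc)
                else:
                    if mol_id in seen_ids:
                        raise ValueError(f"duplicate molecule id {mol_id!r} in {path.name}")
                    seen_ids.add(mol_id)
                    records.append(MoleculeRecord(mol_id, None, desc, label))
                    report.n_read += 1
    finally:
        RDLogger.EnableLog("rdApp.error")

    report.warn_if_failures()
    return records, report


def write_smiles(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.smiles} {r.id}\n")


def write_sdf(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for r in records:
            mol = r.mol()
            mol.SetProp("_Name", r.id)
            mol.SetProp("label", r.label)
            writer.write(mol)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# model serialization (versioned JSON)
# ---------------------------------------------------------------------------

def save_model(model: ISEModel, path: str | Path) -> None:
    """Serialize a validated model to the versioned JSON format.

    Confusion counts are stored as integers and bounds as JSON decimals;
    MCC and weights are re-derived on load so the file carries no float
    drift.
    """
    model.validate()
    payload = {
        "format": "ise-screen-model",
        "version": MODEL_FORMAT_VERSION,
        "n_actives": model.n_actives,
        "n_inactives": model.n_inactives,
        "config": model.config.to_dict(),
        "filters": [
            {
                "clauses": [{"name": c.name, "low": c.low, "high": c.high}
                            for c in f.clauses],
                "counts": {"tp": f.counts.tp, "fp": f.counts.fp,
                           "tn": f.counts.tn, "fn": f.counts.fn},
            }
            for f in model.filters
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> ISEModel:
    """Load a model saved by :func:`save_model`; inverse up to float re-derivation."""
    from . import ise_core  # local import: MCC/weight re-derivation
    from . import screening

    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != "ise-screen-model":
        raise ModelFormatError(f"{path} is not an ise-screen model file")
    if payload.get("version") != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"model format version {payload.get('version')} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})")
    for key in ("n_actives", "n_inactives", "filters"):
        if key not in payload:
            raise ModelFormatError(f"model file missing required field {key!r}")

    n_act, n_inact = int(payload["n_actives"]), int(payload["n_inactives"])
    filters: list[RangeFilter] = []
    weights: list[float] = []
    for entry in payload["filters"]:
        try:
            clauses = tuple(RangeClause(c["name"], float(c["low"]), float(c["high"]))
                            for c in entry["clauses"])
            cnt = entry["counts"]
            counts = ConfusionCounts(int(cnt["tp"]), int(cnt["fp"]),
                                     int(cnt["tn"]), int(cnt["fn"]))
        except (KeyError, TypeError) as exc:
            raise ModelFormatError(f"malformed filter entry in {path}: {exc}") from exc
        if counts.n_actives != n_act or counts.n_inactives != n_inact:
            raise ModelFormatError(
                f"filter counts in {path} inconsistent with stated class sizes")
        filters.append(RangeFilter(clauses, counts, ise_core.balanced_mcc(counts)))
        weights.append(screening.filter_weight(counts))

    model = ISEModel(filters, n_act, n_inact, weights,
                     ISEConfig.from_dict(payload.get("config", {})))
    model.validate()
    return model
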