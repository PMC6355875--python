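"""MBI scoring, library ranking, and screening evaluation.

The molecular bioactivity index (MBI) turns a set of binary pass/fail
filters into a quantitative ranking score. Each filter i carries a weight
``w_i``; a molecule that passes the filter gains ``+w_i`` and one that
fails it loses ``-w_i``, so

    MBI = Σ_{passed} w_i − Σ_{failed} w_i.

By default ``w_i = TPR_i / FPR_i`` on the training set — the rate form of
the filter's true-positive/false-positive trade-off, which keeps weights
invariant to training class sizes. When a filter accepted no training
inactive at all (FP = 0) its FPR is floored at ``1 / (2 · n_inactives)``.
A raw-count mode (``w_i = TP_i / FP_i``) is available for comparison, as
is an optional divide-by-filter-count normalization of the score.

Evaluation reduces a scored, labeled library to confusion counts per MBI
border (positives = molecules with score >= border), from which the
balanced MCC, the enrichment factor EF = (TP/nA)/(FP/nI), a rank-based
ROC AUC, and the cumulative active-capture curve are derived.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .datamodel_io import ConfusionCounts, DescriptorTable, ISEModel
from .ise_core import balanced_mcc

logger = logging.getLogger(__name__)


def filter_weight(counts: ConfusionCounts, raw_counts: bool = False,
                  ) -> float:
    """Per-filter MBI weight.

    Rate form (default): TPR / FPR with FPR floored at 1/(2·n_inactives)
    when FP = 0. Raw-count form: TP / FP with the same halving floor
    (FP = 0 counts as 1/2).
    """
    if counts.n_actives == 0 or counts.n_inactives == 0:
        raise ValueError("filter weight requires both classes in the counts")
    if raw_counts:
        return counts.tp / (counts.fp if counts.fp > 0 else 0.5)
    fpr = counts.fpr if counts.fp > 0 else 1.0 / (2.0 * counts.n_inactives)
    return counts.tpr / fpr


@dataclass
class MBIResult:
    """MBI score of one molecule plus its per-filter pass vector."""

    molecule_id: str
    mbi: float
    passes: np.ndarray  # bool, one entry per model filter


def mbi_score(model: ISEModel, v, molecule_id: str = "",
              normalize: bool = False) -> MBIResult:
    """Score one descriptor vector against every model filter."""
    passes = np.empty(len(model.filters), dtype=bool)
    for i, f in enumerate(model.filters):
        try:
            passes[i] = all(c.low <= float(v[c.name]) <= c.high for c in f.clauses)
        except KeyError as exc:
            raise ValueError(f"descriptor vector lacks {exc.args[0]!r} "
                             f"used by the model") from exc
    w = np.asarray(model.weights)
    score = float(np.where(passes, w, -w).sum())
    if normalize:
        score /= len(model.filters)
    return MBIResult(molecule_id, score, passes)


def score_table(model: ISEModel, table: DescriptorTable,
                normalize: bool = False) -> pd.DataFrame:
    """Vectorized MBI scoring of a whole descriptor table.

    Returns a DataFrame indexed by molecule id with columns ``mbi``,
    ``n_passed`` and ``label``.
    """
    missing = [n for n in model.descriptor_names if n not in table.descriptor_names]
    if missing:
        raise ValueError(f"library table lacks model descriptors {missing}")
    n = len(table)
    w = np.asarray(model.weights)
    pass_mat = np.empty((n, len(model.filters)), dtype=bool)
    for i, f in enumerate(model.filters):
        col = np.ones(n, dtype=bool)
        for c in f.clauses:
            vals = table.values[c.name].to_numpy(dtype=float)
            col &= (vals >= c.low) & (vals <= c.high)
        pass_mat[:, i] = col
    scores = np.where(pass_mat, w, -w).sum(axis=1)
    if normalize:
        scores = scores / len(model.filters)
    return pd.DataFrame({"mbi": scores,
                         "n_passed": pass_mat.sum(axis=1),
                         "label": table.labels.to_numpy()},
                        index=table.values.index)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def enrichment_factor(c: ConfusionCounts) -> float:
    """EF = (TP/nA) / (FP/nI); ``inf`` when FP = 0 (reported as undefined)."""
    if c.n_actives == 0 or c.n_inactives == 0:
        raise ValueError("enrichment factor requires both classes present")
    if c.fp == 0:
        return math.inf
    return c.tpr / c.fpr


def hit_rate_ef(hits: int, tested: int, base_rate: float) -> float:
    """Prospective enrichment: observed hit rate over an assumed base rate."""
    if tested <= 0:
        raise ValueError("tested must be positive")
    if base_rate <= 0:
        raise ValueError("base_rate must be positive")
    return (hits / tested) / base_rate


def confusion_at_border(scores: np.ndarray, labels: np.ndarray,
                        border: float) -> ConfusionCounts:
    """Counts with positives defined as score >= border (closed)."""
    act = labels == "active"
    pos = scores >= border
    tp = int((pos & act).sum())
    fp = int((pos & ~act).sum())
    return ConfusionCounts(tp, fp, int((~act).sum()) - fp, int(act.sum()) - tp)


def threshold_report(scores: Sequence[float], labels: Sequence[str],
                     borders: Sequence[float]) -> pd.DataFrame:
    """Confusion counts and derived metrics per MBI border.

    One row per border with TN/FN/TP/FP, ``enrichment`` (NaN marks the
    undefined FP = 0 case, rendered as an em-dash in text output) and the
    balanced ``mcc``. With an empty class the metrics are emitted as NaN
    and a warning is logged.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    rows = []
    for b in borders:
        c = confusion_at_border(scores, labels, b)
        if c.n_actives == 0 or c.n_inactives == 0:
            logger.warning("border %+g: one class empty; metrics undefined", b)
            ef = mcc = math.nan
        else:
            ef = enrichment_factor(c)
            mcc = balanced_mcc(c)
        rows.append({"border": b, "tn": c.tn, "fn": c.fn, "tp": c.tp, "fp": c.fp,
                     "enrichment": (math.nan if math.isinf(ef) else ef),
                     "mcc": mcc})
    return pd.DataFrame(rows).set_index("border")


def format_threshold_report(report: pd.DataFrame) -> str:
    """Text rendering with the undefined-enrichment em-dash convention."""
    out = report.copy()
    out["enrichment"] = [("—" if (isinstance(v, float) and math.isnan(v)) else f"{v:.1f}")
                         for v in out["enrichment"]]
    out["mcc"] = [f"{v:.3f}" for v in out["mcc"]]
    return out.to_string()


@dataclass
class RocResult:
    """Rank-based AUC plus the cumulative active-capture curve."""

    auc: float
    top_fraction: np.ndarray      # screened fraction of the library
    captured_fraction: np.ndarray  # fraction of actives recovered


def roc_and_enrichment(scores: Sequence[float], labels: Sequence[str],
                       ) -> RocResult:
    """Rank-based ROC AUC (ties averaged) and active-capture curve."""
    scores = np.asarray(scores, dtype=float)
    y = (np.asarray(labels) == "active").astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("ROC requires both classes present")
    auc = float(roc_auc_score(y, scores))
    order = np.argsort(-scores, kind="stable")
    captured = np.cumsum(y[order]) / y.sum()
    top = np.arange(1, len(y) + 1) / len(y)
    return RocResult(auc, top, captured)
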