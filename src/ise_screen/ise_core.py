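"""Iterative stochastic elimination: learning descriptor-range filter models.

The learner searches the combinatorial space of *filters* — conjunctions
of ``k`` (default 4) closed numeric ranges over named molecular
descriptors. A molecule passes a filter iff every descriptor value lies
inside its range. Each filter is scored by the class-balanced Matthews
correlation coefficient of its pass/fail split of a labeled training set.

Because the space of k-subsets of a large descriptor pool is too big to
enumerate, the search alternates two moves:

1. *Stochastic sampling*: many filters are drawn at random (random
   descriptor subsets, range bounds drawn from the actives' empirical
   quantile grid) and scored.
2. *Elimination*: descriptors that consistently appear in the
   worst-scoring filters (lowest mean MCC) are removed from the pool.

Once the surviving pool is small enough that every k-subset can be
enumerated, an exhaustive phase instantiates each subset with its
best-scoring range assignment over the quantile grid. Near-duplicate
filters (pass/fail vectors agreeing on >99% of molecules) are collapsed,
and the filters within ~20% of the top MCC constitute the final model.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Mapping, Sequence

import numpy as np

from .datamodel_io import (ConfusionCounts, DescriptorTable, ISEConfig,
                           ISEModel, RangeClause, RangeFilter)

logger = logging.getLogger(__name__)

_EPS = 1e-12


class NoDiscriminatingFilterError(ValueError):
    """Raised when no sampled or enumerated filter separates the classes."""


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def balanced_mcc(c: ConfusionCounts) -> float:
    """Class-balanced Matthews correlation coefficient.

    The inactive-class counts are rescaled by ``s = n_actives /
    n_inactives`` (FP' = s·FP, TN' = s·TN) before applying the standard
    MCC formula, which removes the sensitivity of plain MCC to class
    imbalance. Equivalent to standard MCC on a dataset in which each
    active row is replicated ``n_inactives`` times and each inactive row
    ``n_actives`` times. A zero factor in the denominator yields 0 by
    convention.
    """
    n_act, n_inact = c.n_actives, c.n_inactives
    if n_act == 0 or n_inact == 0:
        raise ValueError("balanced MCC requires both classes present")
    s = n_act / n_inact
    fp, tn = c.fp * s, c.tn * s
    num = c.tp * tn - fp * c.fn
    den_sq = (c.tp + fp) * (c.tp + c.fn) * (tn + fp) * (tn + c.fn)
    if den_sq <= 0.0:
        return 0.0
    return num / math.sqrt(den_sq)


def _balanced_mcc_arrays(tp: np.ndarray, fp: np.ndarray, n_act: int,
                         n_inact: int) -> np.ndarray:
    """Vectorized balanced MCC from TP/FP arrays (FN/TN implied)."""
    s = n_act / n_inact
    fn = n_act - tp
    fp_s = fp * s
    tn_s = (n_inact - fp) * s
    num = tp * tn_s - fp_s * fn
    den_sq = (tp + fp_s) * (tp + fn) * (tn_s + fp_s) * (tn_s + fn)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den_sq > 0.0, num / np.sqrt(np.maximum(den_sq, _EPS)), 0.0)
    return out


def filter_passes(f: RangeFilter, v: Mapping[str, float]) -> bool:
    """True iff every clause satisfies ``low <= value <= high`` (closed)."""
    try:
        return all(c.low <= float(v[c.name]) <= c.high for c in f.clauses)
    except KeyError as exc:
        raise ValueError(f"descriptor vector lacks {exc.args[0]!r} "
                         f"required by the filter") from exc


def score_filter(f: RangeFilter, table: DescriptorTable) -> RangeFilter:
    """Return a copy of ``f`` carrying confusion counts and balanced MCC
    measured on ``table``."""
    counts = _count_filter(f, table)
    return RangeFilter(f.clauses, counts, balanced_mcc(counts))


def _count_filter(f: RangeFilter, table: DescriptorTable) -> ConfusionCounts:
    missing = [c.name for c in f.clauses if c.name not in table.descriptor_names]
    if missing:
        raise ValueError(f"dataset lacks descriptors {missing} required by the filter")
    passes = np.ones(len(table), dtype=bool)
    for c in f.clauses:
        vals = table.values[c.name].to_numpy(dtype=float)
        passes &= (vals >= c.low) & (vals <= c.high)
    act = table.active_mask()
    tp = int((passes & act).sum())
    fp = int((passes & ~act).sum())
    return ConfusionCounts(tp, fp, table.n_inactives - fp, table.n_actives - tp)


# ---------------------------------------------------------------------------
# bit-packed scoring context
# ---------------------------------------------------------------------------

class _ScoringContext:
    """Precomputed pass masks for every (descriptor, quantile-range) clause.

    Pass vectors are packed 8 molecules per byte so that scoring a filter
    is a few byte-wise ANDs plus popcounts. For each descriptor the
    candidate clause bounds are all ordered pairs from the actives'
    quantile grid, listed widest-first so that ties in MCC resolve toward
    the least restrictive clause.
    """

    def __init__(self, table: DescriptorTable, quantile_grid: int):
        table.validate()
        self.n = len(table)
        self.n_act = table.n_actives
        self.n_inact = table.n_inactives
        if self.n_act == 0 or self.n_inact == 0:
            raise ValueError("training set must contain both actives and inactives")
        act = table.active_mask()
        self.act_packed = np.packbits(act)
        self.inact_packed = np.packbits(~act)

        grid_q = np.linspace(0.0, 1.0, quantile_grid + 1)
        # candidate (low, high) index pairs over the grid, widest range first
        g = quantile_grid + 1
        pairs = sorted(((i, j) for i in range(g) for j in range(i, g)),
                       key=lambda p: (-(p[1] - p[0]), p[0]))
        self.pair_index = pairs
        self.widest = 0  # by construction pairs[0] == (0, g-1)

        X = table.matrix()
        active_rows = X[act]
        self.names = list(table.descriptor_names)
        self.bounds: dict[str, list[tuple[float, float]]] = {}
        self.masks: dict[str, np.ndarray] = {}
        for col, name in enumerate(self.names):
            q = np.quantile(active_rows[:, col], grid_q)
            vals = X[:, col]
            bnds, rows = [], []
            for i, j in pairs:
                low, high = float(q[i]), float(q[j])
                bnds.append((low, high))
                rows.append(np.packbits((vals >= low) & (vals <= high)))
            self.bounds[name] = bnds
            self.masks[name] = np.stack(rows)

    # -- counting ----------------------------------------------------------
    def counts_of_mask(self, mask: np.ndarray) -> ConfusionCounts:
        tp = int(np.bitwise_count(mask & self.act_packed).sum())
        fp = int(np.bitwise_count(mask & self.inact_packed).sum())
        return ConfusionCounts(tp, fp, self.n_inact - fp, self.n_act - tp)

    def filter_mask(self, names: Sequence[str], sel: Sequence[int]) -> np.ndarray:
        mask = self.masks[names[0]][sel[0]].copy()
        for name, s in zip(names[1:], sel[1:]):
            mask &= self.masks[name][s]
        return mask

    def make_filter(self, names: Sequence[str], sel: Sequence[int]) -> RangeFilter:
        clauses = tuple(RangeClause(name, *self.bounds[name][s])
                        for name, s in zip(names, sel))
        counts = self.counts_of_mask(self.filter_mask(names, sel))
        return RangeFilter(clauses, counts, balanced_mcc(counts))

    def best_clause(self, name: str, base: np.ndarray | None) -> tuple[int, float]:
        """Best clause index for ``name`` given the AND of the other
        clauses; ties go to the widest range."""
        cand = self.masks[name] if base is None else self.masks[name] & base
        tp = np.bitwise_count(cand & self.act_packed).sum(axis=1).astype(float)
        fp = np.bitwise_count(cand & self.inact_packed).sum(axis=1).astype(float)
        scores = _balanced_mcc_arrays(tp, fp, self.n_act, self.n_inact)
        best = int(np.argmax(scores))  # first max == widest among ties
        return best, float(scores[best])

    def optimize_subset(self, names: Sequence[str], max_sweeps: int = 4,
                        ) -> RangeFilter:
        """Coordinate-ascent best range assignment for one descriptor subset.

        Clauses start at the widest grid range and are refined one
        descriptor at a time until no strict improvement remains.
        """
        k = len(names)
        sel = [self.widest] * k
        cur = -2.0
        for _ in range(max_sweeps):
            improved = False
            for p in range(k):
                others = [self.masks[names[i]][sel[i]] for i in range(k) if i != p]
                base = None
                if others:
                    base = others[0].copy()
                    for m in others[1:]:
                        base &= m
                best, score = self.best_clause(names[p], base)
                if score > cur + _EPS:
                    sel[p] = best
                    cur = score
                    improved = True
            if not improved:
                break
        return self.make_filter(names, sel)


# ---------------------------------------------------------------------------
# the ISE moves
# ---------------------------------------------------------------------------

def sample_filter(pool: Sequence[str], dataset: DescriptorTable, cfg: ISEConfig,
                  rng: np.random.Generator,
                  _ctx: _ScoringContext | None = None) -> RangeFilter:
    """Draw one random scored filter.

    ``k`` distinct descriptors are drawn uniformly from the pool; each
    clause's (low, high) is an ordered pair of the actives' empirical
    quantiles (decile grid by default). A constant descriptor collapses
    its clause to the single observed value.
    """
    if len(pool) < cfg.k:
        raise ValueError(f"pool of {len(pool)} descriptors cannot yield k={cfg.k} clauses")
    ctx = _ctx or _ScoringContext(dataset, cfg.quantile_grid)
    names = [pool[i] for i in rng.choice(len(pool), size=cfg.k, replace=False)]
    return _random_filter(ctx, names, cfg, rng)


def _random_filter(ctx: _ScoringContext, names: Sequence[str], cfg: ISEConfig,
                   rng: np.random.Generator) -> RangeFilter:
    g = cfg.quantile_grid + 1
    sel = []
    for name in names:
        i, j = sorted(rng.choice(g, size=2, replace=False))
        sel.append(ctx.pair_index.index((int(i), int(j))))
    return ctx.make_filter(names, sel)


def eliminate_descriptors(scored_filters: Sequence[RangeFilter],
                          pool: Sequence[str], cfg: ISEConfig) -> list[str]:
    """Remove the ``elimination_fraction`` of descriptors whose containing
    filters have the lowest mean MCC (ties broken by name order).

    The pool strictly shrinks but never drops below ``k``.
    """
    by_desc: dict[str, list[float]] = {name: [] for name in pool}
    for f in scored_filters:
        if f.mcc is None:
            raise ValueError("filters must be scored before elimination")
        for name in f.descriptor_names:
            if name in by_desc:
                by_desc[name].append(f.mcc)
    uncovered = [name for name, v in by_desc.items() if not v]
    if uncovered:
        raise ValueError(f"descriptors with no sampled filter: {uncovered[:5]}; "
                         "resample before eliminating")
    n_remove = max(1, int(cfg.elimination_fraction * len(pool)))
    n_remove = min(n_remove, len(pool) - cfg.k)
    if n_remove <= 0:
        return list(pool)
    ranked = sorted(pool, key=lambda name: (float(np.mean(by_desc[name])), name))
    doomed = set(ranked[:n_remove])
    logger.debug("eliminating %d descriptors: %s", n_remove, sorted(doomed))
    return [name for name in pool if name not in doomed]


def exhaustive_phase(pool: Sequence[str], dataset: DescriptorTable,
                     cfg: ISEConfig,
                     _ctx: _ScoringContext | None = None) -> list[RangeFilter]:
    """Instantiate and score every k-subset of the pool.

    Each subset gets its best-scoring range assignment over the actives'
    quantile grid (coordinate ascent from the widest ranges).
    """
    n_subsets = math.comb(len(pool), cfg.k)
    if n_subsets > cfg.exhaustive_threshold:
        raise ValueError(f"{n_subsets} subsets exceed the exhaustive threshold "
                         f"{cfg.exhaustive_threshold}")
    if len(pool) < cfg.k:
        raise ValueError("pool smaller than k")
    ctx = _ctx or _ScoringContext(dataset, cfg.quantile_grid)
    return [ctx.optimize_subset(names)
            for names in itertools.combinations(sorted(pool), cfg.k)]


def dedup_filters(filters: Sequence[RangeFilter], overlap: float = 0.99,
                  dataset: DescriptorTable | None = None,
                  _ctx: _ScoringContext | None = None,
                  _masks: Sequence[np.ndarray] | None = None) -> list[RangeFilter]:
    """Collapse filters whose pass/fail vectors agree on > ``overlap`` of
    molecules, keeping the higher-MCC member; output sorted by MCC
    descending (name order breaks exact ties).
    """
    if not filters:
        return []
    if _masks is None:
        if dataset is None:
            raise ValueError("dataset required to compare filter pass vectors")
        passes = []
        act = None
        for f in filters:
            v = np.ones(len(dataset), dtype=bool)
            for c in f.clauses:
                vals = dataset.values[c.name].to_numpy(dtype=float)
                v &= (vals >= c.low) & (vals <= c.high)
            passes.append(np.packbits(v))
        _masks = passes
        n = len(dataset)
    else:
        n = _ctx.n if _ctx is not None else len(dataset)

    order = sorted(range(len(filters)),
                   key=lambda i: (-(filters[i].mcc if filters[i].mcc is not None else -2),
                                  filters[i].descriptor_names))
    max_disagree = (1.0 - overlap) * n
    kept_idx: list[int] = []
    kept_exact: dict[bytes, int] = {}
    kept_masks: list[np.ndarray] = []
    for i in order:
        key = _masks[i].tobytes()
        if key in kept_exact:
            continue
        dup = False
        for m in kept_masks:
            if int(np.bitwise_count(m ^ _masks[i]).sum()) < max_disagree:
                dup = True
                break
        if dup:
            continue
        kept_exact[key] = i
        kept_idx.append(i)
        kept_masks.append(_masks[i])
    return [filters[i] for i in kept_idx]


# ---------------------------------------------------------------------------
# the full loop
# ---------------------------------------------------------------------------

def _sample_batch(ctx: _ScoringContext, pool: list[str], cfg: ISEConfig,
                  rng: np.random.Generator) -> list[RangeFilter]:
    """One iteration's random filters, guaranteeing every pool descriptor
    appears in at least one filter."""
    batch = []
    covered: set[str] = set()
    for _ in range(cfg.filters_per_iteration):
        names = [pool[i] for i in rng.choice(len(pool), size=cfg.k, replace=False)]
        f = _random_filter(ctx, names, cfg, rng)
        covered.update(f.descriptor_names)
        batch.append(f)
    for name in pool:
        if name not in covered:
            others = [p for p in pool if p != name]
            extra = [name] + [others[i] for i in
                              rng.choice(len(others), size=cfg.k - 1, replace=False)]
            batch.append(_random_filter(ctx, extra, cfg, rng))
    return batch


def build_model(dataset: DescriptorTable, cfg: ISEConfig | None = None) -> ISEModel:
    """Run the full ISE loop and assemble the final filter model.

    sample → score → eliminate iterations run until every k-subset of the
    surviving descriptor pool can be enumerated; the exhaustive phase then
    scores all of them, near-duplicates are collapsed, and filters within
    ``band_fraction`` of the top MCC are retained. Fully reproducible
    under ``cfg.seed``.
    """
    from .screening import filter_weight

    cfg = cfg or ISEConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ctx = _ScoringContext(dataset, cfg.quantile_grid)
    pool = sorted(dataset.descriptor_names)
    if len(pool) < cfg.k:
        raise ValueError(f"{len(pool)} descriptors cannot support k={cfg.k} filters")

    iteration = 0
    while math.comb(len(pool), cfg.k) > cfg.exhaustive_threshold:
        iteration += 1
        batch = _sample_batch(ctx, pool, cfg, rng)
        best = max(f.mcc for f in batch)
        new_pool = eliminate_descriptors(batch, pool, cfg)
        logger.info("iteration %d: pool %d -> %d, best sampled MCC %.3f",
                    iteration, len(pool), len(new_pool), best)
        if len(new_pool) >= len(pool):  # cannot shrink further (pool == k)
            break
        pool = new_pool

    scored = exhaustive_phase(pool, dataset, cfg, _ctx=ctx)
    max_mcc = max(f.mcc for f in scored)
    if max_mcc <= 0.0:
        raise NoDiscriminatingFilterError(
            f"no discriminating filter: best exhaustive MCC {max_mcc:.4f} "
            f"over {len(scored)} subsets of {len(pool)} descriptors")
    floor = (1.0 - cfg.band_fraction) * max_mcc
    band = [f for f in scored if f.mcc >= floor]
    logger.info("exhaustive phase: %d subsets, top MCC %.3f, %d filters in band >= %.3f",
                len(scored), max_mcc, len(band), floor)

    masks = [ctx.filter_mask(f.descriptor_names,
                             [ctx.bounds[c.name].index((c.low, c.high))
                              for c in f.clauses]) for f in band]
    kept = dedup_filters(band, cfg.dedup_overlap, _ctx=ctx, _masks=masks)
    logger.info("deduplication: %d -> %d filters", len(band), len(kept))

    weights = [filter_weight(f.counts) for f in kept]
    model = ISEModel(kept, ctx.n_act, ctx.n_inact, weights, cfg)
    model.validate()
    return model
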