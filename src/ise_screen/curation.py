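"""Training-set curation: fingerprints, Tanimoto diversity, applicability domain.

Two curation steps precede model building:

* **Diversity pruning** of the actives — congeneric series inflate
  apparent model quality, so actives more similar than a Tanimoto
  threshold (T = 0.8 by default) to an already-kept active are dropped.
  Similarity uses a hashed linear-path fingerprint (paths of 1–7 bonds,
  folded to 1024 bits), the same family as OpenBabel's FP2.
* **Applicability-domain sampling** of presumed inactives — random
  library molecules are only admitted as training "inactives" if they lie
  within mean ± 2σ of the actives on the four Rule-of-Five descriptors
  (lip_acc, lip_don, cLogP, MW), so the two classes occupy the same
  coarse chemical space and the model cannot win by telling drug-like
  from non-drug-like.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.DataStructs import ExplicitBitVect

from .datamodel_io import DescriptorTable, MoleculeRecord
from .descriptors import RO5_NAMES

logger = logging.getLogger(__name__)

FP_BITS = 1024
FP_MIN_PATH = 1
FP_MAX_PATH = 7


@dataclass
class Fingerprint:
    """Fixed-length hashed path fingerprint of one molecule."""

    bits: ExplicitBitVect
    molecule_id: str

    @property
    def n_bits(self) -> int:
        return self.bits.GetNumBits()

    @property
    def n_on(self) -> int:
        return self.bits.GetNumOnBits()

    def on_bits(self) -> frozenset[int]:
        return frozenset(self.bits.GetOnBits())


def fingerprint(molecule: MoleculeRecord, n_bits: int = FP_BITS) -> Fingerprint:
    """Hashed linear-path fingerprint (1–7 bond paths folded to ``n_bits``).

    A bond-less molecule (single atom) yields an empty bitset and a warning.
    """
    mol = molecule.mol()
    bits = Chem.RDKFingerprint(mol, minPath=FP_MIN_PATH, maxPath=FP_MAX_PATH,
                               fpSize=n_bits, branchedPaths=False)
    if bits.GetNumOnBits() == 0:
        logger.warning("molecule %s has no bond paths; empty fingerprint", molecule.id)
    return Fingerprint(bits, molecule.id)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a ∧ b| / |a ∨ b|; 0.0 when both bitsets are empty."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    union = (a.bits | b.bits).GetNumOnBits()
    if union == 0:
        return 0.0
    return (a.bits & b.bits).GetNumOnBits() / union


def diversity_prune(molecules: Sequence[MoleculeRecord], threshold: float = 0.8,
                    ) -> list[MoleculeRecord]:
    """Greedy first-come diversity pruning.

    Walk molecules in input order; drop any molecule whose Tanimoto
    similarity to an already-retained molecule is >= ``threshold``. The
    retained set therefore contains no pair at or above the threshold.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    kept: list[MoleculeRecord] = []
    kept_fps: list[Fingerprint] = []
    for rec in molecules:
        fp = fingerprint(rec)
        if any(tanimoto(fp, other) >= threshold for other in kept_fps):
            continue
        kept.append(rec)
        kept_fps.append(fp)
    logger.info("diversity pruning at T=%.2f: kept %d of %d",
                threshold, len(kept), len(molecules))
    return kept


@dataclass
class SimilarityReport:
    """Summary of the |X| × |Y| cross-set Tanimoto matrix."""

    max: float
    n_above_04: int
    n_above_07: int
    histogram_counts: np.ndarray  # 20 bins over [0, 1]
    histogram_edges: np.ndarray
    n_pairs: int


def similarity_matrix(set_x: Sequence[MoleculeRecord],
                      set_y: Sequence[MoleculeRecord]) -> np.ndarray:
    fx = [fingerprint(m) for m in set_x]
    fy = [fingerprint(m) for m in set_y]
    return np.array([[tanimoto(a, b) for b in fy] for a in fx])


def similarity_report(set_x: Sequence[MoleculeRecord],
                      set_y: Sequence[MoleculeRecord]) -> SimilarityReport:
    """Cross-set similarity summary: max, counts above 0.4/0.7, histogram."""
    if not set_x or not set_y:
        raise ValueError("both molecule sets must be non-empty")
    mat = similarity_matrix(set_x, set_y)
    flat = mat.ravel()
    counts, edges = np.histogram(flat, bins=20, range=(0.0, 1.0))
    return SimilarityReport(
        max=float(flat.max()),
        n_above_04=int((flat > 0.4).sum()),
        n_above_07=int((flat > 0.7).sum()),
        histogram_counts=counts,
        histogram_edges=edges,
        n_pairs=flat.size,
    )


# ---------------------------------------------------------------------------
# applicability domain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainRange:
    mean: float
    sd: float
    low: float
    high: float


@dataclass
class DomainBox:
    """Per-descriptor mean ± 2σ box computed from the labeled actives.

    σ is the sample standard deviation (n − 1 denominator). With a single
    active (or identical actives) the box degenerates to the exact value.
    """

    ranges: dict[str, DomainRange]

    @classmethod
    def from_actives(cls, actives: DescriptorTable,
                     names: Sequence[str] = RO5_NAMES,
                     sigma_multiplier: float = 2.0) -> "DomainBox":
        mask = actives.active_mask()
        if not mask.any():
            raise ValueError("no labeled actives to define the applicability domain")
        ranges = {}
        for name in names:
            if name not in actives.descriptor_names:
                raise ValueError(f"actives table lacks required descriptor {name!r}")
            vals = actives.values.loc[mask, name].to_numpy(dtype=float)
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            ranges[name] = DomainRange(mean, sd, mean - sigma_multiplier * sd,
                                       mean + sigma_multiplier * sd)
        return cls(ranges)

    def contains(self, descriptors: Mapping[str, float]) -> bool:
        return all(r.low <= float(descriptors[name]) <= r.high
                   for name, r in self.ranges.items())

    def eligibility(self, table: DescriptorTable) -> np.ndarray:
        """Boolean eligibility per molecule; also used to diagnose which
        descriptor is limiting when nothing qualifies."""
        ok = np.ones(len(table), dtype=bool)
        for name, r in self.ranges.items():
            vals = table.values[name].to_numpy(dtype=float)
            ok &= (vals >= r.low) & (vals <= r.high)
        return ok


def sample_inactives(actives: DescriptorTable, candidates: DescriptorTable,
                     n: int, seed: int,
                     sigma_multiplier: float = 2.0) -> DescriptorTable:
    """Draw ``n`` candidates lying inside the actives' ±2σ RO5 domain box.

    Reproducible under ``seed``. If fewer than ``n`` candidates are
    eligible, all of them are returned with a warning; if none are, the
    most restrictive descriptor is named in the error.
    """
    box = DomainBox.from_actives(actives, sigma_multiplier=sigma_multiplier)
    ok = box.eligibility(candidates)
    if not ok.any():
        worst_name, worst_kept = None, None
        for name, r in box.ranges.items():
            vals = candidates.values[name].to_numpy(dtype=float)
            kept = int(((vals >= r.low) & (vals <= r.high)).sum())
            if worst_kept is None or kept < worst_kept:
                worst_name, worst_kept = name, kept
        raise ValueError(
            f"no candidate lies inside the applicability domain; most "
            f"restrictive descriptor is {worst_name!r} ({worst_kept} candidates in range)")
    eligible_ids = [mid for mid, keep in zip(candidates.ids, ok) if keep]
    if len(eligible_ids) <= n:
        if len(eligible_ids) < n:
            logger.warning("only %d of the requested %d candidates are eligible",
                           len(eligible_ids), n)
        chosen = eligible_ids
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(eligible_ids), size=n, replace=False)
        chosen = [eligible_ids[i] for i in sorted(idx)]
    out = candidates.subset(chosen)
    out.labels = out.labels.map(lambda _: "inactive")
    return out
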