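"""Synthetic fixtures with known ground truth for every pipeline stage.

Two generators make the whole toolkit testable without any external data:

* :func:`gen_descriptor_dataset` emulates a curated training table:
  class-conditional normal descriptors where *informative* descriptors
  are mean-shifted between actives and inactives (actives ~ N(shift, 1),
  inactives ~ N(0, 1)) and *noise* descriptors are identically
  distributed in both classes. Normality keeps the best attainable
  filter MCC analytically computable (:func:`expected_clause_mcc`).
  Informative descriptors reuse the Rule-of-Five vocabulary so the
  curation operations run unchanged on synthetic tables. What this does
  not emulate: real descriptor correlation structure, integer-valued
  counts, or multi-modal chemical series.

* :func:`gen_toy_complex` emits a receptor PDB and a docked-pose SDF
  realizing *planned* residue–ligand distances exactly, so the geometric
  pose filter can be checked against an analytically known verdict.
  Residues are glycine-like single-residue placeholders (explicit N and O
  atoms, so H-bond typing is exercised) spaced far apart; each ligand
  atom realizes the planned minimum distance to its residue.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.PDB import PDBIO
from Bio.PDB.StructureBuilder import StructureBuilder
from rdkit import Chem
from rdkit.Geometry import Point3D
from scipy.stats import norm

from .datamodel_io import DescriptorTable
from .geometry import (D_CRUCIAL, D_IMPORTANT, MIN_CRUCIAL, MIN_IMPORTANT,
                       GeometryCriteria)
from .ise_core import balanced_mcc
from .datamodel_io import ConfusionCounts

_RO5_VOCAB = ("lip_acc", "lip_don", "cLogP", "MW", "TPSA")

#: residue anchor spacing (Å); planned distances must stay well below this
RESIDUE_SPACING = 60.0
MAX_PLANNED_DISTANCE = 25.0


# ---------------------------------------------------------------------------
# labeled descriptor tables
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Study conditions for a synthetic labeled descriptor table."""

    n_actives: int = 200
    n_inactives: int = 2000
    n_informative: int = 5
    n_noise: int = 45
    shift: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_actives", "n_inactives", "n_informative"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_noise < 0:
            raise ValueError("n_noise must be >= 0")
        if self.shift < 0:
            raise ValueError("shift must be >= 0")


@dataclass
class SyntheticDataset:
    """A generated table plus its ground-truth descriptor roles."""

    table: DescriptorTable
    informative: list[str]
    noise: list[str]
    spec: SyntheticSpec


def _informative_names(n: int) -> list[str]:
    names = list(_RO5_VOCAB[:n])
    names += [f"inf_{i + 1:02d}" for i in range(len(names), n)]
    return names


def gen_descriptor_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a labeled descriptor table with known informative structure."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    inf_names = _informative_names(spec.n_informative)
    noise_names = [f"noise_{i + 1:02d}" for i in range(spec.n_noise)]
    n = spec.n_actives + spec.n_inactives

    X = rng.standard_normal((n, spec.n_informative + spec.n_noise))
    X[:spec.n_actives, :spec.n_informative] += spec.shift

    ids = ([f"A{i + 1:05d}" for i in range(spec.n_actives)]
           + [f"I{i + 1:05d}" for i in range(spec.n_inactives)])
    labels = pd.Series(["active"] * spec.n_actives + ["inactive"] * spec.n_inactives,
                       index=ids)
    values = pd.DataFrame(X, index=ids, columns=inf_names + noise_names)
    return SyntheticDataset(DescriptorTable(values, labels), inf_names,
                            noise_names, spec)


def expected_clause_mcc(shift: float, low: float, high: float,
                        n_clauses: int = 1) -> float:
    """Analytic balanced MCC of a filter of ``n_clauses`` identical
    [low, high] clauses on independent informative descriptors.

    Population quantities under the generator's model: actives ~
    N(shift, 1) and inactives ~ N(0, 1) per informative descriptor, so
    TPR = (Φ(high−shift) − Φ(low−shift))^c and FPR = (Φ(high) − Φ(low))^c.
    """
    tpr = float(norm.cdf(high - shift) - norm.cdf(low - shift)) ** n_clauses
    fpr = float(norm.cdf(high) - norm.cdf(low)) ** n_clauses
    scale = 1_000_000  # large pseudo-counts: population limit of balanced MCC
    return balanced_mcc(ConfusionCounts(
        tp=round(tpr * scale), fp=round(fpr * scale),
        tn=scale - round(fpr * scale), fn=scale - round(tpr * scale)))


# ---------------------------------------------------------------------------
# toy receptor/pose complexes
# ---------------------------------------------------------------------------

@dataclass
class PosePlan:
    """Planned residue–ligand minimum distances, one row per pose.

    ``distances[p][r]`` is pose p's intended minimum distance (Å) to
    residue r; residues 0..n_crucial-1 are the crucial ones. Energies
    default to the pose index (pose 0 best).
    """

    distances: list[list[float]]
    energies: list[float] | None = None

    def validate(self, n_residues: int) -> None:
        if not self.distances:
            raise ValueError("plan has no poses")
        for p, row in enumerate(self.distances):
            if len(row) != n_residues:
                raise ValueError(f"pose {p}: {len(row)} distances for "
                                 f"{n_residues} residues")
            for d in row:
                if not (0.5 <= d <= MAX_PLANNED_DISTANCE):
                    raise ValueError(
                        f"pose {p}: planned distance {d} Å infeasible "
                        f"(allowed 0.5–{MAX_PLANNED_DISTANCE} Å)")
        if self.energies is not None and len(self.energies) != len(self.distances):
            raise ValueError("one energy per pose required")


@dataclass
class ToyComplex:
    """Generated receptor/pose fixture with analytic ground truth."""

    receptor_pdb: str
    poses_sdf: str
    criteria: GeometryCriteria
    pose_truth: list[bool]          # per pose: passes the criteria?
    accepted: bool                  # molecule verdict
    selected_pose_index: int | None  # lowest-energy passing pose
    plan: PosePlan


def _pose_truth(plan: PosePlan, n_crucial: int, crit: GeometryCriteria) -> list[bool]:
    truth = []
    for row in plan.distances:
        n_cru = sum(1 for d in row[:n_crucial] if d < crit.d_crucial)
        n_imp = sum(1 for d in row if d < crit.d_important)
        truth.append(n_cru >= crit.min_crucial and n_imp >= crit.min_important)
    return truth


def gen_toy_complex(n_important: int, n_crucial: int, plan: PosePlan,
                    seed: int = 0) -> ToyComplex:
    """Emit receptor PDB text + pose SDF text realizing a distance plan.

    ``n_important`` counts all consensus residues (the first
    ``n_crucial`` of them are also crucial-to-H-bond). Each pose's
    minimum distance to residue r is realized exactly (to coordinate
    precision) by a dedicated ligand atom; residues sit on a widely
    spaced line so cross terms cannot undercut the planned minima.
    """
    if not (0 <= n_crucial <= n_important):
        raise ValueError("need 0 <= n_crucial <= n_important")
    plan.validate(n_important)
    rng = np.random.default_rng(seed)

    # residue anchors along x, glycine-like heavy atoms trailing in -x
    anchors = np.array([[i * RESIDUE_SPACING, 0.0, 0.0] for i in range(n_important)])
    atom_offsets = [("N", "N", np.array([0.0, 0.0, 0.0])),
                    ("CA", "C", np.array([-1.5, 0.0, 0.0])),
                    ("C", "C", np.array([-2.9, 0.0, 0.0])),
                    ("O", "O", np.array([-4.1, 0.0, 0.0]))]

    builder = StructureBuilder()
    builder.init_structure("toy")
    builder.init_model(0)
    builder.init_chain("A")
    builder.init_seg("    ")
    serial = 1
    for i, anchor in enumerate(anchors):
        builder.init_residue("GLY", " ", i + 1, " ")
        for name, element, off in atom_offsets:
            builder.init_atom(name, (anchor + off).astype("float32"), 0.0, 1.0,
                              " ", f" {name:<3s}", serial, element=element)
            serial += 1
    buf = io.StringIO()
    pdbio = PDBIO()
    pdbio.set_structure(builder.get_structure())
    pdbio.save(buf)
    receptor_pdb = buf.getvalue()

    # poses: one ligand atom per residue, at the planned distance from the
    # residue's anchor N along a random direction with non-negative x
    energies = plan.energies or [float(p) for p in range(len(plan.distances))]
    records = []
    for p, row in enumerate(plan.distances):
        mol = Chem.RWMol()
        conf = Chem.Conformer(n_important)
        for r, d in enumerate(row):
            u = rng.standard_normal(3)
            u[0] = abs(u[0])
            u /= np.linalg.norm(u)
            pos = anchors[r] + d * u
            element = "O" if r < n_crucial else "C"
            idx = mol.AddAtom(Chem.Atom(element))
            conf.SetAtomPosition(idx, Point3D(*pos))
        m = mol.GetMol()
        m.AddConformer(conf)
        block = Chem.MolToMolBlock(m, kekulize=False)
        records.append(f"{block}>  <energy>\n{energies[p]}\n\n$$$$\n")
    poses_sdf = "".join(records)

    crit = GeometryCriteria(
        crucial={("GLY", i + 1) for i in range(n_crucial)},
        important={("GLY", i + 1) for i in range(n_important)},
    )
    truth = _pose_truth(plan, n_crucial, crit)
    accepted = any(truth)
    selected = None
    if accepted:
        passing = [p for p, ok in enumerate(truth) if ok]
        selected = min(passing, key=lambda p: (energies[p], p))
    return ToyComplex(receptor_pdb, poses_sdf, crit, truth, accepted, selected, plan)


def random_pose_plan(rng: np.random.Generator, n_important: int,
                     n_poses: int = 5) -> PosePlan:
    """A random feasible plan spanning passing and failing geometries.

    Distances are kept away from the 3.5/5.0 Å decision boundaries so the
    analytic verdict is insensitive to coordinate-format precision.
    """
    distances = rng.uniform(2.0, 8.0, size=(n_poses, n_important))
    for cut in (D_CRUCIAL, D_IMPORTANT):
        near = np.abs(distances - cut) < 0.06
        distances[near] += 0.12
    distances = np.round(distances, 2)
    energies = np.round(rng.uniform(-12.0, -2.0, size=n_poses), 3)
    return PosePlan(distances.tolist(), energies.tolist())
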