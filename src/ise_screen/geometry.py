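"""Receptor–ligand contact geometry and docking-pose triage.

Docking energy scores are noisy; this module instead judges docked poses
by whether they reproduce the binding geometry seen in reference crystal
complexes. The workflow:

1. Profile each reference complex: a residue is in *van der Waals
   contact* with the ligand when some heavy-atom pair is within 3.9 Å,
   and *hydrogen-bonded* when some donor/acceptor (N or O) pair is within
   3.3 Å (heavy-atom D–A distance; hydrogens are ignored throughout).
2. Derive consensus residue sets across the reference complexes:
   *important* residues contact more than 3 of the ligands or H-bond at
   least one; *crucial-to-H-bond* residues H-bond every ligand. An
   alternative "contacts >= 70% of the ligands" rule is selectable.
3. Triage docked poses: a pose passes when it comes within 3.5 Å of at
   least 2 crucial residues and within 5 Å of at least 7 important
   residues (strict inequalities; residue distance = minimum over all
   heavy-atom pairs of the whole residue). A molecule is accepted if any
   of its (up to 30) poses passes; the accepted pose is the lowest-energy
   passing one. Voting across several receptor structures accepts a
   molecule only if it is accepted in the required number of structures
   (default: all).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.PDB import PDBParser
from rdkit import Chem

logger = logging.getLogger(__name__)

HBOND_MAX = 3.3    # Å, donor–acceptor heavy-atom distance
VDW_MAX = 3.9      # Å, any heavy-atom pair
D_CRUCIAL = 3.5    # Å, pose criterion vs crucial residues (strict <)
D_IMPORTANT = 5.0  # Å, pose criterion vs important residues (strict <)
MIN_CRUCIAL = 2
MIN_IMPORTANT = 7
MAX_POSES = 30

_POLAR = {"N", "O"}

#: A residue identity usable across complexes: (residue name, sequence number).
ResidueKey = tuple[str, int]


@dataclass
class ResidueSpec:
    """One receptor residue: identity plus heavy-atom coordinates."""

    chain: str
    resname: str
    resseq: int
    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3) Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.coords) == 0:
            raise ValueError(f"residue {self.resname}{self.resseq} has no heavy atoms")
        if not np.isfinite(self.coords).all():
            raise ValueError(f"residue {self.resname}{self.resseq} has non-finite coordinates")

    @property
    def key(self) -> ResidueKey:
        return (self.resname, self.resseq)

    def polar_coords(self) -> np.ndarray:
        idx = [i for i, e in enumerate(self.elements) if e in _POLAR]
        return self.coords[idx]


@dataclass
class Pose:
    """One docked ligand pose: heavy-atom coordinates and an energy score
    (lower is better)."""

    coords: np.ndarray  # (n_atoms, 3) Å
    elements: list[str]
    energy: float
    index: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.coords) == 0:
            raise ValueError(f"pose {self.index} has no atoms")
        if not math.isfinite(self.energy):
            raise ValueError(f"pose {self.index} has non-finite energy")

    def polar_coords(self) -> np.ndarray:
        idx = [i for i, e in enumerate(self.elements) if e in _POLAR]
        return self.coords[idx]


@dataclass
class GeometryCriteria:
    """Consensus residue sets plus the distance/count thresholds of the
    pose acceptance rule."""

    crucial: set[ResidueKey]
    important: set[ResidueKey]
    d_crucial: float = D_CRUCIAL
    d_important: float = D_IMPORTANT
    min_crucial: int = MIN_CRUCIAL
    min_important: int = MIN_IMPORTANT
    hbond_max: float = HBOND_MAX
    vdw_max: float = VDW_MAX

    def validate(self) -> None:
        for name in ("d_crucial", "d_important", "hbond_max", "vdw_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_important > len(self.important):
            raise ValueError(
                f"min_important={self.min_important} exceeds the "
                f"{len(self.important)} important residues")
        if not self.crucial:
            warnings.warn("empty crucial residue set: the pose filter degenerates "
                          "to the important-residue criterion only")


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

def read_receptor(path: str | Path, ligand_resname: str | None = None,
                  ) -> tuple[list[ResidueSpec], Pose | None]:
    """Parse a PDB file into residue specs (hydrogens and waters skipped).

    When ``ligand_resname`` names a HETATM residue, its heavy atoms are
    returned as a zero-energy :class:`Pose` (the crystallographic ligand).
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(Path(path).stem, str(path))
    residues: list[ResidueSpec] = []
    ligand: Pose | None = None
    for model in structure:
        for chain in model:
            for res in chain:
                resname = res.get_resname().strip()
                if resname == "HOH":
                    continue
                names, elements, coords = [], [], []
                for atom in res:
                    el = (atom.element or atom.get_name()[0]).strip().upper()
                    if el == "H" or el == "D":
                        continue
                    names.append(atom.get_name())
                    elements.append(el)
                    coords.append(atom.get_coord())
                if not coords:
                    continue
                if ligand_resname is not None and resname == ligand_resname:
                    ligand = Pose(np.array(coords), elements, energy=0.0)
                    continue
                residues.append(ResidueSpec(chain.id, resname, res.get_id()[1],
                                            names, elements, np.array(coords)))
        break  # first model only
    if ligand_resname is not None and ligand is None:
        raise ValueError(f"ligand residue {ligand_resname!r} not found in {path}")
    return residues, ligand


def read_poses_sdf(path: str | Path, energy_tag: str = "energy") -> list[Pose]:
    """Read docked poses from an SDF file, one conformer per record.

    The energy score is taken from the named SDF data tag.
    """
    poses: list[Pose] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"unparsable SDF record {i + 1} in {path}")
        if not mol.HasProp(energy_tag):
            raise ValueError(f"SDF record {i + 1} lacks energy tag {energy_tag!r}")
        energy = float(mol.GetProp(energy_tag))
        conf = mol.GetConformer()
        coords, elements = [], []
        for atom in mol.GetAtoms():
            if atom.GetSymbol() == "H":
                continue
            elements.append(atom.GetSymbol())
            p = conf.GetAtomPosition(atom.GetIdx())
            coords.append((p.x, p.y, p.z))
        poses.append(Pose(np.array(coords), elements, energy, index=i))
    return poses


def read_criteria(path: str | Path) -> GeometryCriteria:
    """Read a criteria config: ``[crucial]`` / ``[important]`` sections of
    ``chain:resName:resSeq`` lines, optional ``key = value`` threshold
    overrides in ``[thresholds]``."""
    crucial: set[ResidueKey] = set()
    important: set[ResidueKey] = set()
    thresholds: dict[str, float] = {}
    section = None
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            continue
        if section == "thresholds":
            key, _, value = line.partition("=")
            thresholds[key.strip()] = float(value)
            continue
        parts = line.split(":")
        if len(parts) != 3:
            raise ValueError(f"bad residue entry {line!r}; expected chain:resName:resSeq")
        key = (parts[1].strip().upper(), int(parts[2]))
        if section == "crucial":
            crucial.add(key)
        elif section == "important":
            important.add(key)
        else:
            raise ValueError(f"residue entry {line!r} outside a [crucial]/[important] section")
    crit = GeometryCriteria(crucial, important | crucial)
    for key, value in thresholds.items():
        if key in ("min_crucial", "min_important"):
            setattr(crit, key, int(value))
        elif key in ("d_crucial", "d_important", "hbond_max", "vdw_max"):
            setattr(crit, key, float(value))
        else:
            raise ValueError(f"unknown threshold {key!r}")
    crit.validate()
    return crit


def write_criteria(crit: GeometryCriteria, path: str | Path) -> None:
    lines = ["[crucial]"]
    lines += [f"*:{name}:{seq}" for name, seq in sorted(crit.crucial, key=lambda k: k[1])]
    lines.append("[important]")
    lines += [f"*:{name}:{seq}" for name, seq in sorted(crit.important, key=lambda k: k[1])]
    lines.append("[thresholds]")
    for key in ("d_crucial", "d_important", "min_crucial", "min_important",
                "hbond_max", "vdw_max"):
        lines.append(f"{key} = {getattr(crit, key)}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# contact geometry
# ---------------------------------------------------------------------------

def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) == 0 or len(b) == 0:
        return math.inf
    diff = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).min())


def residue_ligand_distance(residue: ResidueSpec, pose: Pose) -> float:
    """Minimum heavy-atom pair distance (Å) between residue and pose."""
    return _min_dist(residue.coords, pose.coords)


@dataclass
class ContactRecord:
    """Contact typing of one residue against one ligand."""

    key: ResidueKey
    hbond: bool
    vdw: bool
    min_dist: float


def contact_profile(residues: Sequence[ResidueSpec], ligand: Pose,
                    hbond_max: float = HBOND_MAX, vdw_max: float = VDW_MAX,
                    ) -> dict[ResidueKey, ContactRecord]:
    """Per-residue contact record against one ligand.

    vdw: some heavy-atom pair <= ``vdw_max``; hbond: some N/O–N/O pair
    <= ``hbond_max``. An H-bond implies a vdW contact in the output.
    """
    lig_polar = ligand.polar_coords()
    profile: dict[ResidueKey, ContactRecord] = {}
    for res in residues:
        d = residue_ligand_distance(res, ligand)
        vdw = d <= vdw_max
        hbond = _min_dist(res.polar_coords(), lig_polar) <= hbond_max
        profile[res.key] = ContactRecord(res.key, hbond, vdw or hbond, d)
    return profile


def derive_consensus_residues(profiles: Sequence[Mapping[ResidueKey, ContactRecord]],
                              important_rule: str = "count_or_hbond",
                              contact_fraction: float = 0.70,
                              ) -> GeometryCriteria:
    """Derive crucial/important residue sets from per-complex profiles.

    ``count_or_hbond`` (default): important residues contact (vdW) more
    than 3 of the ligands or H-bond at least one. ``fraction``: important
    residues contact at least ``contact_fraction`` of the ligands.
    Crucial-to-H-bond residues H-bond the ligand in every complex.
    """
    if not profiles:
        raise ValueError("at least one contact profile required")
    m = len(profiles)
    keys = sorted({k for p in profiles for k in p}, key=lambda k: (k[1], k[0]))
    important: set[ResidueKey] = set()
    crucial: set[ResidueKey] = set()
    for key in keys:
        n_contact = sum(1 for p in profiles if key in p and p[key].vdw)
        n_hbond = sum(1 for p in profiles if key in p and p[key].hbond)
        if important_rule == "count_or_hbond":
            if n_contact > 3 or n_hbond >= 1:
                important.add(key)
        elif important_rule == "fraction":
            if n_contact >= contact_fraction * m:
                important.add(key)
        else:
            raise ValueError(f"unknown important_rule {important_rule!r}")
        if n_hbond == m:
            crucial.add(key)
    if not crucial:
        warnings.warn("no residue H-bonds every ligand: crucial set is empty")
    crit = GeometryCriteria(crucial, important | crucial)
    return crit


# ---------------------------------------------------------------------------
# pose triage
# ---------------------------------------------------------------------------

def pose_passes(pose: Pose, residues: Sequence[ResidueSpec],
                criteria: GeometryCriteria) -> bool:
    """True iff the pose is < ``d_crucial`` Å from at least ``min_crucial``
    crucial residues and < ``d_important`` Å from at least
    ``min_important`` important residues (strict inequalities)."""
    by_key: dict[ResidueKey, list[ResidueSpec]] = {}
    for r in residues:
        by_key.setdefault(r.key, []).append(r)

    def n_within(keys: Iterable[ResidueKey], cutoff: float) -> int:
        n = 0
        for key in keys:
            copies = by_key.get(key, [])
            if copies and min(residue_ligand_distance(r, pose) for r in copies) < cutoff:
                n += 1
        return n

    return (n_within(criteria.crucial, criteria.d_crucial) >= criteria.min_crucial
            and n_within(criteria.important, criteria.d_important) >= criteria.min_important)


@dataclass
class DockVerdict:
    """Outcome of triaging one molecule's pose set against one receptor."""

    accepted: bool
    selected_pose: Pose | None = None
    n_passing: int = 0


def molecule_dock_verdict(poses: Sequence[Pose], residues: Sequence[ResidueSpec],
                          criteria: GeometryCriteria) -> DockVerdict:
    """Accept a molecule iff at least one pose passes; select the
    lowest-energy passing pose (ties → lowest pose index).

    More than 30 poses are truncated to the 30 best-energy ones with a
    warning.
    """
    if not poses:
        raise ValueError("at least one pose required")
    if len(poses) > MAX_POSES:
        logger.warning("truncating %d poses to the %d best-energy ones",
                       len(poses), MAX_POSES)
        poses = sorted(poses, key=lambda p: (p.energy, p.index))[:MAX_POSES]
    passing = [p for p in poses if pose_passes(p, residues, criteria)]
    if not passing:
        return DockVerdict(False, None, 0)
    best = min(passing, key=lambda p: (p.energy, p.index))
    return DockVerdict(True, best, len(passing))


@dataclass
class ConsensusResult:
    accepted: bool
    votes: int
    n_structures: int


def consensus_vote(verdicts: Sequence[DockVerdict | bool],
                   required: int | None = None) -> ConsensusResult:
    """Accept iff the molecule was accepted in >= ``required`` receptor
    structures (default: all of them); report the vote tally."""
    if not verdicts:
        raise ValueError("at least one structure verdict required")
    flags = [v.accepted if isinstance(v, DockVerdict) else bool(v) for v in verdicts]
    if required is None:
        required = len(flags)
    if not (1 <= required <= len(flags)):
        raise ValueError(f"required={required} outside 1..{len(flags)}")
    votes = sum(flags)
    return ConsensusResult(votes >= required, votes, len(flags))
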