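"""2D physico-chemical descriptor computation.

The learning algorithm is descriptor-agnostic; what matters is a broad
panel of named numeric 2D properties per molecule. The default panel
(:data:`DEFAULT_SPEC`) covers >40 RDKit 2D descriptors and pins the four
Rule-of-Five semantics the applicability domain is defined on:

* ``MW`` — molecular weight (average atomic masses, Da)
* ``cLogP`` — Wildman–Crippen log octanol/water partition estimate
* ``lip_acc`` — Lipinski H-bond acceptor count (all N + O)
* ``lip_don`` — Lipinski H-bond donor count (all OH + NH)

All descriptors are computed from the molecular graph only (no 3D), so
values are invariant to input atom ordering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .datamodel_io import DescriptorTable, MoleculeRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DescriptorSpec:
    """A named descriptor and the function computing it from an RDKit Mol."""

    name: str
    fn: Callable[[Chem.Mol], float]


def _aromatic_atoms(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())


def _formal_charge(mol: Chem.Mol) -> int:
    return Chem.GetFormalCharge(mol)


def _default_panel() -> tuple[DescriptorSpec, ...]:
    # RO5 semantics first; their names are relied on by curation.
    panel: list[DescriptorSpec] = [
        DescriptorSpec("MW", Descriptors.MolWt),
        DescriptorSpec("cLogP", Crippen.MolLogP),
        DescriptorSpec("lip_acc", Lipinski.NOCount),
        DescriptorSpec("lip_don", Lipinski.NHOHCount),
        DescriptorSpec("TPSA", rdMolDescriptors.CalcTPSA),
        DescriptorSpec("rotatable_bonds", Lipinski.NumRotatableBonds),
        DescriptorSpec("ring_count", rdMolDescriptors.CalcNumRings),
        DescriptorSpec("aromatic_rings", rdMolDescriptors.CalcNumAromaticRings),
        DescriptorSpec("aromatic_atoms", _aromatic_atoms),
        DescriptorSpec("heavy_atoms", Lipinski.HeavyAtomCount),
        DescriptorSpec("formal_charge", _formal_charge),
        DescriptorSpec("hba", rdMolDescriptors.CalcNumHBA),
        DescriptorSpec("hbd", rdMolDescriptors.CalcNumHBD),
        DescriptorSpec("mol_mr", Crippen.MolMR),
        DescriptorSpec("fraction_csp3", rdMolDescriptors.CalcFractionCSP3),
        DescriptorSpec("num_heteroatoms", Lipinski.NumHeteroatoms),
        DescriptorSpec("num_saturated_rings", rdMolDescriptors.CalcNumSaturatedRings),
        DescriptorSpec("num_aliphatic_rings", rdMolDescriptors.CalcNumAliphaticRings),
        DescriptorSpec("num_amide_bonds", rdMolDescriptors.CalcNumAmideBonds),
        DescriptorSpec("num_spiro_atoms", rdMolDescriptors.CalcNumSpiroAtoms),
        DescriptorSpec("num_bridgehead_atoms", rdMolDescriptors.CalcNumBridgeheadAtoms),
        DescriptorSpec("exact_mw", Descriptors.ExactMolWt),
        DescriptorSpec("qed", Descriptors.qed),
        DescriptorSpec("balaban_j", Descriptors.BalabanJ),
        DescriptorSpec("bertz_ct", Descriptors.BertzCT),
        DescriptorSpec("chi0v", Descriptors.Chi0v),
        DescriptorSpec("chi1v", Descriptors.Chi1v),
        DescriptorSpec("chi2v", Descriptors.Chi2v),
        DescriptorSpec("chi3v", Descriptors.Chi3v),
        DescriptorSpec("kappa1", Descriptors.Kappa1),
        DescriptorSpec("kappa2", Descriptors.Kappa2),
        DescriptorSpec("kappa3", Descriptors.Kappa3),
        DescriptorSpec("hall_kier_alpha", Descriptors.HallKierAlpha),
        DescriptorSpec("labute_asa", Descriptors.LabuteASA),
        DescriptorSpec("max_partial_charge", Descriptors.MaxPartialCharge),
        DescriptorSpec("min_partial_charge", Descriptors.MinPartialCharge),
        DescriptorSpec("num_valence_electrons", Descriptors.NumValenceElectrons),
        DescriptorSpec("num_radical_electrons", Descriptors.NumRadicalElectrons),
        DescriptorSpec("fp_density_morgan2", Descriptors.FpDensityMorgan2),
        DescriptorSpec("mol_wt_heavy", Descriptors.HeavyAtomMolWt),
        DescriptorSpec("nhoh_count", Lipinski.NHOHCount),
        DescriptorSpec("sssr", lambda m: float(len(Chem.GetSSSR(m)))),
    ]
    # VSA series pads the panel with shape/electronics surface descriptors.
    for i in (1, 2, 3, 4, 5):
        panel.append(DescriptorSpec(f"slogp_vsa{i}", getattr(Descriptors, f"SlogP_VSA{i}")))
        panel.append(DescriptorSpec(f"smr_vsa{i}", getattr(Descriptors, f"SMR_VSA{i}")))
    return tuple(panel)


DEFAULT_SPEC: tuple[DescriptorSpec, ...] = _default_panel()

#: The four Rule-of-Five descriptor names the applicability domain uses.
RO5_NAMES = ("lip_acc", "lip_don", "cLogP", "MW")


def compute_descriptors(molecules: Iterable[MoleculeRecord],
                        spec: Sequence[DescriptorSpec] = DEFAULT_SPEC,
                        ) -> DescriptorTable:
    """Compute every descriptor in ``spec`` for every molecule.

    A descriptor that is undefined for some molecule (e.g. partial charges
    on an empty molecule) is recorded as NaN and flagged with a warning;
    downstream learning excludes such molecules via
    :meth:`DescriptorTable.drop_incomplete`.
    """
    molecules = list(molecules)
    if not spec:
        raise ValueError("descriptor spec is empty")
    if not molecules:
        raise ValueError("no molecules")
    names = [s.name for s in spec]
    if len(set(names)) != len(names):
        raise ValueError("duplicate descriptor names in spec")

    rows, n_flagged = [], 0
    for rec in molecules:
        mol = rec.mol()
        row = {}
        for s in spec:
            try:
                v = float(s.fn(mol))
            except Exception:
                v = math.nan
            if math.isnan(v):
                n_flagged += 1
            row[s.name] = v
        rows.append(row)
    if n_flagged:
        logger.warning("%d descriptor values undefined (NaN-flagged)", n_flagged)

    values = pd.DataFrame(rows, index=[r.id for r in molecules], columns=names)
    labels = pd.Series([r.label for r in molecules], index=values.index)
    return DescriptorTable(values, labels)
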