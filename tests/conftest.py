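import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from ise_screen.datamodel_io import (ConfusionCounts, DescriptorTable,
                                     ISEModel, MoleculeRecord, RangeClause,
                                     RangeFilter)


@pytest.fixture
def ethanol():
    return MoleculeRecord("eth1", "CCO")


@pytest.fixture
def benzene():
    return MoleculeRecord("bz1", "c1ccccc1")


@pytest.fixture
def tiny_table():
    """Six molecules, two descriptors, both classes."""
    values = pd.DataFrame(
        {"d1": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0],
         "d2": [0.5, 0.6, 0.4, 0.5, 0.9, 0.1]},
        index=[f"m{i}" for i in range(6)])
    labels = pd.Series(["active"] * 3 + ["inactive"] * 3, index=values.index)
    return DescriptorTable(values, labels)


def make_filter(name_bounds, tp=3, fp=0, tn=3, fn=0):
    """A scored RangeFilter from a {name: (low, high)} mapping."""
    from ise_screen.ise_core import balanced_mcc
    clauses = tuple(RangeClause(n, lo, hi) for n, (lo, hi) in name_bounds.items())
    counts = ConfusionCounts(tp, fp, tn, fn)
    return RangeFilter(clauses, counts, balanced_mcc(counts))


@pytest.fixture
def toy_model():
    """Two-filter model with hand-set weights 2 and 3."""
    f1 = make_filter({"d1": (0.0, 5.0), "d2": (0.0, 1.0)})
    f2 = make_filter({"d1": (0.0, 4.0), "d2": (0.2, 0.8)})
    return ISEModel([f1, f2], n_actives=3, n_inactives=3, weights=[2.0, 3.0])


def replicated_standard_mcc(c: ConfusionCounts) -> float:
    """Independent oracle for the balanced MCC: standard MCC on the
    dataset in which every active row is replicated n_inactives times and
    every inactive row n_actives times (exact rational arithmetic up to
    the final square root)."""
    tp = Fraction(c.tp * c.n_inactives)
    fn = Fraction(c.fn * c.n_inactives)
    fp = Fraction(c.fp * c.n_actives)
    tn = Fraction(c.tn * c.n_actives)
    num = tp * tn - fp * fn
    den2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den2 == 0:
        return 0.0
    return float(num) / math.sqrt(float(den2))


def random_chain_records(rng, n, prefix="r"):
    """Random small organic chain molecules (valid by construction).

    Linear heavy-atom chains over C/N/O/S with single bonds; duplicates
    and close homologues occur naturally, which is what diversity pruning
    needs to exercise.
    """
    symbols = ["C", "C", "C", "N", "O", "S"]
    records = []
    for i in range(n):
        length = int(rng.integers(4, 12))
        mol = Chem.RWMol()
        prev = None
        for _ in range(length):
            idx = mol.AddAtom(Chem.Atom(symbols[rng.integers(len(symbols))]))
            if prev is not None:
                mol.AddBond(prev, idx, Chem.BondType.SINGLE)
            prev = idx
        m = mol.GetMol()
        Chem.SanitizeMol(m)
        records.append(MoleculeRecord(f"{prefix}{i}", Chem.MolToSmiles(m)))
    return records
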