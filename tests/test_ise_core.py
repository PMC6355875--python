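import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from ise_screen import ise_core
from ise_screen.datamodel_io import (ConfusionCounts, DescriptorTable,
                                     ISEConfig, RangeClause, RangeFilter)
from ise_screen.ise_core import (NoDiscriminatingFilterError, balanced_mcc,
                                 build_model, dedup_filters,
                                 eliminate_descriptors, exhaustive_phase,
                                 filter_passes, sample_filter, score_filter)
from ise_screen.synthetic import SyntheticSpec, gen_descriptor_dataset
from conftest import replicated_standard_mcc


class TestBalancedMcc:
    def test_perfect_classifier_is_one(self):
        assert balanced_mcc(ConfusionCounts(50, 0, 200, 0)) == pytest.approx(1.0)

    def test_pass_everything_is_zero_by_convention(self):
        assert balanced_mcc(ConfusionCounts(50, 200, 0, 0)) == 0.0

    def test_absent_class_is_fatal(self):
        with pytest.raises(ValueError):
            balanced_mcc(ConfusionCounts(5, 0, 0, 2))

    def test_equals_replicated_standard_mcc_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(150):
            n_act, n_inact = int(rng.integers(1, 500)), int(rng.integers(1, 5000))
            tp, fp = int(rng.integers(0, n_act + 1)), int(rng.integers(0, n_inact + 1))
            c = ConfusionCounts(tp, fp, n_inact - fp, n_act - tp)
            assert balanced_mcc(c) == pytest.approx(replicated_standard_mcc(c),
                                                    abs=1e-12)


class TestFilterPasses:
    filt = RangeFilter((RangeClause("a", 0.0, 1.0), RangeClause("b", 2.0, 4.0)))

    def test_inside_all_ranges(self):
        assert filter_passes(self.filt, {"a": 0.5, "b": 3.0})

    def test_one_value_above_high(self):
        assert not filter_passes(self.filt, {"a": 0.5, "b": 4.5})

    def test_boundary_values_pass_closed_intervals(self):
        assert filter_passes(self.filt, {"a": 1.0, "b": 2.0})

    def test_missing_descriptor_fatal(self):
        with pytest.raises(ValueError, match="'b'"):
            filter_passes(self.filt, {"a": 0.5})


def test_score_filter_counts_match_brute_force(tiny_table):
    f = RangeFilter((RangeClause("d1", 0.0, 5.0), RangeClause("d2", 0.3, 0.7)))
    scored = score_filter(f, tiny_table)
    expected = []
    for mid in tiny_table.ids:
        v = tiny_table.values.loc[mid]
        expected.append(0.0 <= v["d1"] <= 5.0 and 0.3 <= v["d2"] <= 0.7)
    act = tiny_table.active_mask()
    tp = sum(p and a for p, a in zip(expected, act))
    fp = sum(p and not a for p, a in zip(expected, act))
    assert (scored.counts.tp, scored.counts.fp) == (tp, fp)
    assert scored.counts.n_actives == tiny_table.n_actives
    assert scored.mcc == pytest.approx(balanced_mcc(scored.counts))


class TestSampleFilter:
    def _table(self):
        rng = np.random.default_rng(5)
        values = pd.DataFrame(rng.normal(size=(40, 6)),
                              columns=list("abcdef"),
                              index=[f"m{i}" for i in range(40)])
        labels = pd.Series(["active"] * 20 + ["inactive"] * 20, index=values.index)
        return DescriptorTable(values, labels)

    def test_pool_of_exactly_k_uses_those_descriptors(self):
        t = self._table()
        f = sample_filter(["a", "b", "c", "d"], t, ISEConfig(k=4),
                          np.random.default_rng(0))
        assert sorted(f.descriptor_names) == ["a", "b", "c", "d"]

    def test_fixed_seed_reproduces_the_filter(self):
        t = self._table()
        cfg = ISEConfig(k=4)
        f1 = sample_filter(list("abcdef"), t, cfg, np.random.default_rng(9))
        f2 = sample_filter(list("abcdef"), t, cfg, np.random.default_rng(9))
        assert f1.clauses == f2.clauses and f1.mcc == f2.mcc

    def test_bounds_come_from_the_actives_decile_grid(self):
        values = pd.DataFrame({"x": list(range(1, 11)) + [50.0] * 10,
                               "y": np.linspace(0, 1, 20)},
                              index=[f"m{i}" for i in range(20)])
        labels = pd.Series(["active"] * 10 + ["inactive"] * 10, index=values.index)
        t = DescriptorTable(values, labels)
        grid = set(np.quantile(np.arange(1.0, 11.0), np.linspace(0, 1, 11)))
        rng = np.random.default_rng(2)
        for _ in range(20):
            f = sample_filter(["x", "y"], t, ISEConfig(k=2), rng)
            clause = next(c for c in f.clauses if c.name == "x")
            assert clause.low in grid and clause.high in grid

    def test_pool_smaller_than_k_fatal(self):
        with pytest.raises(ValueError):
            sample_filter(["a"], self._table(), ISEConfig(k=4),
                          np.random.default_rng(0))


def _scored(names, mcc):
    clauses = tuple(RangeClause(n, 0.0, 1.0) for n in names)
    return RangeFilter(clauses, ConfusionCounts(1, 0, 1, 0), mcc)


class TestEliminateDescriptors:
    def test_consistently_bad_descriptor_removed(self):
        pool = ["bad", "g1", "g2", "g3"]
        filters = [_scored(("bad", "g1"), 0.0), _scored(("bad", "g2"), 0.0),
                   _scored(("g1", "g2"), 0.9), _scored(("g2", "g3"), 0.9),
                   _scored(("g1", "g3"), 0.9)]
        out = eliminate_descriptors(filters, pool, ISEConfig(k=2,
                                                             elimination_fraction=0.25))
        assert out == ["g1", "g2", "g3"]

    def test_ties_broken_by_name_order(self):
        pool = ["w", "x", "y", "z"]
        filters = [_scored((a, b), 0.5) for a, b in itertools.combinations(pool, 2)]
        out = eliminate_descriptors(filters, pool,
                                    ISEConfig(k=2, elimination_fraction=0.25))
        assert out == ["x", "y", "z"]  # alphabetically first tied name removed

    def test_fraction_arithmetic(self):
        pool = [f"d{i:02d}" for i in range(20)]
        filters = [_scored((a, b), 0.5) for a, b in zip(pool, pool[1:] + pool[:1])]
        out = eliminate_descriptors(filters, pool,
                                    ISEConfig(k=2, elimination_fraction=0.2))
        assert len(out) == 16

    def test_uncovered_descriptor_requires_resampling(self):
        with pytest.raises(ValueError, match="no sampled filter"):
            eliminate_descriptors([_scored(("a", "b"), 0.5)], ["a", "b", "c"],
                                  ISEConfig(k=2))


class TestExhaustivePhase:
    def _table(self, names):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(rng.normal(size=(30, len(names))), columns=names,
                              index=[f"m{i}" for i in range(30)])
        values.iloc[:15] += 1.0
        labels = pd.Series(["active"] * 15 + ["inactive"] * 15, index=values.index)
        return DescriptorTable(values, labels)

    @pytest.mark.parametrize("n_pool,expected", [(5, 5), (4, 1), (6, 15)])
    def test_enumerates_all_k_subsets(self, n_pool, expected):
        names = list("abcdef")[:n_pool]
        out = exhaustive_phase(names, self._table(names), ISEConfig(k=4))
        assert len(out) == expected
        assert len({f.descriptor_names for f in out}) == expected

    def test_count_above_threshold_fatal(self):
        names = list("abcdefgh")
        with pytest.raises(ValueError, match="exceed"):
            exhaustive_phase(names, self._table(names),
                             ISEConfig(k=4, exhaustive_threshold=10))


class TestDedupFilters:
    def _table(self, n=1000):
        values = pd.DataFrame({"x": np.linspace(0.0, 1.0, n),
                               "y": np.linspace(0.0, 1.0, n)},
                              index=[f"m{i}" for i in range(n)])
        labels = pd.Series(["active"] * (n // 2) + ["inactive"] * (n - n // 2),
                           index=values.index)
        return DescriptorTable(values, labels)

    def test_identical_filters_collapse_to_higher_mcc(self):
        t = self._table()
        f1 = score_filter(RangeFilter((RangeClause("x", 0.0, 0.5),)), t)
        f2 = RangeFilter(f1.clauses, f1.counts, (f1.mcc or 0) - 0.1)
        kept = dedup_filters([f2, f1], 0.99, dataset=t)
        assert kept == [f1]

    def test_half_disagreement_keeps_both(self):
        t = self._table()
        f1 = score_filter(RangeFilter((RangeClause("x", 0.0, 0.5),)), t)
        f2 = score_filter(RangeFilter((RangeClause("x", 0.5, 1.0),)), t)
        assert len(dedup_filters([f1, f2], 0.99, dataset=t)) == 2

    def test_995_of_1000_agreement_drops_lower_mcc(self):
        t = self._table(1000)
        # pass vectors differ on exactly 5 molecules (0.5% < 1% overlap slack)
        f_hi = score_filter(RangeFilter((RangeClause("x", 0.0, 0.4994),)), t)
        f_lo = score_filter(RangeFilter((RangeClause("x", 0.0, 0.4944),)), t)
        n_diff = abs(f_hi.counts.tp + f_hi.counts.fp - f_lo.counts.tp - f_lo.counts.fp)
        assert n_diff == 5
        kept = dedup_filters([f_lo, f_hi], 0.99, dataset=t)
        assert kept == [max((f_hi, f_lo), key=lambda f: f.mcc)]

    def test_output_sorted_by_mcc_descending(self):
        t = self._table()
        filters = [score_filter(RangeFilter((RangeClause("x", 0.0, hi),)), t)
                   for hi in (0.2, 0.5, 0.35)]
        kept = dedup_filters(filters, 0.99, dataset=t)
        assert [f.mcc for f in kept] == sorted((f.mcc for f in kept), reverse=True)


SMALL = SyntheticSpec(n_actives=60, n_inactives=300, n_informative=3,
                      n_noise=9, shift=3.0, seed=5)
SMALL_CFG = ISEConfig(k=4, filters_per_iteration=150, exhaustive_threshold=100,
                      seed=5)


class TestBuildModel:
    def test_same_seed_same_model(self):
        table = gen_descriptor_dataset(SMALL).table
        m1 = build_model(table, SMALL_CFG)
        m2 = build_model(table, SMALL_CFG)
        assert [f.clauses for f in m1.filters] == [f.clauses for f in m2.filters]
        assert m1.weights == m2.weights

    def test_model_invariants(self):
        table = gen_descriptor_dataset(SMALL).table
        model = build_model(table, SMALL_CFG)
        assert model.n_actives == 60 and model.n_inactives == 300
        top = model.filters[0].mcc
        for f in model.filters:
            assert f.counts.tp + f.counts.fn == model.n_actives
            assert f.counts.fp + f.counts.tn == model.n_inactives
            assert f.mcc >= (1 - SMALL_CFG.band_fraction) * top
            assert len(f.clauses) == SMALL_CFG.k

    def test_band_widening_never_shrinks_model(self):
        table = gen_descriptor_dataset(SMALL).table
        sizes = []
        for band in (0.10, 0.20, 0.35):
            cfg = ISEConfig(**{**SMALL_CFG.to_dict(), "band_fraction": band})
            sizes.append(len(build_model(table, cfg).filters))
        assert sizes == sorted(sizes)

    def test_identical_class_distributions_yield_no_usable_model(self):
        # shift 0: classes are the same distribution; either the build
        # aborts or the best filter is close to uninformative
        spec = SyntheticSpec(**{**SMALL.__dict__, "shift": 0.0})
        table = gen_descriptor_dataset(spec).table
        try:
            model = build_model(table, SMALL_CFG)
        except NoDiscriminatingFilterError:
            return
        assert max(f.mcc for f in model.filters) < 0.35
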