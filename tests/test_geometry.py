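import itertools

import numpy as np
import pytest

from ise_screen.geometry import (ContactRecord, DockVerdict, GeometryCriteria,
                                 Pose, ResidueSpec, consensus_vote,
                                 contact_profile, derive_consensus_residues,
                                 molecule_dock_verdict, pose_passes,
                                 read_criteria, residue_ligand_distance,
                                 write_criteria)


def residue(coords, elements=None, resseq=1, resname="GLY"):
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    elements = elements or ["C"] * len(coords)
    names = [f"{e}{i}" for i, e in enumerate(elements)]
    return ResidueSpec("A", resname, resseq, names, elements, coords)


def pose(coords, elements=None, energy=0.0, index=0):
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    return Pose(coords, elements or ["C"] * len(coords), energy, index)


class TestResidueLigandDistance:
    def test_single_pair(self):
        assert residue_ligand_distance(residue([0, 0, 0]), pose([3, 0, 0])) == 3.0

    def test_minimum_over_residue_atoms(self):
        r = residue([[0, 0, 0], [10, 0, 0]])
        assert residue_ligand_distance(r, pose([4, 0, 0])) == pytest.approx(4.0)

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            rc, pc = rng.normal(size=(3, 3)), rng.normal(size=(3, 3))
            expected = min(np.linalg.norm(a - b) for a in rc for b in pc)
            assert residue_ligand_distance(residue(rc), pose(pc)) == pytest.approx(expected)


class TestContactProfile:
    def test_polar_pair_within_hbond_distance(self):
        r = residue([0, 0, 0], ["O"])
        prof = contact_profile([r], pose([3.2, 0, 0], ["N"]))
        rec = prof[r.key]
        assert rec.hbond and rec.vdw

    def test_carbon_pair_is_vdw_only(self):
        r = residue([0, 0, 0], ["C"])
        rec = contact_profile([r], pose([3.8, 0, 0], ["C"]))[r.key]
        assert rec.vdw and not rec.hbond

    def test_beyond_vdw_cutoff_no_contact(self):
        r = residue([0, 0, 0], ["O"])
        rec = contact_profile([r], pose([4.1, 0, 0], ["N"]))[r.key]
        assert not rec.vdw and not rec.hbond

    def test_polar_pair_between_cutoffs_is_vdw_not_hbond(self):
        r = residue([0, 0, 0], ["O"])
        rec = contact_profile([r], pose([3.6, 0, 0], ["N"]))[r.key]
        assert rec.vdw and not rec.hbond

    def test_hbond_implies_vdw_on_random_geometries(self):
        rng = np.random.default_rng(5)
        residues = [residue(rng.normal(scale=3, size=(3, 3)),
                            ["N", "C", "O"], resseq=i + 1) for i in range(10)]
        lig = pose(rng.normal(scale=3, size=(5, 3)), ["C", "N", "O", "C", "C"])
        for rec in contact_profile(residues, lig).values():
            assert not rec.hbond or rec.vdw


def _rec(key, hbond, vdw):
    return {key: ContactRecord(key, hbond, vdw or hbond, 3.0)}


class TestConsensusResidues:
    KEY = ("HIS", 323)

    def _profiles(self, hbond_in, vdw_in, m=5):
        out = []
        for i in range(m):
            out.append(_rec(self.KEY, i < hbond_in, i < vdw_in))
        return out

    def test_hbond_in_all_complexes_is_crucial_and_important(self):
        crit = derive_consensus_residues(self._profiles(5, 5))
        assert self.KEY in crit.crucial and self.KEY in crit.important

    def test_vdw_in_four_of_five_is_important_only(self):
        with pytest.warns(UserWarning, match="crucial"):
            crit = derive_consensus_residues(self._profiles(0, 4))
        assert self.KEY in crit.important and self.KEY not in crit.crucial

    def test_two_contacts_no_hbond_is_neither(self):
        with pytest.warns(UserWarning, match="crucial"):
            crit = derive_consensus_residues(self._profiles(0, 2))
        assert self.KEY not in crit.important and self.KEY not in crit.crucial

    def test_single_hbond_qualifies_as_important(self):
        with pytest.warns(UserWarning, match="crucial"):
            crit = derive_consensus_residues(self._profiles(1, 1))
        assert self.KEY in crit.important and self.KEY not in crit.crucial

    def test_fraction_rule_alternative(self):
        with pytest.warns(UserWarning, match="crucial"):
            crit = derive_consensus_residues(self._profiles(0, 4),
                                             important_rule="fraction",
                                             contact_fraction=0.7)
        assert self.KEY in crit.important
        with pytest.warns(UserWarning, match="crucial"):
            crit = derive_consensus_residues(self._profiles(0, 3),
                                             important_rule="fraction",
                                             contact_fraction=0.7)
        assert self.KEY not in crit.important


def make_site(n_important=9, n_crucial=3):
    """Residues on a line, 60 Å apart; first n_crucial are crucial."""
    residues = [residue([60.0 * i, 0, 0], ["N"], resseq=i + 1)
                for i in range(n_important)]
    crit = GeometryCriteria(
        crucial={("GLY", i + 1) for i in range(n_crucial)},
        important={("GLY", i + 1) for i in range(n_important)})
    return residues, crit


def plan_pose(dists, energy=0.0, index=0):
    coords = [[60.0 * i + d, 0, 0] for i, d in enumerate(dists)]
    return pose(coords, energy=energy, index=index)


class TestPosePasses:
    def test_two_crucial_and_seven_important_pass(self):
        residues, crit = make_site()
        p = plan_pose([3.4, 3.4, 6.0, 4.9, 4.9, 4.9, 4.9, 4.9, 6.0])
        # crucial within 3.5: residues 1,2; within 5.0: 7 residues
        assert pose_passes(p, residues, crit)

    def test_one_crucial_is_not_enough_despite_nine_important(self):
        residues, crit = make_site()
        p = plan_pose([3.4, 4.0, 4.0, 4.9, 4.9, 4.9, 4.9, 4.9, 4.9])
        assert not pose_passes(p, residues, crit)

    def test_six_important_is_not_enough_despite_three_crucial(self):
        residues, crit = make_site()
        p = plan_pose([3.4, 3.4, 3.4, 4.9, 4.9, 4.9, 6.0, 6.0, 6.0])
        assert not pose_passes(p, residues, crit)

    def test_cutoffs_are_strict(self):
        residues, crit = make_site()
        # exactly 3.5 / 5.0 must not count
        p = plan_pose([3.5, 3.4, 3.4, 4.9, 4.9, 4.9, 5.0, 5.0, 5.0])
        assert not pose_passes(p, residues, crit)


class TestDockVerdict:
    def test_lowest_energy_passing_pose_selected(self):
        residues, crit = make_site()
        good = [3.0, 3.0, 3.0, 4.5, 4.5, 4.5, 4.5, 4.5, 4.5]
        poses = [plan_pose(good, energy=-8.0, index=0),
                 plan_pose(good, energy=-10.0, index=1)]
        v = molecule_dock_verdict(poses, residues, crit)
        assert v.accepted and v.selected_pose.index == 1

    def test_all_failing_poses_rejected(self):
        residues, crit = make_site()
        bad = [6.0] * 9
        v = molecule_dock_verdict([plan_pose(bad), plan_pose(bad, index=1)],
                                  residues, crit)
        assert not v.accepted and v.selected_pose is None

    def test_single_passing_pose(self):
        residues, crit = make_site()
        good = [3.0, 3.0, 6.0, 4.5, 4.5, 4.5, 4.5, 4.5, 4.5]
        v = molecule_dock_verdict([plan_pose([6.0] * 9, energy=-20.0),
                                   plan_pose(good, energy=-1.0, index=1)],
                                  residues, crit)
        assert v.accepted and v.selected_pose.index == 1 and v.n_passing == 1

    def test_energy_tie_broken_by_pose_index(self):
        residues, crit = make_site()
        good = [3.0, 3.0, 3.0, 4.5, 4.5, 4.5, 4.5, 4.5, 4.5]
        v = molecule_dock_verdict([plan_pose(good, energy=-5.0, index=0),
                                   plan_pose(good, energy=-5.0, index=1)],
                                  residues, crit)
        assert v.selected_pose.index == 0

    def test_oversized_pose_set_truncated_to_best_30(self, caplog):
        residues, crit = make_site()
        good = [3.0, 3.0, 3.0, 4.5, 4.5, 4.5, 4.5, 4.5, 4.5]
        # the only passing pose has the worst energy -> truncated away
        poses = [plan_pose([6.0] * 9, energy=float(-i), index=i) for i in range(31)]
        poses.append(plan_pose(good, energy=1000.0, index=31))
        with caplog.at_level("WARNING"):
            v = molecule_dock_verdict(poses, residues, crit)
        assert "truncating" in caplog.text
        assert not v.accepted


class TestConsensusVote:
    @pytest.mark.parametrize("flags,required,accepted", [
        ((True, True, True), 3, True),
        ((True, True, False), 3, False),
        ((True, False, False), 1, True),
        ((False, False, False), 1, False),
    ])
    def test_enumerated_cases(self, flags, required, accepted):
        res = consensus_vote(flags, required)
        assert res.accepted == accepted and res.votes == sum(flags)

    def test_default_requires_all_structures(self):
        assert consensus_vote([True, True]).accepted
        assert not consensus_vote([True, False]).accepted

    def test_monotone_in_required(self):
        for flags in itertools.product([True, False], repeat=3):
            accepted = [consensus_vote(flags, r).accepted for r in (1, 2, 3)]
            assert accepted == sorted(accepted, reverse=True)

    def test_verdict_objects_accepted(self):
        v = DockVerdict(True, None, 1)
        assert consensus_vote([v, v], 2).accepted


class TestCriteriaConfig:
    def test_roundtrip(self, tmp_path):
        _, crit = make_site()
        crit.d_crucial = 3.5
        path = tmp_path / "c.cfg"
        write_criteria(crit, path)
        back = read_criteria(path)
        assert back.crucial == crit.crucial
        assert back.important == crit.important
        assert back.min_important == crit.min_important
        assert back.d_important == crit.d_important

    def test_min_important_exceeding_set_rejected(self):
        crit = GeometryCriteria(crucial={("GLY", 1)}, important={("GLY", 1)},
                                min_important=7)
        with pytest.raises(ValueError, match="min_important"):
            crit.validate()

    def test_bad_entry_rejected(self, tmp_path):
        p = tmp_path / "c.cfg"
        p.write_text("[crucial]\nHIS323\n")
        with pytest.raises(ValueError, match="chain:resName:resSeq"):
            read_criteria(p)
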