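"""Superposition, RMSD series, H-bond occupancy and contact maps."""
import numpy as np
import pytest

from xbir3.synthetic import EnsembleRecipe, make_ensemble, make_toy_complex
from xbir3.topology import Trajectory, backbone_selection
from xbir3.traj import (HBondCriterion, contact_map, core_rmsd_series,
                        hbond_occupancy, kabsch_superpose, ligand_rmsd_series)


def rotation(theta, axis=2):
    c, s = np.cos(theta), np.sin(theta)
    m = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    m[i, i] = c; m[i, j] = -s; m[j, i] = s; m[j, j] = c
    return m


class TestKabsch:
    def test_identical_sets(self, rng):
        pts = rng.uniform(-5, 5, (10, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_motion_removed(self, rng):
        pts = rng.uniform(-5, 5, (12, 3))
        moved = pts @ rotation(1.1).T + [7, -3, 2]
        res = kabsch_superpose(pts, moved)
        assert res.rmsd < 1e-9
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-9)

    def test_two_point_hand_case(self):
        # segments of length 2 and 4 share a centroid-aligned optimum: rmsd 1
        res = kabsch_superpose(np.array([[0.0, 0, 0], [2.0, 0, 0]]),
                               np.array([[0.0, 0, 0], [4.0, 0, 0]]))
        assert res.rmsd == pytest.approx(1.0, abs=1e-9)

    def test_collinear_selection_errors(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line + [0.5, 0, 0])

    def test_length_mismatch_errors(self, rng):
        with pytest.raises(ValueError, match="match"):
            kabsch_superpose(rng.uniform(size=(5, 3)), rng.uniform(size=(6, 3)))

    def test_alignment_never_hurts_scored_selection(self, rng):
        ref = rng.uniform(-5, 5, (20, 3))
        mob = ref + rng.normal(0, 0.8, (20, 3))
        aligned = kabsch_superpose(ref, mob).rmsd
        raw = float(np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1))))
        assert aligned <= raw + 1e-12


class TestRmsdSeries:
    def test_frozen_ensemble_zero(self, toy_complex):
        traj = make_ensemble(EnsembleRecipe(toy_complex, sigma=0.0, n_frames=4, seed=0))
        sel = backbone_selection(1, 4)
        assert np.allclose(core_rmsd_series(traj, sel), 0.0, atol=1e-9)

    def test_rigid_body_motion_only_gives_zero(self, toy_complex):
        base = toy_complex.coords()
        frames = [base] + [base @ rotation(0.3 * k).T + [k, 0, -k] for k in (1, 2)]
        traj = Trajectory(toy_complex, frames)
        sel = backbone_selection(1, 4)
        assert np.allclose(core_rmsd_series(traj, sel), 0.0, atol=1e-9)
        lig, unstable = ligand_rmsd_series(traj, sel)
        assert np.allclose(lig, 0.0, atol=1e-9)
        assert not unstable

    def test_jitter_matches_generator_prediction(self):
        # vs the un-jittered base reference, per-atom sigma gives
        # mean rmsd ≈ sqrt(3)·sigma (superposition-DOF correction ~6/3n is
        # negligible at this size)
        top = make_toy_complex(30, seed=6)
        sigma = 0.5
        traj = make_ensemble(EnsembleRecipe(top, sigma=sigma, n_frames=40, seed=8))
        sel = backbone_selection(1, 30)
        rms = core_rmsd_series(traj, sel, reference=top.coords())
        assert rms.mean() == pytest.approx(np.sqrt(3) * sigma, rel=0.15)

    def test_displaced_ligand_rmsd_and_instability_flag(self, toy_complex):
        base = toy_complex.coords()
        lig = toy_complex.segment_positions("ligand")
        shifted = base.copy()
        shifted[lig] += [2.0, 0.0, 0.0]
        # protein fixed, ligand rigidly displaced 2 Å in every frame
        traj = Trajectory(toy_complex, [shifted, shifted, shifted])
        sel = backbone_selection(1, 4)
        rms, unstable = ligand_rmsd_series(traj, sel, reference=base)
        np.testing.assert_allclose(rms, 2.0, atol=1e-9)
        assert not unstable  # mean exactly at the 2 Å threshold, not above
        rms2, unstable2 = ligand_rmsd_series(traj, sel, reference=base,
                                             unstable_threshold=1.5)
        assert unstable2


class TestHBonds:
    def test_planted_occupancy_exact(self, toy_complex):
        donor = next(a.atom_index for a in toy_complex.atoms
                     if a.hbond_role == "donor_heavy" and a.segment == "ligand")
        acceptor = next(a.atom_index for a in toy_complex.atoms
                        if a.hbond_role == "acceptor" and a.segment == "receptor")
        traj = make_ensemble(EnsembleRecipe(toy_complex, sigma=0.2, n_frames=100,
                                            hbond_schedules=[(donor, acceptor, 0.5)],
                                            seed=21))
        occ = hbond_occupancy(traj, HBondCriterion(donor=donor, acceptor=acceptor))
        assert occ == pytest.approx(0.5, abs=1e-12)

    def test_planted_bir3_glu314_pattern(self, toy_complex):
        # the 87.4% occupancy pattern over a 2500-frame ensemble
        donor = next(a.atom_index for a in toy_complex.atoms
                     if a.hbond_role == "donor_heavy" and a.segment == "ligand")
        acceptor = next(a.atom_index for a in toy_complex.atoms
                        if a.hbond_role == "acceptor" and a.segment == "receptor")
        traj = make_ensemble(EnsembleRecipe(toy_complex, sigma=0.3, n_frames=2500,
                                            hbond_schedules=[(donor, acceptor, 0.874)],
                                            seed=22))
        occ = hbond_occupancy(traj, HBondCriterion(donor=donor, acceptor=acceptor))
        assert occ == pytest.approx(0.874, abs=1e-12)
        assert round(occ * 2500) == 2185

    def test_never_satisfied_is_zero(self, toy_complex):
        traj = make_ensemble(EnsembleRecipe(toy_complex, sigma=0.0, n_frames=10, seed=0))
        a1 = toy_complex.atoms[0].atom_index
        a2 = toy_complex.atoms[-1].atom_index
        occ = hbond_occupancy(traj, HBondCriterion(donor=a1, acceptor=a2,
                                                   max_distance=0.5))
        assert occ == 0.0

    def test_unknown_atom_errors(self, toy_complex):
        traj = make_ensemble(EnsembleRecipe(toy_complex, sigma=0.0, n_frames=2, seed=0))
        with pytest.raises(ValueError, match="not found"):
            hbond_occupancy(traj, HBondCriterion(donor=9999, acceptor=1))


class TestContacts:
    def test_far_ligand_all_zero(self, toy_complex):
        base = toy_complex.coords()
        lig = toy_complex.segment_positions("ligand")
        far = base.copy()
        far[lig] += 100.0
        traj = Trajectory(toy_complex, [far, far])
        cm = contact_map(traj)
        assert np.all(cm.frequencies == 0.0)

    def test_frozen_ensemble_binary_entries(self, toy_complex):
        traj = make_ensemble(EnsembleRecipe(toy_complex, sigma=0.0, n_frames=5, seed=0))
        cm = contact_map(traj)
        assert set(np.unique(cm.frequencies)) <= {0.0, 1.0}

    def test_planted_intermittent_contact(self, toy_complex):
        donor = next(a.atom_index for a in toy_complex.atoms
                     if a.hbond_role == "donor_heavy" and a.segment == "ligand")
        acceptor = next(a.atom_index for a in toy_complex.atoms
                        if a.hbond_role == "acceptor" and a.segment == "receptor")
        # schedule moves the *receptor acceptor* next to the ligand donor in
        # 60% of frames (2.9 Å < 4 Å cutoff) and away (6 Å) otherwise
        traj = make_ensemble(EnsembleRecipe(toy_complex, sigma=0.05, n_frames=100,
                                            hbond_schedules=[(donor, acceptor, 0.6)],
                                            seed=30))
        cm = contact_map(traj, cutoff=4.0)
        acc_res = next(a.residue_id for a in toy_complex.atoms if a.atom_index == acceptor)
        row = cm.residue_ids.index(acc_res)
        col = cm.ligand_atom_indices.index(donor)
        assert cm.frequencies[row, col] == pytest.approx(0.6, abs=1e-12)

    def test_invalid_cutoff(self, toy_complex):
        traj = Trajectory(toy_complex, [toy_complex.coords()])
        with pytest.raises(ValueError):
            contact_map(traj, cutoff=0.0)
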