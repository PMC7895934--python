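"""Membrane pose angles, occlusion, d_Gz, ensemble binning, loop insertion."""

import math

import numpy as np
import pytest

from rascal.membrane import (CRD_LOOP_RANGES, KRAS_FIT_RANGES, MembraneFrame,
                             PoseAngles, WeightError,
                             align_complex_to_posed_reference, align_to_pose,
                             compute_dgz, construct_pose, count_clashes,
                             ensemble_summary, loop_insertion, pose_angles)
from rascal.structio import AtomRecord, Selection, StructureModel, coords_of, select_atoms
from rascal.synth import (DgzBinModel, make_complex_like, make_kras_like,
                          make_lipid_slab, make_pose_ensemble)

FIT_SEL = Selection(chains=("A",), residue_ranges=KRAS_FIT_RANGES,
                    atom_names=("CA",))


class TestPoseAngles:
    def test_zero_tilt_reports_zero_rotation(self, kras_like, slab):
        """With the α5 axis parallel to the normal every rotation is
        equivalent, so rotation is reported as 0 by convention."""
        posed = construct_pose(kras_like, slab, 0.0, 0.0, 30.0)
        angles = pose_angles(posed, slab)
        assert angles.tilt < 1e-6
        assert angles.rotation == 0.0

    @pytest.mark.parametrize("tilt,rot", [(90.0, -15.0), (90.0, -85.0),
                                          (90.0, 105.0), (35.0, 170.0),
                                          (120.0, -179.0), (1.0, 0.0)])
    def test_construct_then_measure_roundtrip(self, kras_like, slab, tilt, rot):
        posed = construct_pose(kras_like, slab, tilt, rot, 30.0, azimuth=77.0)
        angles = pose_angles(posed, slab)
        assert abs(angles.tilt - tilt) < 1e-6
        assert abs((angles.rotation - rot + 180) % 360 - 180) < 1e-6
        assert abs(compute_dgz(posed, slab) - 30.0) < 1e-9

    def test_spin_about_normal_leaves_angles_unchanged(self, kras_like, slab):
        posed = construct_pose(kras_like, slab, 75.0, 40.0, 25.0)
        base = pose_angles(posed, slab)
        theta = math.radians(123.0)
        R = np.array([[math.cos(theta), -math.sin(theta), 0],
                      [math.sin(theta), math.cos(theta), 0], [0, 0, 1.0]])
        com = coords_of(list(posed.atoms())).mean(axis=0)
        spun = posed.transform(R, com - R @ com)
        spun_angles = pose_angles(spun, slab)
        assert abs(spun_angles.tilt - base.tilt) < 1e-6
        assert abs(spun_angles.rotation - base.rotation) < 1e-5

    def test_joint_rigid_transform_invariance(self, kras_like):
        """Rotating protein and membrane frame together changes nothing."""
        slab = make_lipid_slab(40, 40, 5, 2.0, 4.0)
        posed = construct_pose(kras_like, slab, 60.0, 25.0, 28.0)
        theta = math.radians(33)
        R = np.array([[1, 0, 0], [0, math.cos(theta), -math.sin(theta)],
                      [0, math.sin(theta), math.cos(theta)]])
        t = np.array([4.0, -7.0, 11.0])
        moved_model = posed.transform(R, t)
        moved_frame = MembraneFrame(
            lipid_coords=slab.lipid_coords @ R.T + t,
            normal=R @ slab.normal,
            com=R @ slab.com + t,
            headgroup_offset=float((R @ slab.normal) @ (R @ (slab.normal * slab.headgroup_offset) + t)))
        a = pose_angles(posed, slab)
        b = pose_angles(moved_model, moved_frame)
        assert abs(a.tilt - b.tilt) < 1e-6
        assert abs(a.rotation - b.rotation) < 1e-5
        assert abs(compute_dgz(posed, slab) - compute_dgz(moved_model, moved_frame)) < 1e-9
        occ_a = count_clashes(posed, slab)
        occ_b = count_clashes(moved_model, moved_frame)
        assert occ_a.n_res_clash == occ_b.n_res_clash

    def test_too_few_helix_atoms_degenerate(self, slab):
        stub = StructureModel.from_atoms([
            AtomRecord("A", r, "", "ALA", "CA", "C", np.array([0.0, 0, r]))
            for r in (152, 153, 154)])
        with pytest.raises(Exception):
            pose_angles(stub, slab)


class TestAlignToPose:
    def test_identity_when_reference_is_self(self, complex_like):
        ref = coords_of(select_atoms(complex_like, FIT_SEL))
        assert ref.shape[0] == 138  # 23 + 17 + 98 Cα in the fit ranges
        moved, fit_rmsd = align_to_pose(complex_like, ref, FIT_SEL)
        assert fit_rmsd < 1e-12
        np.testing.assert_allclose(coords_of(list(moved.atoms())),
                                   coords_of(list(complex_like.atoms())),
                                   atol=1e-9)

    def test_recovers_known_transform_and_moves_all_chains(self, complex_like):
        theta = math.radians(50)
        R = np.array([[math.cos(theta), 0, math.sin(theta)], [0, 1, 0],
                      [-math.sin(theta), 0, math.cos(theta)]])
        t = np.array([3.0, 14.0, -6.0])
        target = complex_like.transform(R, t)
        ref = coords_of(select_atoms(target, FIT_SEL))
        moved, fit_rmsd = align_to_pose(complex_like, ref, FIT_SEL)
        assert fit_rmsd < 1e-9
        np.testing.assert_allclose(coords_of(list(moved.atoms())),
                                   coords_of(list(target.atoms())), atol=1e-6)


class TestOcclusion:
    def test_distant_protein_has_no_clashes(self, complex_like, slab):
        high = complex_like.transform(np.eye(3), np.array([0, 0, 80.0]))
        occ = count_clashes(high, slab)
        assert occ.n_res_clash == 0
        assert occ.clashing_residues == []

    def test_cutoff_boundary_at_one_angstrom(self, slab):
        """0.9 Å from a lipid atom counts; 1.1 Å does not (0.1 nm cutoff)."""
        lipid = slab.lipid_coords[0]
        for dz, expect in ((0.9, 1), (1.1, 0)):
            atom = AtomRecord("A", 1, "", "ALA", "CA", "C",
                              lipid + np.array([0, 0, dz]))
            model = StructureModel.from_atoms([atom])
            assert count_clashes(model, slab).n_res_clash == expect

    def test_matches_double_loop_oracle(self, rng, slab):
        for _ in range(5):
            atoms = [AtomRecord("A", i + 1, "", "ALA", "CA", "C",
                                rng.uniform([-30, -30, -6], [30, 30, 8]))
                     for i in range(40)]
            model = StructureModel.from_atoms(atoms)
            expected = set()
            for atom in atoms:
                for lip in slab.lipid_coords:
                    if math.dist(atom.coords, lip) <= 1.0:
                        expected.add(atom.residue_key)
            occ = count_clashes(model, slab)
            assert occ.n_res_clash == len(expected)
            assert set(occ.clashing_residues) == expected

    def test_clashes_monotone_on_approach(self, complex_like, slab, kras_like):
        posed_ref = construct_pose(kras_like, slab, 90.0, -15.0, 40.0)
        posed, _ = align_complex_to_posed_reference(complex_like, posed_ref, FIT_SEL)
        counts = []
        for drop in (0.0, 10.0, 20.0, 30.0, 40.0):
            moved = posed.transform(np.eye(3), -drop * slab.normal)
            counts.append(count_clashes(moved, slab).n_res_clash)
        assert counts == sorted(counts)

    def test_dgz_matches_mass_weighted_oracle(self, kras_like, slab):
        posed = construct_pose(kras_like, slab, 45.0, 60.0, 23.5)
        atoms = list(posed.atoms())
        masses = {"C": 12.011}
        num = sum(masses[a.element] * a.coords for a in atoms)
        com = num / (12.011 * len(atoms))
        oracle = (com - slab.com) @ slab.normal
        assert abs(compute_dgz(posed, slab) - oracle) < 1e-9
        assert abs(compute_dgz(posed, slab) - 23.5) < 1e-9


class TestEnsembleSummary:
    def test_single_pose_single_bin(self):
        out = ensemble_summary([(PoseAngles(90.0, -15.0), 31.5)])
        assert out.n_poses == 1
        ((key, cell),) = out.bins.items()
        assert key == (90.0, -20.0) or key == (90.0, -10.0)
        assert cell["count"] == 1
        assert cell["mean_dgz"] == 31.5

    def test_bin_counts_conserve_poses(self, rng):
        poses = [(PoseAngles(float(t), float(r)), float(d))
                 for t, r, d in zip(rng.uniform(0, 180, 500),
                                    rng.uniform(-180, 180, 500),
                                    rng.normal(30, 2, 500))]
        out = ensemble_summary(poses, bin_halfwidth=5.0)
        assert out.n_poses == 500
        assert sum(c["count"] for c in out.bins.values()) == 500

    def test_single_bin_reduces_to_weighted_mean(self):
        poses = [(PoseAngles(90.0, -13.0), 30.0, 1.0),
                 (PoseAngles(91.0, -11.0), 34.0, 3.0)]
        out = ensemble_summary(poses)
        ((_, cell),) = out.bins.items()
        assert np.isclose(cell["mean_dgz"], (30.0 + 3 * 34.0) / 4.0)

    def test_rotation_bins_wrap_at_180(self):
        out = ensemble_summary([(PoseAngles(90.0, 179.0), 1.0),
                                (PoseAngles(90.0, -179.0), 3.0)],
                               bin_halfwidth=5.0)
        assert len(out.bins) == 1  # both fall in the ±180° bin
        ((_, cell),) = out.bins.items()
        assert np.isclose(cell["mean_dgz"], 2.0)

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(WeightError):
            ensemble_summary([(PoseAngles(90.0, 0.0), 1.0, 0.0)])

    def test_recovers_generative_bin_means(self):
        """Per-bin d_Gz means of a synthetic ensemble match the generative
        model within 3 standard errors."""
        model = DgzBinModel(default_mean=30.0, noise_sd=0.8, bin_halfwidth=5.0)
        poses, truth = make_pose_ensemble(
            400, tilt_dist=(90.0, 4.0), rot_dist=(-15.0, 4.0),
            dgz_model=model, seed=13, with_models=False)
        out = ensemble_summary([(p.angles, p.d_gz) for p in poses])
        for key, cell in out.bins.items():
            if cell["count"] < 5:
                continue
            se = model.noise_sd / math.sqrt(cell["count"])
            assert abs(cell["mean_dgz"] - truth.bin_means[key]) < 3 * se + 1e-9


class TestLoopInsertion:
    def test_high_pose_inserts_nothing(self, complex_like, slab):
        high = complex_like.transform(np.eye(3), np.array([0, 0, 70.0]))
        table = loop_insertion(high, slab, raf_chain="B")
        assert not table["inserted"].any()
        assert (table["depth_A"] < 0).all()

    def test_constructed_two_angstrom_insertion(self, slab):
        atoms = [AtomRecord("B", r, "", "ALA", "CA", "C",
                            np.array([float(r), 0.0, slab.headgroup_offset - 2.0]))
                 for r in range(143, 152)]
        model = StructureModel.from_atoms(atoms)
        table = loop_insertion(model, slab,
                               loop_sels=[Selection(chains=("B",))])
        assert table["inserted"].all()
        np.testing.assert_allclose(table["depth_A"], 2.0, atol=1e-9)

    def test_alpha45_pose_inserts_both_crd_loops(self, complex_like, kras_like):
        """Aligned onto a membrane-proximal α4/α5-facing pose, each CRD loop
        (143-151, 157-164) inserts at least one residue while the KRAS
        G-domain stays clear of the bilayer."""
        frame = make_lipid_slab(200, 200, 2.0, headgroup_z=2.0, thickness=4.0)
        posed_ref = construct_pose(kras_like, frame, 90.0, -15.0, 15.0)
        posed, fit_rmsd = align_complex_to_posed_reference(
            complex_like, posed_ref, FIT_SEL)
        assert fit_rmsd < 1e-9
        table = loop_insertion(posed, frame, raf_chain="B")
        for loop_idx in (0, 1):
            sub = table[table["loop"] == loop_idx]
            assert sub["inserted"].sum() >= 1
        occ = count_clashes(posed, frame, gdomain_sel=Selection(chains=("A",)))
        loop_res = set()
        for lo, hi in CRD_LOOP_RANGES:
            loop_res.update(range(lo, hi + 1))
        assert all(res[0] == "B" and res[1] in loop_res
                   for res in occ.clashing_residues)
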