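"""The seven featurizers, the 35-way combination scheme, and their oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import memstate as ms
from memstate.featurize import (DEFAULT_RECIP_BIN_EDGES, FeatureParams,
                                FeatureSpec, assemble_features,
                                backbone_dihedrals,
                                enumerate_combined_featurizations,
                                lipid_weighted_distance,
                                reciprocal_distance_histogram,
                                rmsd_to_reference, solvent_shell_counts)
from memstate.systems import Trajectory

from conftest import make_topology


class TestEnumeration:
    def test_exactly_35_combined_featurizations(self):
        assert len(enumerate_combined_featurizations()) == 35

    def test_three_protein_only_specs(self):
        only = [s for s in enumerate_combined_featurizations()
                if s.water == "none" and s.lipid == "none"]
        assert len(only) == 3

    def test_specs_unique_and_non_empty(self):
        specs = enumerate_combined_featurizations()
        assert len(set(specs)) == 35
        assert all((s.protein, s.water, s.lipid) != ("none", "none", "none")
                   for s in specs)

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError):
            FeatureSpec("none", "none", "none")


class TestDihedrals:
    def test_rigid_motion_leaves_features_unchanged(self, embedded_system):
        _, _, topo, traj = embedded_system
        rot = Rotation.from_euler("xyz", [30, -40, 75], degrees=True).as_matrix()
        moved = Trajectory(traj.xyz @ rot.T + np.array([1.0, -2.0, 3.0]),
                           traj.frame_interval, traj.box * 10)
        a = backbone_dihedrals(traj, topo)
        b = backbone_dihedrals(moved, topo)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_angles_match_mdtraj(self, embedded_system):
        """Independent oracle: mdtraj's phi/psi on the converted system."""
        import mdtraj as md
        from memstate.systems import to_mdtraj

        _, _, topo, traj = embedded_system
        ours = backbone_dihedrals(traj, topo)
        n = ours.n_features // 2
        ang = np.arctan2(ours.values[:, :n], ours.values[:, n:])
        mdt = to_mdtraj(topo, traj)
        _, phi = md.compute_phi(mdt)
        _, psi = md.compute_psi(mdt)
        theirs = {}
        labels = [lab[:-4] for lab in ours.labels[:n]]
        phi_labels = [f"phi_{i}" for i in range(2, phi.shape[1] + 2)]
        psi_labels = [f"psi_{i}" for i in range(1, psi.shape[1] + 1)]
        theirs.update(zip(phi_labels, phi.T))
        theirs.update(zip(psi_labels, psi.T))
        for j, lab in enumerate(labels):
            delta = np.angle(np.exp(1j * (ang[:, j] - theirs[lab])))
            np.testing.assert_allclose(delta, 0.0, atol=1e-4)

    def test_sin_cos_encoding_is_on_the_unit_circle(self, embedded_system):
        _, _, topo, traj = embedded_system
        fm = backbone_dihedrals(traj, topo)
        n = fm.n_features // 2
        np.testing.assert_allclose(fm.values[:, :n] ** 2 + fm.values[:, n:] ** 2,
                                   1.0, atol=1e-12)


class TestRMSD:
    def test_frame_against_itself_is_zero(self, embedded_system):
        _, _, topo, traj = embedded_system
        fm = rmsd_to_reference(traj, topo, traj.xyz[0])
        assert fm.values[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_transform_gives_zero_rmsd(self, embedded_system):
        _, _, topo, traj = embedded_system
        rot = Rotation.from_euler("zyx", [15, 70, -25], degrees=True).as_matrix()
        moved = traj.xyz[0] @ rot.T + np.array([0.3, 0.1, -0.2])
        fm = rmsd_to_reference(
            Trajectory(moved[None], traj.frame_interval, traj.box), topo, traj.xyz[0])
        assert fm.values[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_matches_mdtraj_superposition(self, embedded_system):
        import mdtraj as md
        from memstate.systems import to_mdtraj

        _, _, topo, traj = embedded_system
        ours = rmsd_to_reference(traj, topo, traj.xyz[0]).values[:, 0]
        mdt = to_mdtraj(topo, traj)
        theirs = md.rmsd(mdt, mdt, 0, atom_indices=topo.protein_heavy)
        np.testing.assert_allclose(ours, theirs, atol=2e-4)  # mdtraj is float32

    def test_never_above_any_sampled_rotation(self):
        """Grid oracle: optimal RMSD lower-bounds RMSD at sampled rotations."""
        rng = np.random.default_rng(3)
        topo = make_topology([(f"C", "ALA", i + 1, "protein_heavy") for i in range(4)])
        ref = rng.normal(size=(4, 3))
        frame = rng.normal(size=(4, 3))
        traj = Trajectory(frame[None], 1.0, np.array([50.0, 50, 50]))
        opt = rmsd_to_reference(traj, topo, ref).values[0, 0]
        ref_c = ref - ref.mean(axis=0)
        x_c = frame - frame.mean(axis=0)

        def rmsd_at(r):
            return np.sqrt(np.mean(np.sum((x_c @ r.as_matrix().T - ref_c) ** 2, axis=1)))

        samples = Rotation.random(2000, rng=np.random.default_rng(5))
        vals = np.array([rmsd_at(r) for r in samples])
        assert opt <= vals.min() + 1e-12  # optimality lower-bounds every sample
        # refine the best sampled rotation with an independent local search
        from scipy.optimize import minimize

        start = samples[int(np.argmin(vals))].as_rotvec()
        refined = minimize(lambda v: rmsd_at(Rotation.from_rotvec(v)), start,
                           method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12}).fun
        assert opt == pytest.approx(refined, abs=1e-4)

    def test_too_few_atoms_rejected(self):
        topo = make_topology([("C", "ALA", 1, "protein_heavy"),
                              ("C", "ALA", 2, "protein_heavy")])
        traj = Trajectory(np.zeros((1, 2, 3)) + np.arange(2)[None, :, None], 1.0)
        with pytest.raises(ValueError):
            rmsd_to_reference(traj, topo, traj.xyz[0])


class TestReciprocalDistances:
    def test_two_atoms_single_count_in_correct_bin(self):
        topo = make_topology([("C", "ALA", 1, "protein_heavy"),
                              ("C", "ALA", 2, "protein_heavy")])
        xyz = np.array([[[0, 0, 0], [0.5, 0, 0]]], dtype=float)
        fm = reciprocal_distance_histogram(Trajectory(xyz, 1.0), topo)
        expected_bin = np.searchsorted(DEFAULT_RECIP_BIN_EDGES, 2.0, side="right") - 1
        assert fm.values[0, expected_bin] == 1.0
        assert fm.values[0].sum() == 1.0

    def test_rows_sum_to_one(self, embedded_system):
        _, _, topo, traj = embedded_system
        fm = reciprocal_distance_histogram(traj, topo)
        np.testing.assert_allclose(fm.values.sum(axis=1), 1.0, atol=1e-12)

    def test_five_atom_frame_matches_enumerated_pairs(self):
        rng = np.random.default_rng(8)
        xyz = rng.uniform(0.2, 1.5, size=(1, 5, 3))
        topo = make_topology([("C", "ALA", i + 1, "protein_heavy") for i in range(5)])
        fm = reciprocal_distance_histogram(Trajectory(xyz, 1.0), topo)
        recips = [1.0 / np.linalg.norm(xyz[0, i] - xyz[0, j])
                  for i in range(5) for j in range(i + 1, 5)]
        assert len(recips) == 10
        expected, _ = np.histogram(recips, bins=DEFAULT_RECIP_BIN_EDGES)
        np.testing.assert_allclose(fm.values[0], expected / expected.sum())

    def test_coincident_atoms_rejected(self):
        topo = make_topology([("C", "ALA", 1, "protein_heavy"),
                              ("C", "ALA", 2, "protein_heavy")])
        with pytest.raises(ValueError, match="coincident"):
            reciprocal_distance_histogram(Trajectory(np.zeros((1, 2, 3)), 1.0), topo)


class TestSolventShell:
    def _tiny(self, waters):
        entries = [("C", "ALA", 1, "protein_heavy"), ("C", "LIG", 2, "ligand_heavy")]
        entries += [("O", "HOH", 10 + i, "water_oxygen") for i in range(len(waters))]
        topo = make_topology(entries)
        xyz = np.concatenate([[[0.0, 0, 0], [2.0, 0, 0]], waters]).astype(float)[None]
        return topo, Trajectory(xyz + 2.5, 1.0, np.array([8.0, 8.0, 8.0]))

    def test_no_solvent_gives_zeros(self):
        topo, traj = self._tiny(np.empty((0, 3)))
        fm = solvent_shell_counts(traj, topo, "water_oxygen", 0.3)
        assert fm.values.shape == (1, 2)
        assert np.all(fm.values == 0)

    def test_single_water_counts_for_one_atom_only(self):
        topo, traj = self._tiny(np.array([[0.25, 0.0, 0.0]]))
        fm = solvent_shell_counts(traj, topo, "water_oxygen", 0.3)
        np.testing.assert_array_equal(fm.values[0], [1.0, 0.0])

    def test_matches_brute_force_minimum_image_count(self):
        rng = np.random.default_rng(17)
        box = np.array([3.0, 3.5, 4.0])
        n_wat = 50
        entries = [("C", "ALA", i + 1, "protein_heavy") for i in range(6)]
        entries += [("O", "HOH", 100 + i, "water_oxygen") for i in range(n_wat)]
        topo = make_topology(entries)
        xyz = rng.uniform(0, 1, size=(2, 6 + n_wat, 3)) * box
        traj = Trajectory(xyz, 1.0, box)
        fm = solvent_shell_counts(traj, topo, "water_oxygen", 1.0)
        for f in range(2):
            for a in range(6):
                delta = xyz[f, 6:] - xyz[f, a]
                delta -= box * np.round(delta / box)
                expected = np.sum(np.linalg.norm(delta, axis=1) <= 1.0)
                assert fm.values[f, a] == expected

    def test_radius_beyond_half_box_rejected(self):
        topo, traj = self._tiny(np.array([[0.25, 0.0, 0.0]]))
        with pytest.raises(ValueError, match="minimum image"):
            solvent_shell_counts(traj, topo, "water_oxygen", 5.0)

    def test_invariant_to_atom_order_within_a_role(self):
        rng = np.random.default_rng(1)
        waters = rng.uniform(-1, 1, size=(20, 3))
        topo, traj = self._tiny(waters)
        fm = solvent_shell_counts(traj, topo, "water_oxygen", 0.8)
        perm = rng.permutation(20)
        topo2, traj2 = self._tiny(waters[perm])
        fm2 = solvent_shell_counts(traj2, topo2, "water_oxygen", 0.8)
        np.testing.assert_array_equal(fm.values, fm2.values)


class TestLipidWeightedDistance:
    def _system(self, lipids):
        entries = [("C", "ALA", 1, "protein_heavy")]
        entries += [("P", "LIP", 10 + i, "lipid_phosphorus") for i in range(len(lipids))]
        topo = make_topology(entries)
        xyz = np.concatenate([[[0.0, 0, 0]], lipids]).astype(float)[None] + 5.0
        return topo, Trajectory(xyz, 1.0, np.array([20.0, 20.0, 20.0]))

    def test_single_phosphorus_at_sigma_gives_inverse_e(self):
        topo, traj = self._system(np.array([[0.3, 0.0, 0.0]]))
        fm = lipid_weighted_distance(traj, topo, sigma_nm=0.3)
        assert fm.values[0, 0] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_distant_phosphorus_contributes_nothing(self):
        topo, traj = self._system(np.array([[9.0, 0.0, 0.0]]))
        fm = lipid_weighted_distance(traj, topo, sigma_nm=0.3)
        assert fm.values[0, 0] < 1e-12

    def test_matches_hand_summed_exponentials(self):
        lipids = np.array([[0.4, 0.1, 0.0], [0.0, 0.9, 0.3]])
        topo, traj = self._system(lipids)
        fm = lipid_weighted_distance(traj, topo, sigma_nm=0.25)
        expected = sum(np.exp(-np.linalg.norm(l) / 0.25) for l in lipids)
        assert fm.values[0, 0] == pytest.approx(expected, rel=1e-12)


class TestAssembly:
    def test_protein_only_spec_equals_bare_featurizer(self, embedded_system):
        _, _, topo, traj = embedded_system
        combined = assemble_features(traj, topo, FeatureSpec(protein="dihedrals"))
        alone = backbone_dihedrals(traj, topo)
        np.testing.assert_array_equal(combined.values, alone.values)
        assert combined.labels == alone.labels

    def test_full_spec_column_count_is_the_sum_of_parts(self, embedded_system):
        _, _, topo, traj = embedded_system
        params = FeatureParams(reference_xyz=traj.xyz[0])
        spec = FeatureSpec("rmsd", "shell_0.3nm", "lipid_weighted_distance")
        combined = assemble_features(traj, topo, spec, params)
        parts = (rmsd_to_reference(traj, topo, traj.xyz[0]).n_features
                 + solvent_shell_counts(traj, topo, "water_oxygen", 0.3).n_features
                 + lipid_weighted_distance(traj, topo).n_features)
        assert combined.n_features == parts

    def test_assembly_is_deterministic(self, embedded_system):
        _, _, topo, traj = embedded_system
        spec = FeatureSpec("reciprocal_distances", "shell_1.0nm", "lipid_shell")
        a = assemble_features(traj, topo, spec)
        b = assemble_features(traj, topo, spec)
        np.testing.assert_array_equal(a.values, b.values)

    def test_hdf5_round_trip(self, tmp_path, embedded_system):
        _, _, topo, traj = embedded_system
        fm = assemble_features(traj, topo, FeatureSpec(protein="rmsd"),
                               FeatureParams(reference_xyz=traj.xyz[0]))
        path = tmp_path / "fm.h5"
        fm.save_hdf5(path)
        back = ms.FeatureMatrix.load_hdf5(path)
        np.testing.assert_array_equal(back.values, fm.values)
        assert back.spec == fm.spec
        assert back.frame_interval == fm.frame_interval
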