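"""Collective variables, free-energy landscapes, basin thermodynamics."""

import numpy as np
import pytest

import memstate as ms
from memstate.landscape import (BasinDefinition, DeltaGResult,
                                basin_deltaG, basin_deltaG_from_frames,
                                bootstrap_deltaG, compute_cv,
                                compute_membrane_frame,
                                count_coordinating_waters, delta_delta_G,
                                msm_weighted_histogram, propose_basins,
                                unweighted_histogram, FreeEnergyLandscape)
from memstate.msm import estimate_msm, stationary_frame_weights
from memstate.synthetic import KT_300K
from memstate.systems import Trajectory

from conftest import make_topology


class TestMembraneFrame:
    def test_planes_at_plus_minus_two_give_zero_center(self, embedded_system):
        cfg, _, topo, traj = embedded_system
        z_center, bottom = compute_membrane_frame(traj, topo)
        np.testing.assert_allclose(z_center, cfg.box[2] / 2, atol=1e-12)
        # the peptide sits above the membrane, so its proximal leaflet is upper
        np.testing.assert_allclose(bottom, cfg.box[2] / 2 + cfg.leaflet_z, atol=1e-12)

    def test_translation_equivariance(self, embedded_system):
        _, _, topo, traj = embedded_system
        moved = Trajectory(traj.xyz + np.array([0.0, 0.0, 1.0]),
                           traj.frame_interval, traj.box + 2.0)
        z0, b0 = compute_membrane_frame(traj, topo)
        z1, b1 = compute_membrane_frame(moved, topo)
        np.testing.assert_allclose(z1, z0 + 1.0, atol=1e-12)
        np.testing.assert_allclose(b1, b0 + 1.0, atol=1e-12)

    def test_leaflet_means_match_known_generator_labels(self, embedded_system):
        cfg, _, topo, traj = embedded_system
        n = cfg.n_lipids_per_leaflet
        lip = topo.lipid_phosphorus
        z_center, bottom = compute_membrane_frame(traj, topo)
        upper_mean = traj.xyz[:, lip[:n], 2].mean(axis=1)
        np.testing.assert_allclose(bottom, upper_mean, atol=1e-12)

    def test_overlapping_leaflets_are_ambiguous(self):
        entries = ([("CA", "MET", 9, "alpha_carbon")]
                   + [("P", "LIP", 100 + i, "lipid_phosphorus") for i in range(10)])
        topo = make_topology(entries)
        rng = np.random.default_rng(0)
        xyz = np.zeros((1, 11, 3))
        xyz[0, 1:, 2] = rng.normal(5.0, 0.1, size=10)  # one fuzzy plane
        with pytest.raises(ValueError, match="ambiguous"):
            compute_membrane_frame(Trajectory(xyz, 1.0, np.array([6.0, 6, 12])), topo)


class TestComputeCV:
    def test_missing_zinc_is_reported(self, embedded_system):
        _, _, topo, traj = embedded_system
        import copy

        broken = copy.deepcopy(topo)
        broken.roles[broken.zinc[0]] = "protein_heavy"
        with pytest.raises(ValueError, match="zinc"):
            compute_cv(traj, broken)

    def test_rigid_z_translation_leaves_cvs_unchanged(self, embedded_system):
        _, pts, topo, traj = embedded_system
        moved = Trajectory(traj.xyz + np.array([0.0, 0.0, 0.8]),
                           traj.frame_interval, traj.box + 2.0)
        cv0 = compute_cv(traj, topo)
        cv1 = compute_cv(moved, topo)
        np.testing.assert_allclose(cv1.d, cv0.d, atol=1e-9)
        np.testing.assert_allclose(cv1.theta, cv0.theta, atol=1e-9)


class TestLandscapes:
    def test_single_state_msm_equals_unweighted_histogram(self):
        rng = np.random.default_rng(2)
        arrays = [rng.normal(size=(50, 2)) + [1.5, 20] for _ in range(4)]
        states = [np.zeros(50, dtype=np.int64) for _ in range(4)]
        msm = estimate_msm(states, 1.0, 1.0, n_states=1)
        edges = (np.linspace(-2, 5, 11), np.linspace(-40, 80, 11))
        weighted = msm_weighted_histogram(arrays, states, msm, bins=edges)
        raw = unweighted_histogram(arrays, bins=edges)
        np.testing.assert_allclose(weighted.p, raw.p, atol=1e-15)

    def test_two_to_one_mass_ratio_gives_kt_ln_two(self):
        pts = np.array([[0.5, 0.0]] * 1 + [[1.5, 0.0]] * 2, dtype=float)
        land = unweighted_histogram([pts], bins=(np.array([0., 1., 2.]),
                                                 np.array([-1., 1.])), kT=KT_300K)
        f = land.free_energy
        assert f[1, 0] == 0.0
        assert f[0, 0] == pytest.approx(KT_300K * np.log(2.0), abs=1e-12)

    def test_mass_conservation_and_min_shift(self, two_well_states):
        cfg, cvs, states = two_well_states
        msm = estimate_msm(states, 4.5, cvs.frame_interval, n_states=60)
        land = msm_weighted_histogram(cvs.trajectories, states, msm, bins=30)
        assert land.p.sum() == pytest.approx(1.0, abs=1e-9)
        f = land.free_energy
        assert np.nanmin(f) == 0.0
        assert np.isnan(f[land.p == 0]).all()

    def test_reweighting_beats_raw_histogram_on_biased_starts(self, two_well_states):
        cfg, cvs, states = two_well_states
        msm = estimate_msm(states, 4.5, cvs.frame_interval, n_states=60)
        edges = (np.linspace(0.6, 2.5, 25), np.linspace(-25, 70, 25))
        ref = ms.exact_histogram_masses(cfg, *edges)
        weighted = msm_weighted_histogram(cvs.trajectories, states, msm, bins=edges,
                                          kT=cfg.kT)
        raw = unweighted_histogram(cvs.trajectories, bins=edges, kT=cfg.kT)
        err_w = np.abs(weighted.p - ref).sum()
        err_r = np.abs(raw.p - ref).sum()
        assert err_w < err_r

    def test_csv_output_has_one_row_per_bin(self, tmp_path):
        rng = np.random.default_rng(1)
        land = unweighted_histogram([rng.normal(size=(100, 2))], bins=8)
        path = tmp_path / "land.csv"
        land.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert len(df) == 64
        assert list(df.columns) == ["d_center_nm", "theta_center_deg",
                                    "F_kcal_mol", "p"]


class TestBasinDeltaG:
    def test_symmetric_wells_give_zero_within_sampling_error(self):
        from memstate.synthetic import SyntheticConfig, WellSpec, sample_langevin

        cfg = SyntheticConfig(
            wells=(WellSpec((1.0, -20.0), 2.0, (0.15, 8.0)),
                   WellSpec((2.0, 20.0), 2.0, (0.15, 8.0))),
            confinement_strength=1.0, confinement_center=(1.5, 0.0),
            n_trajectories=30, frames_per_trajectory=400, seed=3)
        pts = sample_langevin(cfg).concatenated()
        basins = BasinDefinition(deep=(0.0, 1.5, -90, 90), shallow=(1.5, 3.0, -90, 90))
        res = basin_deltaG_from_frames(pts, np.ones(len(pts)), basins, cfg.kT)
        assert abs(res.delta_g) < 0.2  # ~3x the Monte-Carlo standard error

    def test_swapping_basin_labels_flips_the_sign(self, two_well_states):
        cfg, cvs, states = two_well_states
        pts = cvs.concatenated()
        w = np.ones(len(pts))
        basins = ms.default_basins()
        swapped = BasinDefinition(deep=basins.shallow, shallow=basins.deep)
        a = basin_deltaG_from_frames(pts, w, basins, cfg.kT)
        b = basin_deltaG_from_frames(pts, w, swapped, cfg.kT)
        assert a.delta_g == pytest.approx(-b.delta_g, abs=1e-12)

    def test_landscape_and_frame_routes_agree(self, two_well_states):
        cfg, cvs, states = two_well_states
        pts = cvs.concatenated()
        basins = ms.default_basins()
        # bin-center attribution equals exact frame attribution when the grid
        # covers both basins and the basin boundary (d = 1.475) is a bin edge
        edges = (np.linspace(0.4, 2.8, 97), np.linspace(-40.0, 90.0, 27))
        land = unweighted_histogram(cvs.trajectories, bins=edges, kT=cfg.kT)
        a = basin_deltaG(land, basins)
        b = basin_deltaG_from_frames(pts, np.ones(len(pts)), basins, cfg.kT)
        assert a.delta_g == pytest.approx(b.delta_g, abs=1e-9)

    def test_empty_basin_is_an_error(self):
        pts = np.array([[1.0, 0.0], [1.1, 5.0]])
        basins = BasinDefinition(deep=(0.5, 1.5, -90, 90), shallow=(2.0, 3.0, -90, 90))
        with pytest.raises(ValueError, match="zero probability"):
            basin_deltaG_from_frames(pts, np.ones(2), basins)


class TestDeltaDeltaG:
    def _res(self, dg):
        return DeltaGResult(0.5, 0.5, dg, KT_300K)

    def test_printed_example(self):
        assert delta_delta_G(self._res(0.9), self._res(1.9)) == pytest.approx(1.0)

    def test_identical_results_give_zero(self):
        assert delta_delta_G(self._res(1.2), self._res(1.2)) == 0.0

    def test_antisymmetry(self):
        a, b = self._res(0.4), self._res(-0.7)
        assert delta_delta_G(a, b) == -delta_delta_G(b, a)

    def test_mismatched_temperatures_rejected(self):
        a = DeltaGResult(0.5, 0.5, 1.0, 0.5961)
        b = DeltaGResult(0.5, 0.5, 1.0, 0.62)
        with pytest.raises(ValueError, match="kT"):
            delta_delta_G(a, b)


class TestBootstrap:
    def test_identical_trajectories_give_zero_ci_range(self):
        rng = np.random.default_rng(4)
        block = np.r_[np.zeros(30, dtype=np.int64), np.ones(30, dtype=np.int64)]
        states = np.r_[block, block]  # both hop directions occur
        traj = np.column_stack([np.where(states == 0, 1.0, 2.0)
                                + rng.normal(0, 0.05, 120),
                                rng.normal(0, 5, 120)])
        basins = BasinDefinition(deep=(0.5, 1.5, -90, 90), shallow=(1.5, 2.5, -90, 90))
        res = bootstrap_deltaG([traj, traj.copy()], [states, states.copy()],
                               basins, 1.0, 1.0, B=25, seed=1)
        assert res.ci_range == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_gives_identical_intervals(self, two_well_states):
        cfg, cvs, states = two_well_states
        basins = ms.default_basins()
        kwargs = dict(B=20, level=0.95, seed=6, n_states=60, kT=cfg.kT)
        a = bootstrap_deltaG(cvs.trajectories[:20], states[:20], basins, 4.5,
                             cvs.frame_interval, **kwargs)
        b = bootstrap_deltaG(cvs.trajectories[:20], states[:20], basins, 4.5,
                             cvs.frame_interval, **kwargs)
        assert (a.ci_lower, a.ci_upper) == (b.ci_lower, b.ci_upper)

    def test_json_output_round_trips(self, tmp_path, two_well_states):
        import json

        cfg, cvs, states = two_well_states
        res = bootstrap_deltaG(cvs.trajectories[:10], states[:10],
                               ms.default_basins(), 4.5, cvs.frame_interval,
                               kT=cfg.kT, B=10, seed=2, n_states=60)
        path = tmp_path / "dg.json"
        res.to_json(path)
        data = json.loads(path.read_text())
        assert data["delta_G_kcal_mol"] == res.delta_g
        assert data["n_replicates"] == 10


class TestBasinProposal:
    def test_two_well_oracle_landscape_yields_disjoint_basins(self):
        cfg = ms.two_well_config()
        edges = (np.linspace(0.5, 2.6, 41), np.linspace(-30, 75, 41))
        p = ms.exact_histogram_masses(cfg, *edges)
        land = FreeEnergyLandscape(edges[0], edges[1], p, cfg.kT)
        basins = propose_basins(land)
        # deep basin sits at smaller depth and contains the deep well center
        assert basins.deep[0] <= 1.15 <= basins.deep[1]
        assert basins.shallow[0] <= 1.80 <= basins.shallow[1]


class TestWaterCoordination:
    def _system(self, waters):
        entries = [("C1", "LIG", 1, "ligand_heavy"), ("C2", "LIG", 1, "ligand_heavy")]
        entries += [("O", "HOH", 10 + i, "water_oxygen") for i in range(len(waters))]
        topo = make_topology(entries)
        targets = np.array([[2.0, 2.0, 2.0], [2.4, 2.0, 2.0]])
        xyz = np.concatenate([targets, waters])[None].astype(float)
        return topo, Trajectory(xyz, 1.0, np.array([5.0, 5.0, 5.0]))

    def test_no_waters_gives_zero(self):
        topo, traj = self._system(np.empty((0, 3)))
        counts = count_coordinating_waters(traj, topo, topo.indices("ligand_heavy"))
        assert counts[0] == 0

    def test_single_water_in_range_counts_once(self):
        topo, traj = self._system(np.array([[2.3, 2.0, 2.0]]))  # near both targets
        counts = count_coordinating_waters(traj, topo, topo.indices("ligand_heavy"))
        assert counts[0] == 1

    def test_matches_brute_force_minimum_image_loop(self):
        rng = np.random.default_rng(9)
        waters = rng.uniform(0, 5, size=(80, 3))
        topo, traj = self._system(waters)
        counts = count_coordinating_waters(traj, topo, topo.indices("ligand_heavy"),
                                           d_max=0.9)
        box = traj.box
        targets = traj.xyz[0, :2]
        expected = 0
        for w in traj.xyz[0, 2:]:
            hit = False
            for t in targets:
                delta = w - t
                delta -= box * np.round(delta / box)
                if np.linalg.norm(delta) <= 0.9:
                    hit = True
            expected += hit
        assert counts[0] == expected
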