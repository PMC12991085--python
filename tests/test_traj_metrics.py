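"""Trajectory geometry metrics against constructions and brute-force oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from hcnfep.synthetic import ToyTrajectorySpec, gen_toy_trajectory
from hcnfep.traj_metrics import (
    MetricSeries,
    TrajectoryView,
    com_displacement,
    hbond_metrics,
    helix_angle,
    kabsch_superpose,
    lid_distance,
    ligand_rmsd,
)


def rotation(axis, degrees):
    return Rotation.from_rotvec(
        np.asarray(axis, float) / np.linalg.norm(axis) * np.radians(degrees)
    ).as_matrix()


def quaternion_search_rmsd(mobile, reference, n_grid=3000, seed=0):
    """Brute-force minimum RMSD: random rotation grid + local refinement."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def rmsd_of(rotvec):
        r = Rotation.from_rotvec(rotvec).as_matrix()
        d = mob @ r.T - ref
        return np.sqrt(np.mean(np.sum(d * d, axis=1)))

    grid = Rotation.random(n_grid, random_state=seed).as_rotvec()
    best = min(grid, key=rmsd_of)
    res = minimize(rmsd_of, best, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20_000})
    return res.fun


def simple_view(n_frames, builder):
    """Build a TrajectoryView from a per-frame coordinate builder."""
    coords = np.stack([builder(f) for f in range(n_frames)])
    return coords


class TestKabsch:
    def test_identity_on_equal_configurations(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(trans, 0.0, atol=1e-12)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_exact_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(12, 3))
        r_true = rotation([0, 0, 1], 90)
        mobile = ref @ r_true.T + np.array([5.0, -3.0, 2.0])
        rot, trans, rmsd = kabsch_superpose(mobile, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(mobile @ rot.T + trans, ref, atol=1e-10)

    def test_proper_rotation_even_for_reflected_input(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(8, 3))
        mirrored = ref * np.array([1.0, 1.0, -1.0])
        rot, _, _ = kabsch_superpose(mirrored, ref)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_matches_quaternion_grid_oracle_on_noisy_instances(self):
        rng = np.random.default_rng(3)
        for trial in range(20):
            ref = rng.normal(size=(50, 3))
            r_true = Rotation.random(random_state=100 + trial).as_matrix()
            mobile = (ref + rng.normal(0, 0.1, ref.shape)) @ r_true.T + rng.normal(size=3)
            _, _, rmsd = kabsch_superpose(mobile, ref)
            oracle = quaternion_search_rmsd(mobile, ref, seed=trial)
            assert rmsd == pytest.approx(oracle, abs=1e-6)
            assert rmsd <= oracle + 1e-9  # Kabsch is the true minimum

    def test_too_few_or_collinear_atoms_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line)


class TestLigandMetrics:
    def _protein_ligand_view(self, ligand_offsets):
        """Static non-degenerate protein scaffold; ligand shifted per frame."""
        rng = np.random.default_rng(7)
        sheet = rng.normal(size=(10, 3)) * 5.0
        ligand0 = rng.normal(size=(4, 3)) + np.array([8.0, 0.0, 0.0])
        frames = []
        for off in ligand_offsets:
            frames.append(np.vstack([sheet, ligand0 + np.asarray(off)]))
        return TrajectoryView(
            coordinates=np.stack(frames),
            selections={"sheet_ca": np.arange(10), "ligand": np.arange(10, 14)},
        )

    def test_static_trajectory_all_zero(self):
        view = self._protein_ligand_view([(0, 0, 0)] * 5)
        assert np.allclose(ligand_rmsd(view).values, 0.0, atol=1e-10)
        assert np.allclose(com_displacement(view).values, 0.0, atol=1e-10)

    def test_global_rigid_motion_removed_by_alignment(self):
        rng = np.random.default_rng(11)
        base = self._protein_ligand_view([(0, 0, 0)] * 6).coordinates[0]
        frames = []
        for f in range(6):
            r = Rotation.random(random_state=f).as_matrix()
            frames.append(base @ r.T + rng.normal(size=3) * 10)
        view = TrajectoryView(
            coordinates=np.stack(frames),
            selections={"sheet_ca": np.arange(10), "ligand": np.arange(10, 14)},
        )
        assert np.allclose(ligand_rmsd(view).values, 0.0, atol=1e-8)
        assert np.allclose(com_displacement(view).values, 0.0, atol=1e-8)

    def test_uniform_ligand_translation_equals_its_magnitude(self):
        """A 2 Å shift of the whole ligand gives RMSD = COM displacement = 2."""
        view = self._protein_ligand_view([(0, 0, 0)] + [(0, 0, 2.0)] * 4)
        np.testing.assert_allclose(ligand_rmsd(view).values[1:], 2.0, atol=1e-10)
        np.testing.assert_allclose(com_displacement(view).values[1:], 2.0, atol=1e-10)

    def test_com_345_triangle(self):
        view = self._protein_ligand_view([(0, 0, 0), (3.0, 4.0, 0.0)])
        assert com_displacement(view).values[1] == pytest.approx(5.0, abs=1e-10)

    def test_random_walk_matches_independent_com_recomputation(self):
        spec = ToyTrajectorySpec(n_frames=30, ligand_motion="random_walk",
                                 step_sigma=0.3, seed=5)
        traj, truth = gen_toy_trajectory(spec)
        series = com_displacement(traj)
        # independent oracle: plain mean over ligand atoms, no alignment code
        lig = traj.selections["ligand"]
        coms = traj.coordinates[:, lig, :].mean(axis=1)
        oracle = np.linalg.norm(coms - coms[0], axis=1)
        np.testing.assert_allclose(series.values, oracle, atol=1e-8)
        np.testing.assert_allclose(series.values, truth["com_displacement"].values,
                                   atol=1e-8)

    def test_reference_frame_out_of_range(self):
        view = self._protein_ligand_view([(0, 0, 0)] * 3)
        with pytest.raises(IndexError):
            ligand_rmsd(view, reference_frame=3)


class TestLidDistance:
    def test_explicit_distances(self):
        coords = np.zeros((2, 2, 3))
        coords[0, 1] = [0.0, 0.0, 7.0]  # frame 0: 7 Å apart; frame 1: coincident
        view = TrajectoryView(coordinates=coords,
                              selections={"lid_pair": np.array([0, 1])})
        np.testing.assert_allclose(lid_distance(view).values, [7.0, 0.0])

    def test_monotone_opening_schedule(self):
        spec = ToyTrajectorySpec(n_frames=20, lid_schedule=(5.0, 15.0))
        traj, truth = gen_toy_trajectory(spec)
        series = lid_distance(traj)
        np.testing.assert_allclose(series.values, truth["lid_distance"].values,
                                   atol=1e-10)
        assert np.all(np.diff(series.values) > 0)

    def test_missing_lid_pair(self):
        view = TrajectoryView(coordinates=np.zeros((1, 3, 3)))
        with pytest.raises(KeyError):
            lid_distance(view)


def rod(n, direction, spacing=1.5, origin=(0.0, 0.0, 0.0)):
    d = np.asarray(direction, float) / np.linalg.norm(direction)
    return np.asarray(origin) + np.outer(np.arange(n) * spacing, d)


class TestHelixAngle:
    def _view(self, helix_b, helix_c):
        coords = np.vstack([helix_b, helix_c])[None]
        nb = len(helix_b)
        return TrajectoryView(
            coordinates=coords,
            selections={"helixB_ca": np.arange(nb),
                        "helixC_ca": np.arange(nb, nb + len(helix_c))},
        )

    def test_parallel_rods_zero_degrees(self):
        view = self._view(rod(6, [0, 0, 1]), rod(6, [0, 0, 1], origin=(8, 0, 0)))
        assert helix_angle(view).values[0] == pytest.approx(0.0, abs=1e-8)

    def test_orthogonal_rods_ninety_degrees(self):
        view = self._view(rod(6, [1, 0, 0]), rod(6, [0, 0, 1], origin=(0, 8, 0)))
        assert helix_angle(view).values[0] == pytest.approx(90.0, abs=1e-8)

    def test_constructed_helix_tilt_recovered(self):
        """Ideal α-helix rods at a 30° relative tilt read back as 30° ± 0.5°."""
        spec = ToyTrajectorySpec(n_frames=5, helix_tilt_schedule=30.0)
        traj, truth = gen_toy_trajectory(spec)
        series = helix_angle(traj)
        np.testing.assert_allclose(series.values, 30.0, atol=0.5)
        np.testing.assert_allclose(series.values, truth["helix_angle"].values,
                                   atol=0.5)

    def test_symmetric_and_order_invariant(self):
        b, c = rod(7, [1, 0, 1]), rod(7, [0, 1, 2], origin=(9, 0, 0))
        base = helix_angle(self._view(b, c)).values[0]
        swapped = helix_angle(self._view(c, b)).values[0]
        reversed_b = helix_angle(self._view(b[::-1], c)).values[0]
        assert base == pytest.approx(swapped, abs=1e-9)
        assert base == pytest.approx(reversed_b, abs=1e-9)

    def test_angle_folded_into_first_quadrant(self):
        view = self._view(rod(6, [0, 0, 1]), rod(6, [0, 1, 5], origin=(8, 0, 0)))
        val = helix_angle(view).values[0]
        assert 0.0 <= val <= 90.0

    def test_degenerate_inertia_tensor_names_frame(self):
        # a perfectly symmetric square has two equal small moments
        square = np.array([[1, 1, 0], [-1, 1, 0], [-1, -1, 0], [1, -1, 0]], float)
        view = self._view(square, rod(6, [0, 0, 1], origin=(8, 0, 0)))
        with pytest.raises(ValueError, match="frame 0"):
            helix_angle(view)


class TestHbondMetrics:
    def _view(self, d, h, a):
        coords = np.array([[d, h, a]], dtype=float)
        return TrajectoryView(coordinates=coords,
                              selections={"hbond_triplets": [(0, 1, 2)]})

    def test_collinear_geometry_present(self):
        series, flags, occ = hbond_metrics(
            self._view([0, 0, 0], [1, 0, 0], [2.9, 0, 0]))
        assert series[0].values[0] == pytest.approx(2.9)
        assert flags[0, 0]
        assert occ[0] == 1.0

    def test_distance_failure(self):
        _, flags, _ = hbond_metrics(self._view([0, 0, 0], [1, 0, 0], [3.1, 0, 0]))
        assert not flags[0, 0]

    @pytest.mark.parametrize("deviation,expected", [(25.0, False), (15.0, True)])
    def test_angle_criterion_at_fixed_distance(self, deviation, expected):
        """Acceptor rotated to the stated D–H–A deviation at 2.8 Å."""
        dev = np.radians(deviation)
        d_da = 2.8
        r = -np.cos(dev) + np.sqrt(np.cos(dev) ** 2 - 1 + d_da**2)
        a = np.array([1, 0, 0]) + r * np.array([np.cos(dev), np.sin(dev), 0.0])
        assert np.linalg.norm(a) == pytest.approx(d_da, abs=1e-12)
        _, flags, _ = hbond_metrics(self._view([0, 0, 0], [1, 0, 0], a))
        assert bool(flags[0, 0]) is expected

    def test_schedule_verdicts_match_construction(self):
        spec = ToyTrajectorySpec(
            n_frames=4,
            hbond_distance_schedule=np.array([2.8, 3.2, 2.8, 2.9]),
            hbond_deviation_schedule=np.array([5.0, 5.0, 25.0, 19.9]),
        )
        traj, truth = gen_toy_trajectory(spec)
        series, flags, occ = hbond_metrics(traj)
        np.testing.assert_allclose(series[0].values, truth["hbond_distance"].values,
                                   atol=1e-9)
        assert list(flags[0]) == [True, False, False, True]
        assert occ[0] == pytest.approx(0.5)

    def test_overlapping_triplet_rejected(self):
        view = TrajectoryView(coordinates=np.zeros((1, 3, 3)),
                              selections={"hbond_triplets": [(0, 0, 2)]})
        with pytest.raises(ValueError, match="overlapping"):
            hbond_metrics(view)


class TestRigidMotionInvariance:
    def test_frame_internal_metrics_invariant_per_frame(self):
        """Lid distance, helix angle and H-bond geometry are unchanged when
        every frame is independently rotated and translated."""
        spec = ToyTrajectorySpec(n_frames=8, ligand_motion="linear",
                                 drift=(0.05, 0, 0), lid_schedule=(6, 9),
                                 helix_tilt_schedule=(10, 40), seed=2)
        traj, _ = gen_toy_trajectory(spec)
        moved = traj.coordinates.copy()
        rng = np.random.default_rng(4)
        for f in range(traj.n_frames):
            r = Rotation.random(random_state=50 + f).as_matrix()
            moved[f] = traj.coordinates[f] @ r.T + rng.normal(size=3) * 20
        moved_view = TrajectoryView(coordinates=moved, selections=traj.selections,
                                    frame_times=traj.frame_times)
        for metric in (lid_distance, helix_angle):
            np.testing.assert_allclose(metric(moved_view).values,
                                       metric(traj).values, atol=1e-8)
        _, flags_a, _ = hbond_metrics(traj)
        _, flags_b, _ = hbond_metrics(moved_view)
        np.testing.assert_array_equal(flags_a, flags_b)
        # superposition-based metrics also survive per-frame rigid motion
        for metric in (ligand_rmsd, com_displacement):
            np.testing.assert_allclose(metric(moved_view).values,
                                       metric(traj).values, atol=1e-7)


def test_metric_series_shape_guard():
    with pytest.raises(ValueError):
        MetricSeries("x", np.zeros(3), np.zeros(4))
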