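import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kinpocket import (
    FrameSeries,
    ScalarSeries,
    center_of_mass,
    distribution,
    kabsch_superpose,
    min_group_distance,
    pocket_size_series,
    rmsd_series,
    rmsf,
)
from conftest import selection
from oracles import brute_min_distance, quaternion_superpose_rmsd


def _rotation_z(deg):
    t = np.deg2rad(deg)
    return np.array([
        [np.cos(t), -np.sin(t), 0.0],
        [np.sin(t), np.cos(t), 0.0],
        [0.0, 0.0, 1.0],
    ])


class TestCenterOfMass:
    def test_unit_masses_symmetric(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        com = center_of_mass(coords, selection([0, 1]), np.ones(2))
        assert np.allclose(com, [1.0, 0, 0])

    def test_mass_weighting(self):
        coords = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        com = center_of_mass(coords, selection([0, 1]), np.array([1.0, 3.0]))
        assert np.allclose(com, [3.0, 0, 0])

    def test_single_atom_is_identity(self):
        coords = np.array([[1.0, 2.0, 3.0], [9.0, 9.0, 9.0]])
        com = center_of_mass(coords, selection([0]), np.array([12.0, 1.0]))
        assert np.allclose(com, [1.0, 2.0, 3.0])

    def test_empty_selection_raises(self):
        with pytest.raises(ValueError, match="empty"):
            center_of_mass(np.zeros((3, 3)), selection([]), np.ones(3))


class TestMinGroupDistance:
    def test_three_four_five(self):
        coords = np.array([[0.0, 0, 0], [3.0, 4.0, 0]])
        d = min_group_distance(coords, selection([0]), selection([1]))
        assert d == pytest.approx(5.0)

    def test_minimum_wins(self):
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0], [2.0, 0, 0]])
        d = min_group_distance(coords, selection([0, 1]), selection([2]))
        assert d == pytest.approx(2.0)

    def test_overlapping_selections_raise(self):
        with pytest.raises(ValueError, match="overlap"):
            min_group_distance(np.zeros((3, 3)), selection([0, 1]),
                               selection([1, 2]))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_brute_force_pair_scan(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(-5, 5, size=(14, 3))
        idx_a, idx_b = list(range(6)), list(range(6, 14))
        d = min_group_distance(coords, selection(idx_a), selection(idx_b))
        assert d == pytest.approx(brute_min_distance(coords, idx_a, idx_b))


class TestPocketSize:
    def test_constant_planted_separation(self):
        group = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1.0, 0]])
        frame = np.vstack([group, group + np.array([20.5, 0, 0])])
        traj = FrameSeries(np.repeat(frame[None], 4, axis=0), dt=10.0)
        series = pocket_size_series(
            traj, selection([3, 4, 5]), selection([0, 1, 2]), np.ones(6)
        )
        assert np.allclose(series.values, 20.5)

    def test_translation_along_axis_adds_exactly(self):
        group = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1.0, 0]])
        base = np.vstack([group, group + np.array([20.0, 0, 0])])
        shifted = base.copy()
        shifted[3:] += np.array([2.5, 0, 0])  # along the COM-COM axis
        traj = FrameSeries(np.stack([base, shifted]), dt=1.0)
        series = pocket_size_series(
            traj, selection([3, 4, 5]), selection([0, 1, 2]), np.ones(6)
        )
        assert series.values[1] - series.values[0] == pytest.approx(2.5)

    def test_recovers_planted_breathing_distances(self, small_scene):
        from kinpocket import resolve_selection
        _, topology, frames, truth = small_scene
        series = pocket_size_series(
            frames,
            resolve_selection(topology, "resid 759:761"),
            resolve_selection(topology, "resid 790:792"),
            topology.masses,
        )
        assert np.abs(series.values - truth.pocket_distances).max() < 1e-6


class TestKabsch:
    def _cloud(self, rng, n=20):
        return rng.uniform(-4, 4, size=(n, 3))

    def test_rigid_motion_is_fully_removable(self):
        rng = np.random.default_rng(1)
        ref = self._cloud(rng)
        mob = ref @ _rotation_z(90).T + np.array([5.0, 5.0, 5.0])
        _, _, rmsd = kabsch_superpose(mob, ref, selection(range(len(ref))))
        assert rmsd <= 1e-8

    def test_identity_on_identical_structures(self):
        rng = np.random.default_rng(2)
        ref = self._cloud(rng)
        rot, trans, rmsd = kabsch_superpose(ref, ref, selection(range(len(ref))))
        assert rmsd <= 1e-10
        assert np.allclose(rot, np.eye(3), atol=1e-8)

    def test_gaussian_noise_closed_form(self):
        # E[rmsd^2] = 3 sigma^2 for small iid coordinate noise.
        rng = np.random.default_rng(3)
        sigma = 0.1
        ref = rng.uniform(-10, 10, size=(500, 3))
        mob = ref + rng.normal(0, sigma, ref.shape)
        _, _, rmsd = kabsch_superpose(mob, ref, selection(range(500)))
        assert rmsd == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_too_few_or_collinear_atoms_raise(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError, match=">= 3"):
            kabsch_superpose(line[:2], line[:2], selection([0, 1]))
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line, selection(range(4)))

    def test_proper_rotation_no_reflection(self):
        rng = np.random.default_rng(4)
        ref = self._cloud(rng)
        mob = self._cloud(rng)
        rot, _, _ = kabsch_superpose(mob, ref, selection(range(len(ref))))
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_aligned_rmsd_never_exceeds_unaligned(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.uniform(-3, 3, size=(12, 3))
        mob = rng.uniform(-3, 3, size=(12, 3))
        _, _, aligned = kabsch_superpose(mob, ref, selection(range(12)))
        unaligned = np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1)))
        assert aligned <= unaligned + 1e-9


class TestRmsdSeries:
    def test_rigid_body_trajectory_is_all_zero(self):
        rng = np.random.default_rng(5)
        ref = rng.uniform(-5, 5, size=(15, 3))
        frames = [ref]
        for i in range(4):
            frames.append(ref @ _rotation_z(30 * (i + 1)).T + rng.uniform(-3, 3, 3))
        traj = FrameSeries(np.stack(frames), dt=1.0)
        series = rmsd_series(traj, selection(range(15)))
        assert np.all(series.values <= 1e-8)

    def test_single_displaced_atom_equals_d_over_sqrt_n(self):
        rng = np.random.default_rng(6)
        n, d = 25, 1.7
        ref = rng.uniform(-5, 5, size=(n, 3))
        frame1 = ref.copy()
        frame1[0] += np.array([d, 0, 0])
        traj = FrameSeries(np.stack([ref, frame1]), dt=1.0)
        series = rmsd_series(traj, fit_sel=selection(range(1, n)),
                             measure_sel=selection(range(n)))
        assert series.values[1] == pytest.approx(d / np.sqrt(n), abs=1e-10)

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(7)
        ref = rng.uniform(-5, 5, size=(30, 3))
        frames = [ref + rng.normal(0, 0.4, ref.shape) for _ in range(6)]
        traj = FrameSeries(np.stack([ref] + frames), dt=1.0)
        series = rmsd_series(traj, selection(range(30)))
        for i in range(1, traj.n_frames):
            expected = quaternion_superpose_rmsd(traj[i], ref)
            assert series.values[i] == pytest.approx(expected, abs=1e-6)


class TestRmsf:
    def test_static_trajectory_is_all_zero(self):
        rng = np.random.default_rng(8)
        frame = rng.uniform(-5, 5, size=(10, 3))
        traj = FrameSeries(np.repeat(frame[None], 5, axis=0), dt=1.0)
        profile = rmsf(traj, selection(range(10)))
        assert np.all(profile.values <= 1e-10)

    def test_single_frame_raises(self):
        with pytest.raises(ValueError, match="single frame"):
            rmsf(FrameSeries(np.zeros((1, 4, 3)), dt=1.0),
                 selection(range(4)))

    def test_sigma_scaling_is_linear(self):
        rng = np.random.default_rng(9)
        base = rng.uniform(-5, 5, size=(8, 3))
        n_frames = 3000

        def jittered(sigma, seed):
            r = np.random.default_rng(seed)
            coords = np.repeat(base[None], n_frames, axis=0)
            coords[:, 0, :] += r.normal(0, sigma, (n_frames, 3))
            return FrameSeries(coords, dt=1.0)

        fit = selection(range(1, 8))
        r1 = rmsf(jittered(0.25, 10), fit, selection([0])).values[0]
        r2 = rmsf(jittered(0.50, 10), fit, selection([0])).values[0]
        assert r2 / r1 == pytest.approx(2.0, rel=0.05)
        assert r1 == pytest.approx(0.25 * np.sqrt(3), rel=0.05)


class TestDistribution:
    def test_constant_series_single_bin(self):
        dist = distribution(ScalarSeries(np.full(10, 4.2), dt=1.0), 0.1)
        assert len(dist.probabilities) == 1
        assert dist.probabilities[0] == pytest.approx(1.0)

    def test_two_equal_bins(self):
        dist = distribution(ScalarSeries(np.array([1.0, 1, 3, 3]), dt=1.0), 2.0)
        assert np.allclose(dist.probabilities, [0.5, 0.5])

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            distribution(ScalarSeries(np.array([]), dt=1.0), 0.1)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_sums_to_one_and_fraction_below_counts(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0.0, 15.0, size=200)
        series = ScalarSeries(values, dt=1.0)
        dist = distribution(series, 0.1)
        assert dist.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        threshold = 3.5  # multiple of the bin width: exact edge
        expected = np.mean(values < threshold)
        assert dist.fraction_below(threshold) == pytest.approx(expected, abs=1e-12)
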