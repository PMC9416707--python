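import numpy as np
import pytest
from scipy import stats

import driftwalk as dw
from driftwalk import (
    SimulationConfig,
    free_space,
    matrix_cavity,
    move_legal,
    propose_displacement,
    sample_start,
    simulate_ensemble,
    simulate_trajectory,
)
from driftwalk.structure import BinaryStructure


def sampling_oracle(structure, p0, p1, spacing):
    """Dense point sampling along the segment, each sample classified by pixel."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = np.hypot(*(p1 - p0))
    n = max(2, int(np.ceil(length / spacing)) + 1)
    ts = np.linspace(0.0, 1.0, n)
    pts = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    H, W = structure.shape
    ix = np.floor(pts[:, 0]).astype(int) % W
    iy = np.floor(pts[:, 1]).astype(int) % H
    return not structure.obstacle[iy, ix].any()


class TestSampleStart:
    def test_single_matrix_pixel_always_chosen(self, rng):
        obstacle = np.ones((8, 8), dtype=bool)
        obstacle[3, 5] = False
        structure = BinaryStructure(obstacle)
        for _ in range(10):
            assert np.array_equal(sample_start(structure, rng), [5.5, 3.5])

    def test_all_obstacle_structure_is_an_error(self, rng):
        with pytest.raises(ValueError, match="no matrix"):
            sample_start(BinaryStructure(np.ones((4, 4), dtype=bool)), rng)

    def test_uniform_over_matrix_pixels(self, rng):
        structure = free_space(4, 4)
        draws = 32_000
        counts = np.zeros(16)
        for _ in range(draws):
            x, y = sample_start(structure, rng)
            counts[int(y) * 4 + int(x)] += 1
        assert stats.chisquare(counts).pvalue > 1e-4

    def test_start_lies_in_matrix_pixel(self, small_obstacle_structure, rng):
        for _ in range(200):
            x, y = sample_start(small_obstacle_structure, rng)
            assert not small_obstacle_structure.obstacle[int(y), int(x)]


class TestProposeDisplacement:
    def test_zero_sigma_gives_exact_drift(self, rng):
        d = propose_displacement(rng, 0.0, (0.3, -0.2))
        assert np.array_equal(d, [0.3, -0.2])

    def test_moments_without_drift(self):
        rng = np.random.default_rng(7)
        sigma = 0.01
        d = propose_displacement(rng, sigma, (0.0, 0.0), size=1_000_000)
        se = sigma / np.sqrt(len(d))
        assert np.all(np.abs(d.mean(axis=0)) < 4 * se)
        assert np.mean((d**2).sum(axis=1)) == pytest.approx(sigma**2, rel=0.01)

    def test_mean_squared_norm_with_drift(self):
        rng = np.random.default_rng(8)
        sigma, lam = 0.01, 0.02
        d = propose_displacement(rng, sigma, (lam, 0.0), size=1_000_000)
        assert np.mean((d**2).sum(axis=1)) == pytest.approx(sigma**2 + lam**2, rel=0.01)


class TestMoveLegal:
    def test_endpoint_in_obstacle_is_illegal(self):
        obstacle = np.zeros((8, 8), dtype=bool)
        obstacle[4, 4] = True
        structure = BinaryStructure(obstacle)
        assert not move_legal(structure, (2.5, 2.5), (4.5, 4.5))

    def test_move_within_one_matrix_pixel_is_legal(self, small_obstacle_structure):
        iy, ix = np.argwhere(small_obstacle_structure.matrix)[0]
        assert move_legal(
            small_obstacle_structure, (ix + 0.2, iy + 0.2), (ix + 0.8, iy + 0.8)
        )

    def test_crossing_a_one_pixel_wall_is_illegal(self):
        obstacle = np.zeros((8, 8), dtype=bool)
        obstacle[:, 4] = True  # vertical wall
        structure = BinaryStructure(obstacle)
        assert not move_legal(structure, (3.5, 2.5), (5.5, 2.7))

    def test_start_in_obstacle_raises(self):
        obstacle = np.zeros((4, 4), dtype=bool)
        obstacle[1, 1] = True
        with pytest.raises(ValueError, match="obstacle"):
            move_legal(BinaryStructure(obstacle), (1.5, 1.5), (0.5, 0.5))

    def test_periodic_wrap_detects_obstacle_across_boundary(self):
        obstacle = np.zeros((8, 8), dtype=bool)
        obstacle[3, 0] = True
        structure = BinaryStructure(obstacle)
        # segment leaves the right edge and wraps onto column 0
        assert not move_legal(structure, (7.5, 3.5), (8.5, 3.5))
        assert move_legal(structure, (7.5, 5.5), (8.5, 5.5))

    def test_oversized_segment_warns_but_is_evaluated(self, small_obstacle_structure):
        iy, ix = np.argwhere(small_obstacle_structure.matrix)[0]
        with pytest.warns(UserWarning, match="period"):
            move_legal(small_obstacle_structure, (ix + 0.5, iy + 0.5), (ix + 200.5, iy + 0.5))

    def test_agrees_with_dense_sampling_oracle(self):
        """Exact traversal vs dense sampling on 10^4 random segments.

        The traversal can never miss a crossed pixel, so any disagreement
        must be a sampling miss of a sub-spacing corner clip; those are
        re-checked at 100x finer spacing and must all resolve.
        """
        rng = np.random.default_rng(99)
        structures = [
            dw.generate_artificial(rho, 32, 32, size_dist=("lognormal", 2.0, 0.4), seed=s)
            for rho, s in [(0.5, 1), (0.7, 2), (0.9, 3)]
        ]
        n_checked = 0
        unresolved = []
        while n_checked < 10_000:
            structure = structures[n_checked % len(structures)]
            matrix_idx = np.argwhere(structure.matrix)
            iy, ix = matrix_idx[rng.integers(len(matrix_idx))]
            p0 = np.array([ix, iy]) + rng.random(2)
            p1 = p0 + rng.uniform(-2.0, 2.0, size=2)
            exact = move_legal(structure, p0, p1)
            sampled = sampling_oracle(structure, p0, p1, spacing=0.01)
            n_checked += 1
            if exact and not sampled:
                pytest.fail("traversal missed an obstacle the sampler found")
            if sampled and not exact:
                if sampling_oracle(structure, p0, p1, spacing=1e-4) is not False:
                    unresolved.append((p0, p1))
        assert not unresolved


class TestSimulate:
    def test_ballistic_free_space_is_exact(self):
        structure = free_space(64, 64)
        config = SimulationConfig(
            sigma=0.0, drift=(0.3, 0.0), n_trajectories=1, n_steps=500, seed=0
        )
        traj = simulate_trajectory(structure, config)
        expected = traj.start + np.outer(np.arange(501) * 0.3, [1.0, 0.0])
        assert np.allclose(traj.positions, expected, atol=1e-9)

    def test_enclosed_cavity_rejects_every_exiting_step(self):
        # sigma = 0 with a super-pixel drift: every proposal leaves the
        # 1x1 cavity, so every step is rejected and the walker is frozen
        structure = matrix_cavity(16, 16, cavity=1)
        config = SimulationConfig(
            sigma=0.0, drift=(1.5, 0.0), n_trajectories=1, n_steps=2000, seed=4
        )
        traj = simulate_trajectory(structure, config, keep_accepted=True)
        assert not traj.accepted.any()
        assert np.all(traj.positions == traj.positions[0])

    def test_cavity_displacement_bounded_by_cavity_diameter(self):
        structure = matrix_cavity(16, 16, cavity=3)
        config = SimulationConfig(
            sigma=0.4, drift=(0.1, 0.0), n_trajectories=4, n_steps=5000, seed=5
        )
        for traj in simulate_ensemble(structure, config):
            assert np.sqrt(traj.squared_displacement().max()) <= 3 * np.sqrt(2)

    def test_wrapped_positions_never_inside_obstacles(self, small_obstacle_structure):
        config = SimulationConfig(
            sigma=0.2, drift=(0.05, 0.0), n_trajectories=10, n_steps=5000, seed=6
        )
        H, W = small_obstacle_structure.shape
        for traj in simulate_ensemble(small_obstacle_structure, config):
            ix = np.floor(traj.positions[:, 0]).astype(int) % W
            iy = np.floor(traj.positions[:, 1]).astype(int) % H
            assert not small_obstacle_structure.obstacle[iy, ix].any()

    def test_ensemble_reproducible_and_seed_sensitive(self, small_obstacle_structure):
        config = SimulationConfig(
            sigma=0.05, drift=(0.0, 0.0), n_trajectories=3, n_steps=200, seed=12
        )
        a = simulate_ensemble(small_obstacle_structure, config)
        b = simulate_ensemble(small_obstacle_structure, config)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.positions, tb.positions)
        other = simulate_ensemble(
            small_obstacle_structure,
            SimulationConfig(
                sigma=0.05, drift=(0.0, 0.0), n_trajectories=3, n_steps=200, seed=13
            ),
        )
        assert not np.array_equal(a[0].positions, other[0].positions)

    def test_single_trajectory_matches_first_substream(self, small_obstacle_structure):
        config = SimulationConfig(
            sigma=0.05, drift=(0.0, 0.0), n_trajectories=1, n_steps=100, seed=3
        )
        ensemble = simulate_ensemble(small_obstacle_structure, config)
        child = np.random.SeedSequence(3).spawn(1)[0]
        alone = simulate_trajectory(
            small_obstacle_structure, config, rng=np.random.default_rng(child)
        )
        assert np.array_equal(ensemble[0].positions, alone.positions)

    def test_free_space_msd_matches_sigma_squared_t(self):
        structure = free_space(256, 256)
        config = SimulationConfig(
            sigma=0.01, drift=(0.0, 0.0), n_trajectories=500, n_steps=2000, seed=21
        )
        trajs = simulate_ensemble(structure, config, record_steps=[0, 2000])
        msd_end = np.mean([t.squared_displacement()[-1] for t in trajs])
        assert msd_end == pytest.approx(config.sigma**2 * 2000, rel=0.1)

    def test_free_space_with_drift_crossover(self):
        """MSD = sigma^2 t + Lambda^2 t^2: alpha ~ 1 early, ~ 2 late."""
        structure = free_space(256, 256)
        sigma, lam = 0.1, 0.003  # crossover t* = sigma^2 / lam^2 ~ 1.1e3
        config = SimulationConfig(
            sigma=sigma, drift=(lam, 0.0), n_trajectories=300, n_steps=100_000, seed=22
        )
        record = dw.log_spaced_steps(100_000, per_decade=20)
        trajs = simulate_ensemble(structure, config, record_steps=record)
        msd = dw.ensemble_msd(trajs)
        early = dw.fit_anomalous_exponent(msd, window=(10, 100))
        late = dw.fit_anomalous_exponent(msd, window=(20_000, 100_000))
        assert early.alpha == pytest.approx(1.0, abs=0.1)
        assert late.alpha == pytest.approx(2.0, abs=0.1)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(sigma=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(n_trajectories=0)
        with pytest.raises(ValueError):
            SimulationConfig(n_steps=0)
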