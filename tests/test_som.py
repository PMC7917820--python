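import math

import numpy as np
import pytest

import spikesom as sp
from spikesom.som import lattice_coordinates


class TestNormalizeRange:
    def test_midpoint_maps_to_zero_and_extremes_to_unit(self):
        seqs = [np.array([[10.0], [20.0], [30.0]])]
        im = sp.normalize_range(seqs)
        assert im.sequences[0, :, 0] == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_channel_maps_to_zero_and_is_flagged(self):
        seqs = [np.full((5, 2), 3.0)]
        im = sp.normalize_range(seqs)
        assert np.all(im.sequences == 0.0)
        assert im.degenerate.all()

    def test_normalisation_pools_across_sequences(self, rng):
        a, b = rng.standard_normal((2, 101, 4))
        im = sp.normalize_range([a, b])
        pooled = im.sequences.reshape(-1, 4)
        assert np.allclose(pooled.min(axis=0), -1.0)
        assert np.allclose(pooled.max(axis=0), 1.0)

    def test_invert_roundtrips_to_1e9(self, rng):
        raw = rng.uniform(-50, 50, size=(3, 101, 6))
        im = sp.normalize_range(list(raw))
        back = im.invert(im.sequences)
        assert np.abs(back - raw).max() < 1e-9


class TestAssembleInputVectors:
    @pytest.mark.parametrize("subset,signals,dim", [
        ("whole", "both", 64), ("upper", "velocities_only", 8),
        ("lower", "angles_only", 6), ("whole", "angles_only", 32),
        ("upper", "both", 16),
    ])
    def test_dimensions(self, cohort_means, registry, subset, signals, dim):
        im = sp.assemble_input_vectors(cohort_means, registry, subset, signals)
        assert im.sequences.shape == (19, 101, dim)

    def test_angle_columns_precede_velocity_columns(self, cohort_means, registry):
        im = sp.assemble_input_vectors(cohort_means, registry, "upper", "both")
        assert all(n.endswith("_psi") for n in im.channel_names[:8])
        assert all(n.endswith("_phi") for n in im.channel_names[8:])

    def test_unknown_subset_rejected(self, cohort_means, registry):
        with pytest.raises(ValueError, match="unknown segment subset"):
            sp.assemble_input_vectors(cohort_means, registry, "arms", "both")


class TestDefaultGrid:
    def test_unit_count_follows_scaled_heuristic(self):
        rows, cols = sp.default_grid(1919, map_scale="big")
        target = 4 * math.ceil(5 * math.sqrt(1919))
        assert abs(rows * cols - target) / target < 0.05

    def test_isotropic_covariance_gives_square_grid(self, rng):
        data = rng.standard_normal((500, 5))
        rows, cols = sp.default_grid(500, data, "normal")
        assert abs(rows - cols) <= 1

    def test_small_sample_normal_scale(self):
        rows, cols = sp.default_grid(4, map_scale="normal")
        assert abs(rows * cols - 10) <= 1

    def test_anisotropic_data_elongates_grid(self, rng):
        data = rng.standard_normal((500, 2)) * np.array([10.0, 1.0])
        rows, cols = sp.default_grid(500, data, "normal")
        assert max(rows, cols) / min(rows, cols) > 2


class TestLattice:
    def test_hexagonal_nearest_neighbour_distance_is_one(self):
        xy = lattice_coordinates(5, 6, "hexagonal")
        d = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() == pytest.approx(1.0)

    def test_hexagonal_interior_units_have_six_neighbours(self):
        grid = sp.SOMGrid(rows=5, cols=6, weights=np.zeros((30, 2)))
        counts = [len(n) for n in grid.neighbour_lists()]
        assert max(counts) == 6
        interior = 2 * 6 + 2  # unit in row 2, col 2
        assert counts[interior] == 6


class TestInitLinear:
    def test_weights_lie_in_the_data_plane(self, rng):
        basis = rng.standard_normal((2, 8))
        coeffs = rng.standard_normal((200, 2))
        data = coeffs @ basis + 5.0
        grid = sp.init_linear(data, 4, 5)
        centred = grid.weights - data.mean(axis=0)
        # residual after projecting onto the plane spanned by the basis
        proj = centred @ np.linalg.pinv(basis) @ basis
        assert np.abs(centred - proj).max() < 1e-9

    def test_deterministic(self, rng):
        data = rng.standard_normal((100, 6))
        g1 = sp.init_linear(data, 3, 4)
        g2 = sp.init_linear(data, 3, 4)
        assert np.array_equal(g1.weights, g2.weights)

    def test_better_than_zero_init_on_centred_data(self, rng):
        data = rng.standard_normal((300, 5)) @ np.diag([3, 2, 1, 0.5, 0.1])
        data -= data.mean(axis=0)
        grid = sp.init_linear(data, 5, 5)
        zero = sp.SOMGrid(rows=5, cols=5, weights=np.zeros((25, 5)))
        assert sp.quantization_error(grid, data) <= sp.quantization_error(zero, data)


class TestFindBMU:
    def test_exact_weight_match(self, rng):
        grid = sp.SOMGrid(rows=3, cols=4, weights=rng.standard_normal((12, 5)))
        assert sp.find_bmu(grid, grid.weights[7]) == 7

    def test_tie_breaks_to_lowest_index(self):
        w = np.zeros((6, 2))
        w[2] = w[5] = [1.0, 1.0]
        grid = sp.SOMGrid(rows=2, cols=3, weights=w)
        assert sp.find_bmu(grid, [1.0, 1.0]) == 2

    def test_matches_exhaustive_scan(self, rng):
        grid = sp.SOMGrid(rows=5, cols=6, weights=rng.standard_normal((30, 4)))
        for v in rng.standard_normal((100, 4)):
            brute = min(range(30), key=lambda u: ((grid.weights[u] - v) ** 2).sum())
            assert sp.find_bmu(grid, v) == brute


class TestTraining:
    def test_single_repeated_input_converges_to_target(self):
        x = np.array([0.3, -0.7, 0.2])
        im = sp.normalize_range([np.tile(x, (101, 1))])
        # normalised input is constant -> all zeros; train on raw instead
        grid = sp.SOMGrid(rows=2, cols=2, weights=np.ones((4, 3)))
        im_raw = sp.InputMatrix(sequences=np.tile(x, (1, 101, 1)), ids=["s"],
                                channel_names=list("abc"), mins=np.zeros(3),
                                maxs=np.ones(3))
        cfg = sp.SOMConfig(phase1_epochs=5, phase2_epochs=10, seed=0)
        trained = sp.train_sequential(grid, im_raw, cfg)
        bmu = sp.find_bmu(trained, x)
        assert np.abs(trained.weights[bmu] - x).max() < 1e-3

    def test_separated_clusters_get_distinct_bmus(self, rng):
        a = rng.normal(0, 0.05, size=(101, 3)) + np.array([5.0, 0, 0])
        b = rng.normal(0, 0.05, size=(101, 3)) - np.array([5.0, 0, 0])
        im = sp.normalize_range([a, b])
        X = im.pooled()
        grid = sp.init_linear(X, 3, 4)
        trained = sp.train_sequential(grid, im, sp.SOMConfig(phase1_epochs=3,
                                                             phase2_epochs=5, seed=1))
        bmu_a = sp.find_bmu(trained, im.sequences[0].mean(axis=0))
        bmu_b = sp.find_bmu(trained, im.sequences[1].mean(axis=0))
        assert bmu_a != bmu_b

    def test_training_reduces_quantization_error(self, cohort_means, registry,
                                                 fast_som_config):
        im = sp.assemble_input_vectors(cohort_means, registry, "lower", "both")
        X = im.pooled()
        rows, cols = sp.default_grid(X.shape[0], X, "small")
        grid = sp.init_linear(X, rows, cols)
        trained = sp.train_sequential(grid, im, fast_som_config)
        assert sp.quantization_error(trained, X) <= sp.quantization_error(grid, X)

    def test_bit_reproducible_with_fixed_seed(self, rng):
        seqs = [rng.standard_normal((101, 4)) for _ in range(3)]
        im = sp.normalize_range(seqs)
        cfg = sp.SOMConfig(phase1_epochs=2, phase2_epochs=2, seed=42)
        g1 = sp.train_sequential(sp.init_linear(im.pooled(), 3, 3), im, cfg)
        g2 = sp.train_sequential(sp.init_linear(im.pooled(), 3, 3), im, cfg)
        assert np.array_equal(g1.weights, g2.weights)

    def test_nonfinite_input_rejected(self):
        bad = np.full((1, 101, 2), np.nan)
        im = sp.InputMatrix(sequences=bad, ids=["s"], channel_names=["a", "b"],
                            mins=np.zeros(2), maxs=np.ones(2))
        grid = sp.SOMGrid(rows=2, cols=2, weights=np.zeros((4, 2)))
        with pytest.raises(ValueError, match="non-finite"):
            sp.train_sequential(grid, im, sp.SOMConfig())

    def test_batch_training_also_reduces_qe(self, rng):
        seqs = [rng.standard_normal((101, 3)) for _ in range(4)]
        im = sp.normalize_range(seqs)
        X = im.pooled()
        grid = sp.init_linear(X, 4, 4)
        cfg = sp.SOMConfig(training="batch", phase1_epochs=5, phase2_epochs=5,
                           phase2_sigma=(1.5, 0.3))
        trained = sp.train_sequential(grid, im, cfg)
        assert sp.quantization_error(trained, X) <= sp.quantization_error(grid, X)


class TestUMatrix:
    def test_identical_weights_give_zeros(self):
        grid = sp.SOMGrid(rows=3, cols=3, weights=np.ones((9, 4)))
        assert np.allclose(sp.compute_umatrix(grid).values, 0.0)

    def test_two_unit_grid_single_neighbour(self):
        w = np.array([[0.0, 0.0], [3.5, 0.0]])
        grid = sp.SOMGrid(rows=1, cols=2, weights=w)
        assert sp.compute_umatrix(grid).values == pytest.approx([3.5, 3.5])

    def test_matches_bruteforce_neighbour_enumeration(self, rng):
        grid = sp.SOMGrid(rows=4, cols=5, weights=rng.standard_normal((20, 3)))
        um = sp.compute_umatrix(grid)
        xy = grid.lattice_xy
        for u in range(20):
            dists = [np.linalg.norm(grid.weights[v] - grid.weights[u])
                     for v in range(20)
                     if v != u and abs(np.linalg.norm(xy[v] - xy[u]) - 1) < 1e-9]
            assert um.values[u] == pytest.approx(np.mean(dists))


class TestTrajectoryDistances:
    def _traj(self, positions, sid="s"):
        pos = np.asarray(positions, dtype=float)
        return sp.BMUTrajectory(sequence_id=sid, positions=pos,
                                unit_indices=np.zeros(len(pos), dtype=int))

    def test_identical_trajectories_distance_zero(self, rng):
        pos = rng.integers(0, 5, size=(101, 2)).astype(float)
        assert sp.trajectory_distance(self._traj(pos), self._traj(pos)) == 0.0

    def test_unit_offset_gives_101(self):
        pos = np.zeros((101, 2))
        off = pos + np.array([1.0, 0.0])
        assert sp.trajectory_distance(self._traj(pos), self._traj(off)) == 101.0

    def test_matches_per_timepoint_bruteforce(self, rng):
        a = rng.standard_normal((101, 2))
        b = rng.standard_normal((101, 2))
        brute = sum(((a[t] - b[t]) ** 2).sum() for t in range(101))
        assert sp.trajectory_distance(self._traj(a), self._traj(b)) == \
            pytest.approx(brute, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            sp.trajectory_distance(self._traj(np.zeros((101, 2))),
                                   self._traj(np.zeros((50, 2))))

    def test_pairwise_matrix_symmetric_zero_diagonal(self, rng):
        trajs = [self._traj(rng.standard_normal((101, 2)), f"s{i}") for i in range(6)]
        dm = sp.pairwise_distance_matrix(trajs)
        assert np.array_equal(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)
        assert (dm.values >= 0).all()

    def test_bmu_trajectory_equals_map_of_find_bmu(self, rng):
        grid = sp.SOMGrid(rows=4, cols=4, weights=rng.standard_normal((16, 3)))
        seq = rng.standard_normal((101, 3))
        traj = sp.bmu_trajectory(grid, seq)
        for t in range(101):
            assert traj.unit_indices[t] == sp.find_bmu(grid, seq[t])
        assert np.array_equal(traj.positions, grid.lattice_xy[traj.unit_indices])


def test_within_player_distance_below_between_player_median(cohort_means, registry,
                                                            fast_som_config):
    """Successful and faulty spikes of the same player land closer on the
    map than different players' patterns for nearly all players."""
    im = sp.assemble_input_vectors(cohort_means, registry, "whole", "both")
    grid = sp.train_som(im, fast_som_config)
    trajs = [sp.bmu_trajectory(grid, im.sequences[i], im.ids[i])
             for i in range(im.n_sequences)]
    dm = sp.pairwise_distance_matrix(trajs)
    player = [i.rsplit("_", 1)[0] for i in dm.ids]
    idx = {s: i for i, s in enumerate(dm.ids)}
    within = [dm.values[idx[p + "_succ"], idx[p + "_fault"]]
              for p in set(player) if p + "_fault" in idx]
    between = [dm.values[i, j] for i in range(dm.n) for j in range(i + 1, dm.n)
               if player[i] != player[j]]
    wins = sum(v < np.median(between) for v in within)
    assert len(within) == 9
    assert wins >= 8
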