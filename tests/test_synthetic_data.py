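"""Ground-truth sampler and SDE simulator behavior."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import chisquare

from trendy.synthetic_data import (
    GroundTruthGRN,
    SimulationParams,
    generate_corpus,
    sample_grn,
    simulate_cells,
)


class TestSampleGrn:
    def test_degenerate_distribution_gives_zero_matrix(self):
        g = sample_grn(10, probs=(0.0, 1.0, 0.0), rng_seed=0)
        assert np.array_equal(g.matrix, np.zeros((10, 10)))

    def test_zero_mass_on_zero_gives_all_nonzero(self):
        g = sample_grn(3, probs=(0.5, 0.0, 0.5), rng_seed=0)
        assert (g.matrix != 0).all()

    def test_entries_are_signed_ternary(self):
        g = sample_grn(10, rng_seed=3)
        assert set(np.unique(g.matrix)) <= {-1.0, 0.0, 1.0}

    def test_empirical_frequencies_match_probs(self):
        draws = np.concatenate(
            [sample_grn(10, rng_seed=s).matrix.ravel() for s in range(100)]
        )
        freq_neg = (draws == -1).mean()
        assert abs(freq_neg - 0.1) < 0.01

    def test_chi_square_not_rejected(self):
        # 10,000 entries against the (0.1, 0.8, 0.1) three-point law
        draws = np.concatenate(
            [sample_grn(10, rng_seed=s).matrix.ravel() for s in range(100)]
        )
        observed = [(draws == v).sum() for v in (-1, 0, 1)]
        expected = [len(draws) * p for p in (0.1, 0.8, 0.1)]
        assert chisquare(observed, expected).pvalue > 0.01

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n": 1},
            {"n": 5, "probs": (0.5, 0.5, 0.5)},
            {"n": 5, "probs": (-0.1, 1.0, 0.1)},
        ],
    )
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sample_grn(**kwargs)

    def test_reproducible_under_seed(self):
        a = sample_grn(8, rng_seed=42).matrix
        b = sample_grn(8, rng_seed=42).matrix
        assert np.array_equal(a, b)


class TestSimulateCells:
    def test_fixed_point_of_noise_free_system(self, zero_grn):
        # with A=0 and sigma=0 the drift vanishes at X = beta/theta = 5
        p = SimulationParams(sigma=0.0, n_cells=4)
        init = np.full((4, 3), 5.0)
        ds = simulate_cells(zero_grn, p, rng_seed=0, init_state=init)
        for snap in ds.snapshots:
            assert np.allclose(snap, 5.0, atol=1e-12)

    def test_noise_free_trajectory_matches_ode_oracle(self, zero_grn):
        # A=0, sigma=0: dX = V(beta - theta X)dt, solvable by a stiff ODE
        # solver; fine step keeps the first-order discretization error small
        p = SimulationParams(sigma=0.0, n_cells=1, dt=0.001)
        init = np.array([[9.0, 0.5, 3.0]])
        ds = simulate_cells(zero_grn, p, rng_seed=0, init_state=init)
        sol = solve_ivp(
            lambda t, x: p.V * (p.beta - p.theta * x),
            (0.0, 1.0),
            init[0],
            t_eval=ds.times,
            rtol=1e-10,
            atol=1e-12,
        )
        for snap, ref in zip(ds.snapshots, sol.y.T):
            assert np.abs(snap[0] - ref).max() / np.abs(ref).max() < 1e-3

    def test_monotone_convergence_toward_equilibrium(self, zero_grn):
        p = SimulationParams(sigma=0.0, n_cells=2)
        init = np.array([[9.0, 9.0, 9.0], [0.1, 0.1, 0.1]])
        ds = simulate_cells(zero_grn, p, rng_seed=0, init_state=init)
        above = np.array([s[0] for s in ds.snapshots])
        below = np.array([s[1] for s in ds.snapshots])
        assert (np.diff(above, axis=0) <= 1e-12).all()
        assert (np.diff(below, axis=0) >= -1e-12).all()

    def test_default_recording_gives_eleven_snapshots(self, zero_grn):
        ds = simulate_cells(zero_grn, SimulationParams(n_cells=3), rng_seed=0)
        assert len(ds.times) == 11
        assert ds.times[0] == 0.0 and ds.times[-1] == 1.0

    def test_stochastic_equilibrium_mean(self, zero_grn):
        p = SimulationParams(sigma=0.1, n_cells=4000)
        ds = simulate_cells(zero_grn, p, rng_seed=5)
        mean_end = ds.at_time(1.0).mean(axis=0)
        assert np.abs(mean_end - 5.0).max() < 0.25  # within 5% of beta/theta

    def test_all_values_nonnegative(self):
        grn = sample_grn(6, rng_seed=9)
        ds = simulate_cells(grn, SimulationParams(sigma=1.0, n_cells=50), rng_seed=9)
        for snap in ds.snapshots:
            assert (snap >= 0).all()

    def test_gene_relabeling_equivariance(self):
        # noise-free: permuting the GRN and the initial states permutes outputs
        grn = sample_grn(5, rng_seed=11)
        p = SimulationParams(sigma=0.0, n_cells=7)
        rng = np.random.default_rng(0)
        init = rng.uniform(0, 10, size=(7, 5))
        perm = np.array([3, 0, 4, 1, 2])
        a_perm = grn.matrix[np.ix_(perm, perm)]
        ds = simulate_cells(grn, p, init_state=init)
        ds_perm = simulate_cells(
            GroundTruthGRN(a_perm), p, init_state=init[:, perm]
        )
        for s, sp in zip(ds.snapshots, ds_perm.snapshots):
            assert np.allclose(sp, s[:, perm], atol=1e-10)

    @pytest.mark.parametrize(
        "bad",
        [
            {"dt": -0.01},
            {"t_end": 0.095},
            {"record_times": (0.0, 0.055)},
            {"sigma": -0.1},
            {"theta": 0.0},
        ],
    )
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            SimulationParams(**bad)


class TestGenerateCorpus:
    def test_single_sample_shape(self):
        corpus = generate_corpus(1, n=4, params=SimulationParams(n_cells=20), rng_seed=0)
        assert len(corpus) == 1
        grn, data = corpus[0]
        assert grn.n == 4
        assert all(s.shape == (20, 4) for s in data.snapshots)
        assert data.grn is grn

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            generate_corpus(0, n=4)

    def test_same_master_seed_bitwise_identical(self):
        p = SimulationParams(n_cells=10)
        c1 = generate_corpus(3, n=4, params=p, rng_seed=99)
        c2 = generate_corpus(3, n=4, params=p, rng_seed=99)
        for (g1, d1), (g2, d2) in zip(c1, c2):
            assert np.array_equal(g1.matrix, g2.matrix)
            for s1, s2 in zip(d1.snapshots, d2.snapshots):
                assert np.array_equal(s1, s2)

    def test_samples_are_distinct(self):
        c = generate_corpus(3, n=4, params=SimulationParams(n_cells=10), rng_seed=0)
        assert not np.array_equal(c[0][0].matrix, c[1][0].matrix) or not np.array_equal(
            c[0][1].snapshots[0], c[1][1].snapshots[0]
        )
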