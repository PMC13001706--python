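"""Minimum-norm perturbation core, per-window normalization, sliding driver."""

import numpy as np
import pytest

from fragmap import (
    FragilityModel,
    TargetEigenvalue,
    calc_adj_frag,
    electrode_fragility,
    generate,
    min_norm_perturbation,
    normalize_window,
    omega_grid,
    random_stable_system,
)

from oracles import oracle_min_norm, random_feasible_gammas


class TestMinNormPerturbation:
    def test_zero_matrix_hand_calculation(self):
        # A = 0: r = (A - I)^{-1} e_0 = -e_0, so gamma = (1, 0), norm 1,
        # and A + gamma e_0^T = e_0 e_0^T has eigenvalue 1.
        res = min_norm_perturbation(np.zeros((2, 2)), TargetEigenvalue(1.0, 0.0),
                                    0, "column")
        assert np.allclose(res.gamma, [1.0, 0.0])
        assert res.norm == pytest.approx(1.0)
        assert np.min(np.abs(np.linalg.eigvals(np.zeros((2, 2)) + res.delta())
                             - 1.0)) < 1e-12

    def test_existing_eigenvalue_needs_no_perturbation(self):
        A = np.array([[0.0, 1.0], [-1.0, 0.0]])  # eigenvalues +/- i
        res = min_norm_perturbation(A, TargetEigenvalue(0.0, 1.0), 0)
        assert res.norm == 0.0
        assert np.all(res.gamma == 0)

    @pytest.mark.parametrize("structure", ["column", "row"])
    def test_eigenvalue_placement(self, rng, structure):
        """A + Delta always has an eigenvalue at the requested target."""
        for _ in range(30):
            m = int(rng.integers(3, 9))
            A = random_stable_system(m, float(rng.uniform(0.5, 0.95)),
                                     int(rng.integers(2 ** 31)))
            k = int(rng.integers(m))
            tgt = TargetEigenvalue.from_angle(float(rng.uniform(0, np.pi)))
            res = min_norm_perturbation(A, tgt, k, structure)
            eigs = np.linalg.eigvals(A + res.delta())
            assert np.min(np.abs(eigs - tgt.value)) < 1e-8

    def test_norm_equals_spectral_norm_of_delta(self, rng):
        A = random_stable_system(5, 0.8, 99)
        res = min_norm_perturbation(A, TargetEigenvalue.from_angle(1.0), 2)
        assert res.norm == pytest.approx(np.linalg.norm(res.delta(), 2))

    def test_matches_constrained_minimizer(self, rng):
        """Closed form vs the independent det-constrained SLSQP oracle."""
        for seed in [0, 1, 2, 3]:
            m = 5 + seed
            A = random_stable_system(m, 0.8, seed=seed)
            k = 2
            tgt = TargetEigenvalue.from_angle(np.pi / 4)
            closed = min_norm_perturbation(A, tgt, k).norm
            orc = oracle_min_norm(A, tgt.value, k, seed=seed)
            assert closed == pytest.approx(orc, rel=1e-4)

    def test_no_feasible_point_beats_closed_form(self):
        """Minimality: 1000 random points on the constraint set are no better."""
        A = random_stable_system(5, 0.85, seed=21)
        k = 1
        tgt = TargetEigenvalue.from_angle(2.0)
        closed = min_norm_perturbation(A, tgt, k).norm
        feas = random_feasible_gammas(A, tgt.value, k, n=1000, seed=5)
        norms = np.linalg.norm(feas, axis=1)
        assert np.all(norms >= closed - 1e-8)

    def test_invalid_inputs(self):
        A = np.zeros((3, 3))
        with pytest.raises(IndexError):
            min_norm_perturbation(A, TargetEigenvalue(1.0, 0.0), 5)
        with pytest.raises(ValueError):
            min_norm_perturbation(A, TargetEigenvalue(1.0, 0.0), 0, "diag")
        with pytest.raises(ValueError):
            TargetEigenvalue(1.0, 1.0)  # modulus sqrt(2)


class TestElectrodeFragility:
    def test_single_target_grid(self):
        A = random_stable_system(4, 0.8, seed=1)
        grid = [TargetEigenvalue.from_angle(0.7)]
        norm, tgt = electrode_fragility(A, 0, grid)
        assert norm == pytest.approx(min_norm_perturbation(A, grid[0], 0).norm)
        assert tgt == grid[0]

    def test_eigenvalue_on_grid_gives_zero(self):
        A = np.array([[0.0, 1.0], [-1.0, 0.0]])
        norm, _ = electrode_fragility(A, 1, [TargetEigenvalue(0.0, 1.0)])
        assert norm == 0.0

    def test_denser_grid_never_increases_minimum(self, rng):
        A = random_stable_system(5, 0.9, seed=13)
        coarse = omega_grid(11)
        dense = omega_grid(21)  # superset of the 11-point grid
        for k in range(5):
            n_c, _ = electrode_fragility(A, k, coarse)
            n_d, _ = electrode_fragility(A, k, dense)
            assert n_d <= n_c + 1e-12

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            electrode_fragility(np.zeros((2, 2)), 0, [])


class TestNormalizeWindow:
    def test_reverse_scaling_formula(self):
        assert np.allclose(normalize_window(np.array([2.0, 1.0, 4.0])),
                           [0.5, 0.75, 0.0])

    def test_all_equal_maps_to_zero(self):
        assert np.allclose(normalize_window(np.array([3.0, 3.0, 3.0])), 0.0)

    def test_zero_entry_maps_to_one(self):
        out = normalize_window(np.array([0.0, 2.0, 1.0]))
        assert out[0] == pytest.approx(1.0)

    def test_all_zero_degenerate(self):
        assert np.allclose(normalize_window(np.zeros(4)), 0.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            normalize_window(np.array([1.0, -0.5]))


class TestPermutationCovariance:
    def test_permuting_electrodes_permutes_fragility(self, rng):
        m = 6
        A = random_stable_system(m, 0.9, seed=3)
        grid = omega_grid(21)
        perm = rng.permutation(m)
        P = np.eye(m)[perm]
        A_p = P @ A @ P.T
        base = np.array([electrode_fragility(A, k, grid)[0] for k in range(m)])
        permed = np.array([electrode_fragility(A_p, k, grid)[0] for k in range(m)])
        assert np.allclose(permed, base[perm], rtol=1e-9)


@pytest.fixture(scope="module")
def dataset():
    return generate(seed=11)


class TestCalcAdjFrag:
    def test_window_count_and_spacing(self, dataset):
        ep = dataset.epoch  # N = 2000 at 500 Hz
        res = calc_adj_frag(ep, window=250, step=125, omega_grid_size=11)
        assert res.n_windows == (2000 - 250) // 125 + 1
        assert np.allclose(np.diff(res.window_starts), 125 / 500.0)
        assert res.window_starts[0] == pytest.approx(ep.start_time)

    def test_fragility_column_invariants(self, dataset):
        res = calc_adj_frag(dataset.epoch, omega_grid_size=11)
        assert res.fragility.min() >= 0.0 and res.fragility.max() <= 1.0
        for j in range(res.n_windows):
            col, raw = res.fragility[:, j], res.raw_norms[:, j]
            assert col.min() == 0.0  # max-raw-norm electrode pinned to 0
            # reverse scaling reproduced entry-wise, which implies the
            # within-column ordering is the reverse of the raw-norm ordering
            assert np.allclose(col, (raw.max() - raw) / raw.max())
            assert np.allclose(np.argsort(np.argsort(col)),
                               np.argsort(np.argsort(-raw)))

    def test_parallel_identical_to_serial(self, dataset):
        serial = calc_adj_frag(dataset.epoch, omega_grid_size=11, parallel=False)
        par = calc_adj_frag(dataset.epoch, omega_grid_size=11, parallel=True)
        assert np.array_equal(serial.fragility, par.fragility)
        assert np.array_equal(serial.raw_norms, par.raw_norms)
        assert np.array_equal(serial.lambdas, par.lambdas)

    def test_planted_node_dominates_post_onset(self, dataset):
        res = calc_adj_frag(dataset.epoch)
        post = res.window_starts >= 0.0
        top = np.argmax(res.fragility[:, post], axis=0)
        frac = np.isin(top, dataset.truth).mean()
        assert frac > 0.5

    def test_window_larger_than_epoch_rejected(self, dataset):
        with pytest.raises(ValueError, match="window"):
            FragilityModel(dataset.epoch, window=10 ** 6)

    def test_lambda_sensitivity_trend(self, dataset):
        """Mean raw perturbation norm is non-decreasing in the ridge penalty."""
        means = []
        for lam in (1e-4, 1e-3, 1e-2):
            res = calc_adj_frag(dataset.epoch, lam=lam, omega_grid_size=21)
            means.append(res.raw_norms.mean())
        assert means[0] <= means[1] + 1e-12 <= means[2] + 2e-12
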