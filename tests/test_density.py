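"""Density maps, marginals and the median-centred correlation."""

import numpy as np
import pytest
from scipy import stats

from cordmap import (GridSpec, IdealizedFrame, bandwidth_from_sd,
                     correlation_matrix, density_correlation, density_matrix,
                     marginal)
from cordmap.errors import (EmptyInputError, ParameterError,
                            UndefinedCorrelationError)


def median_centred_corr_bruteforce(a, b):
    """Independent evaluation of the median-centred correlation: explicit
    double sums, no vectorized shortcuts shared with the implementation."""
    med_a = float(np.median(np.asarray(a).ravel()))
    med_b = float(np.median(np.asarray(b).ravel()))
    num = ssa = ssb = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            da = a[i, j] - med_a
            db = b[i, j] - med_b
            num += da * db
            ssa += da * da
            ssb += db * db
    return num / np.sqrt(ssa * ssb)


class TestBandwidth:
    def test_scott_rule_closed_form(self, rng):
        sample = rng.normal(0.0, 1.0, size=100)
        sample = (sample - sample.mean()) / sample.std(ddof=1) * 100.0
        assert bandwidth_from_sd(sample) == pytest.approx(100 * 100 ** -0.2)

    def test_single_point_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="minimum bandwidth"):
            assert bandwidth_from_sd(np.array([5.0])) == 10.0

    def test_constant_sample_falls_back(self):
        with pytest.warns(UserWarning, match="minimum bandwidth"):
            assert bandwidth_from_sd(np.full(50, 3.3)) == 10.0

    def test_scale_equivariance(self, rng):
        sample = rng.normal(0.0, 80.0, size=500)
        assert bandwidth_from_sd(2 * sample) == pytest.approx(
            2 * bandwidth_from_sd(sample))


class TestDensityMatrix:
    def test_single_cell_unimodal_at_origin(self):
        rho = density_matrix([0.0], [0.0], bandwidth=(30.0, 30.0))
        assert rho.total_mass == pytest.approx(1.0, abs=1e-12)
        i, j = np.unravel_index(np.argmax(rho.values), rho.values.shape)
        assert abs(rho.grid.x_centres[i]) <= rho.grid.spacing_um
        assert abs(rho.grid.y_centres[j]) <= rho.grid.spacing_um

    def test_mass_is_one_regardless_of_input(self, rng):
        for n in (1, 7, 500):
            x = rng.uniform(-800, 800, n)
            y = rng.uniform(-400, 400, n)
            rho = density_matrix(x, y)
            assert rho.total_mass == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_input_gives_symmetric_map(self):
        rho = density_matrix([-200.0, 200.0], [100.0, 100.0],
                             bandwidth=(50.0, 50.0))
        np.testing.assert_allclose(rho.values, rho.values[::-1, :], atol=1e-12)

    def test_gaussian_mass_in_two_sigma_window(self, rng):
        # mass inside ±2σ of a known Gaussian ≈ 95.45% (per axis: erf(2/√2))
        n = 1000
        x = rng.normal(0.0, 150.0, n)
        y = rng.normal(0.0, 120.0, n)
        rho = density_matrix(np.clip(x, -840, 840), np.clip(y, -440, 440),
                             bandwidth=(10.0, 10.0))
        inside = (np.abs(rho.grid.x_centres)[:, None] <= 300.0) & \
                 (np.abs(rho.grid.y_centres)[None, :] <= 240.0)
        expected = (stats.norm.cdf(2) - stats.norm.cdf(-2)) ** 2
        assert rho.values[inside].sum() == pytest.approx(expected, abs=0.04)

    def test_order_invariance(self, rng):
        x = rng.uniform(-500, 500, 100)
        y = rng.uniform(-300, 300, 100)
        perm = rng.permutation(100)
        a = density_matrix(x, y, bandwidth=(40.0, 40.0))
        b = density_matrix(x[perm], y[perm], bandwidth=(40.0, 40.0))
        np.testing.assert_allclose(a.values, b.values, atol=1e-14)

    def test_empty_input_raises(self):
        with pytest.raises(EmptyInputError):
            density_matrix([], [])


class TestMarginal:
    def test_sums_to_one_from_cells_and_from_matrix(self, rng):
        x = rng.normal(300, 100, 400)
        y = rng.normal(-200, 80, 400)
        rho = density_matrix(x, y)
        for axis in ("x", "y"):
            assert marginal(rho, axis).total == pytest.approx(1.0, abs=1e-9)
            coords = x if axis == "x" else y
            assert marginal(coords, axis).total == pytest.approx(1.0, abs=1e-9)

    def test_matrix_marginal_equals_row_column_sums(self, rng):
        rho = density_matrix(rng.uniform(-500, 500, 50),
                             rng.uniform(-300, 300, 50))
        np.testing.assert_allclose(marginal(rho, "x").weights,
                                   rho.values.sum(axis=1))
        np.testing.assert_allclose(marginal(rho, "y").weights,
                                   rho.values.sum(axis=0))

    def test_single_cell_marginal_is_discretized_gaussian(self):
        rho = density_matrix([0.0], [0.0], bandwidth=(60.0, 60.0))
        m = marginal(rho, "x")
        c = m.centres
        expected = np.exp(-0.5 * (c / 60.0) ** 2)
        expected[np.abs(c) > 4 * 60.0] = 0.0  # kernel truncated at 4σ
        expected /= expected.sum()
        np.testing.assert_allclose(m.weights, expected, atol=1e-12)

    def test_symmetric_map_gives_symmetric_marginal(self):
        rho = density_matrix([-150.0, 150.0], [0.0, 0.0], bandwidth=(50.0, 50.0))
        w = marginal(rho, "x").weights
        np.testing.assert_allclose(w, w[::-1], atol=1e-12)

    def test_invalid_axis(self):
        with pytest.raises(ParameterError):
            marginal(np.array([1.0, 2.0]), "z")


class TestDensityCorrelation:
    def test_self_correlation_is_one(self, rng):
        rho = density_matrix(rng.normal(200, 90, 300), rng.normal(100, 90, 300))
        assert density_correlation(rho, rho) == pytest.approx(1.0, abs=1e-12)

    def test_positive_affine_invariance(self, rng):
        a = rng.random((5, 5))
        assert density_correlation(a, 3.7 * a + 0.2) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_two_by_two_example(self):
        a = np.array([[1.0, 0.0], [0.0, 0.0]])
        b = np.array([[0.0, 0.0], [0.0, 1.0]])
        assert density_correlation(a, b) == 0.0

    def test_matches_bruteforce_on_random_matrices(self, rng):
        for _ in range(100):
            shape = tuple(rng.integers(2, 6, size=2))
            a, b = rng.random(shape), rng.random(shape)
            r = density_correlation(a, b)
            assert r == pytest.approx(median_centred_corr_bruteforce(a, b),
                                      abs=1e-12)
            assert density_correlation(b, a) == pytest.approx(r, abs=1e-14)
            assert -1.0 <= r <= 1.0

    def test_zero_variance_is_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            density_correlation(np.ones((3, 3)), np.random.rand(3, 3))

    def test_grid_refinement_stability(self, rng):
        x = rng.normal(250, 130, 800)
        y = rng.normal(-150, 110, 800)
        x2 = rng.normal(230, 130, 800)
        y2 = rng.normal(-160, 110, 800)
        coarse = GridSpec.for_frame(IdealizedFrame(), 25.0)
        fine = coarse.refined(2)
        bw = (60.0, 60.0)
        r_coarse = density_correlation(density_matrix(x, y, coarse, bw),
                                       density_matrix(x2, y2, coarse, bw))
        r_fine = density_correlation(density_matrix(x, y, fine, bw),
                                     density_matrix(x2, y2, fine, bw))
        assert abs(r_coarse - r_fine) < 0.05


class TestCorrelationMatrix:
    def test_duplicated_experiments_give_all_ones(self, rng):
        rho = density_matrix(rng.normal(300, 100, 200), rng.normal(200, 80, 200))
        mat = correlation_matrix({"a": rho, "b": rho, "c": rho})
        np.testing.assert_allclose(mat.values, 1.0, atol=1e-12)

    def test_disjoint_quadrant_clouds_decorrelate(self, rng):
        grid = GridSpec.for_frame()
        a = density_matrix(rng.normal(400, 30, 300), rng.normal(300, 30, 300),
                           grid, (15.0, 15.0))
        b = density_matrix(rng.normal(-400, 30, 300), rng.normal(-300, 30, 300),
                           grid, (15.0, 15.0))
        assert abs(density_correlation(a, b)) < 0.1

    def test_same_distribution_cohorts_correlate(self, rng):
        grid = GridSpec.for_frame()
        maps = []
        for _ in range(2):
            x = np.concatenate([rng.normal(320, 110, 700), rng.normal(-250, 120, 300)])
            y = np.concatenate([rng.normal(230, 90, 700), rng.normal(-200, 100, 300)])
            maps.append(density_matrix(x, y, grid))
        assert density_correlation(*maps) > 0.9
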