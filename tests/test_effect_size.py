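"""Hedges' G, the two-level bootstrap, and positional medians."""

import numpy as np
import pytest

from cordmap import (QuadrantLabel, hedges_g, hierarchical_bootstrap,
                     median_position, pairwise_effect_matrix)
from cordmap.effect_size import effect_band
from cordmap.errors import (EmptyInputError, InsufficientDataError,
                            UndefinedEffectError)

from conftest import make_experiment

DORSAL_IPSI = QuadrantLabel(side="ipsi", half="dorsal")


def hedges_g_textbook(a, b):
    """Independent oracle: the standard bias-corrected formula written out."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp = np.sqrt(((na - 1) * a.std(ddof=1) ** 2 + (nb - 1) * b.std(ddof=1) ** 2)
                 / (na + nb - 2))
    j = 1 - 3 / (4 * (na + nb) - 9)
    return j * (a.mean() - b.mean()) / sp


class TestHedgesG:
    def test_hand_computed_case(self):
        # means 2 vs 3, pooled SD 1, J = 1 - 3/15 = 0.8
        assert hedges_g([1, 2, 3], [2, 3, 4]) == pytest.approx(-0.8, abs=1e-12)

    def test_identical_samples_give_zero(self):
        assert hedges_g([3, 1, 4, 1], [3, 1, 4, 1]) == 0.0

    def test_antisymmetry(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(2, 30))
            b = rng.normal(0.3, 1.2, rng.integers(2, 30))
            assert hedges_g(a, b) == pytest.approx(-hedges_g(b, a), abs=1e-14)

    def test_matches_textbook_oracle(self, rng):
        for _ in range(50):
            a = rng.normal(0, 1, rng.integers(2, 40))
            b = rng.normal(rng.normal(), np.exp(rng.normal()), rng.integers(2, 40))
            assert hedges_g(a, b) == pytest.approx(hedges_g_textbook(a, b),
                                                   abs=1e-12)

    def test_too_few_observations(self):
        with pytest.raises(InsufficientDataError):
            hedges_g([1.0], [2.0, 3.0])

    def test_zero_pooled_sd_undefined(self):
        with pytest.raises(UndefinedEffectError):
            hedges_g([2.0, 2.0], [5.0, 5.0])

    @pytest.mark.parametrize("g,band", [
        (0.05, "none"), (-0.19, "none"), (0.2, "small"), (-0.49, "small"),
        (0.5, "medium"), (0.79, "medium"), (-0.8, "large"), (2.0, "large")])
    def test_effect_bands(self, g, band):
        assert effect_band(g) == band


def animals(rng, n_animals, n_cells, mean=320.0, sd=110.0):
    return [rng.normal(mean, sd, n_cells) for _ in range(n_animals)]


class TestHierarchicalBootstrap:
    def test_same_seed_bit_identical(self, rng):
        ga, gb = animals(rng, 4, 60), animals(rng, 4, 60)
        r1 = hierarchical_bootstrap(ga, gb, n_replicas=500, seed=7)
        r2 = hierarchical_bootstrap(ga, gb, n_replicas=500, seed=7)
        assert r1 == r2

    def test_null_is_centred_near_zero(self, rng):
        res = hierarchical_bootstrap(animals(rng, 6, 200), animals(rng, 6, 200),
                                     n_replicas=2000, seed=1)
        assert abs(res.g_median) < 0.1
        assert res.g_iqr[0] <= res.g_median <= res.g_iqr[1]

    def test_shift_recovered_with_expected_sign(self, rng):
        res = hierarchical_bootstrap(
            animals(rng, 6, 200, mean=320.0),
            animals(rng, 6, 200, mean=320.0 + 0.5 * 110.0),
            n_replicas=2000, seed=2)
        # group B shifted +0.5 pooled SD => g ≈ -0.5
        assert res.g_iqr[0] <= -0.5 <= res.g_iqr[1] or abs(res.g_median + 0.5) < 0.15

    def test_single_animal_degrades_to_flat_bootstrap(self, rng):
        res = hierarchical_bootstrap([rng.normal(0, 1, 150)],
                                     [rng.normal(1, 1, 150)],
                                     n_replicas=500, seed=3)
        assert res.n_animals == (1, 1)
        assert abs(res.g_median + 1.0) < 0.35

    def test_ragged_animal_sizes_supported(self, rng):
        ga = [rng.normal(0, 1, n) for n in (50, 120, 80)]
        gb = [rng.normal(0, 1, n) for n in (70, 60)]
        res = hierarchical_bootstrap(ga, gb, n_replicas=300, seed=4)
        assert res.n_cells == (250, 130)
        assert res.n_replicas == 300

    def test_ragged_and_uniform_paths_agree_statistically(self, rng):
        # same data via the vectorized (uniform sizes) and loop (ragged) paths
        base = [rng.normal(0.0, 1.0, 100) for _ in range(4)]
        shifted = [a + 0.4 for a in base]
        uniform = hierarchical_bootstrap(base, shifted, n_replicas=2000, seed=5)
        ragged = hierarchical_bootstrap(
            [a[: 99 if i == 0 else 100] for i, a in enumerate(base)],
            shifted, n_replicas=2000, seed=5)
        assert uniform.g_median == pytest.approx(ragged.g_median, abs=0.1)

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            hierarchical_bootstrap([], [np.ones(5)])


class TestMedianPosition:
    def test_odd_count_median(self):
        exp = make_experiment([(100, 200), (300, 200), (500, 200)])
        assert median_position(exp, DORSAL_IPSI).median_um == 300.0

    def test_even_count_midpoint(self):
        exp = make_experiment([(100, 50), (200, 50)])
        assert median_position(exp, DORSAL_IPSI).median_um == 150.0

    def test_motor_neurons_excluded(self):
        xy = [(100, 200), (300, 200), (500, 200)]
        exp = make_experiment(xy)
        exp_mn = make_experiment([(900, 200)], cell_class="motor_neuron")
        exp.cells += exp_mn.cells
        assert median_position(exp, DORSAL_IPSI).median_um == 300.0

    def test_empty_quadrant_flagged(self):
        exp = make_experiment([(-100, -200)])
        with pytest.raises(EmptyInputError):
            median_position(exp, DORSAL_IPSI)

    def test_recovers_generator_centre(self, rng):
        xy = np.column_stack([rng.normal(320, 80, 600),
                              np.abs(rng.normal(200, 60, 600))])
        exp = make_experiment(xy)
        assert median_position(exp, DORSAL_IPSI).median_um == pytest.approx(
            320.0, abs=15.0)


class TestPairwiseEffectMatrix:
    def test_identical_experiments_all_zero(self, rng):
        xy = np.column_stack([rng.normal(320, 90, 200),
                              np.abs(rng.normal(200, 60, 200))])
        exps = [make_experiment(xy, experiment_id=f"e{i}") for i in range(3)]
        mat, summary = pairwise_effect_matrix(exps, DORSAL_IPSI)
        low = mat.values[np.tril_indices(3, k=-1)]
        np.testing.assert_allclose(low, 0.0, atol=1e-12)
        assert summary["g_median"] == pytest.approx(0.0, abs=1e-12)

    def test_one_sd_separation_detected(self, rng):
        a = np.column_stack([rng.normal(250, 80, 400),
                             np.abs(rng.normal(200, 60, 400))])
        b = np.column_stack([rng.normal(330, 80, 400),
                             np.abs(rng.normal(200, 60, 400))])
        mat, _ = pairwise_effect_matrix(
            [make_experiment(a, "a"), make_experiment(b, "b")], DORSAL_IPSI)
        assert mat.loc["b", "a"] == pytest.approx(1.0, abs=0.25)

    def test_summary_median_matches_bruteforce(self, rng):
        clouds = [np.column_stack([rng.normal(300 + 20 * i, 90, 150),
                                   np.abs(rng.normal(200, 60, 150))])
                  for i in range(4)]
        exps = [make_experiment(c, f"e{i}") for i, c in enumerate(clouds)]
        mat, summary = pairwise_effect_matrix(exps, DORSAL_IPSI)
        signed = [hedges_g(clouds[i][:, 0], clouds[j][:, 0])
                  for i in range(4) for j in range(i + 1, 4)]
        assert summary["n_pairs"] == 6
        assert summary["g_median"] == pytest.approx(np.median(signed), abs=1e-12)
        assert mat.iloc[1, 0] == pytest.approx(abs(signed[0]), abs=1e-12)

    def test_upper_triangle_left_empty(self, rng):
        xy = np.column_stack([rng.normal(300, 90, 100),
                              np.abs(rng.normal(200, 60, 100))])
        mat, _ = pairwise_effect_matrix(
            [make_experiment(xy, "a"), make_experiment(xy, "b")], DORSAL_IPSI)
        assert np.isnan(mat.loc["a", "b"])
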