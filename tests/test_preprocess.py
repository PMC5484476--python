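import numpy as np
import pytest

from igspec import (
    PRESETS,
    PreprocessConfig,
    Spectrum,
    SpectrumSet,
    apply_savgol,
    average_replicates,
    preprocess_set,
    savgol_weights,
    select_regions,
    snv,
    vector_normalize,
)
from igspec.preprocess import DEFAULT_REGIONS

GRID = np.arange(4000.0, 650.0, -4.0)


def spec(absorbances, sample="a", rep=1, grid=GRID):
    return Spectrum(sample, rep, "lab", grid, absorbances)


class TestSavgolWeights:
    def test_five_point_quadratic_smoothing_weights(self):
        np.testing.assert_allclose(savgol_weights(5, 2, 0), np.array([-3, 12, 17, 12, -3]) / 35)

    @pytest.mark.parametrize("window,polyorder", [(5, 2), (9, 2), (11, 3)])
    def test_smoothing_weights_sum_to_one(self, window, polyorder):
        assert savgol_weights(window, polyorder, 0).sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("deriv", [1, 2])
    def test_derivative_weights_sum_to_zero(self, deriv):
        assert savgol_weights(9, 2, deriv, step=-4.0).sum() == pytest.approx(0.0, abs=1e-12)

    def test_invalid_combinations_rejected(self):
        with pytest.raises(ValueError):
            savgol_weights(8, 2, 0)
        with pytest.raises(ValueError):
            savgol_weights(5, 2, 3)


class TestApplySavgol:
    def test_quadratic_reproduced_exactly_on_interior(self):
        q = 1.0 + 0.5 * GRID - 1e-3 * GRID**2
        out = apply_savgol(spec(q), PreprocessConfig())
        np.testing.assert_allclose(out.absorbances, q[4:-4], rtol=1e-9)
        assert out.wavenumbers.size == GRID.size - 8  # half-windows dropped

    def test_first_derivative_of_linear_ramp_is_slope(self):
        out = apply_savgol(
            spec(2.0 + 0.003 * GRID), PreprocessConfig(base="first_derivative")
        )
        np.testing.assert_allclose(out.absorbances, 0.003, rtol=1e-9)

    def test_second_derivative_of_constant_is_zero(self):
        out = apply_savgol(
            spec(np.full(GRID.size, 5.0)), PreprocessConfig(base="second_derivative")
        )
        np.testing.assert_allclose(out.absorbances, 0.0, atol=1e-12)

    def test_short_spectrum_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            apply_savgol(spec(np.ones(5), grid=GRID[:5]), PreprocessConfig())


class TestNormalizations:
    def test_snv_hand_example(self):
        out = snv(spec(np.array([1.0, 2.0, 3.0]), grid=GRID[:3]))
        np.testing.assert_allclose(out.absorbances, [-1.0, 0.0, 1.0])

    def test_snv_output_standardized(self, rng):
        out = snv(spec(rng.normal(size=GRID.size)))
        assert out.absorbances.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.absorbances.std(ddof=1) == pytest.approx(1.0)

    def test_snv_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            snv(spec(np.full(GRID.size, 2.0)))

    def test_vector_normalize_345(self):
        out = vector_normalize(spec(np.array([3.0, 4.0]), grid=GRID[:2]))
        np.testing.assert_allclose(out.absorbances, [0.6, 0.8])

    def test_vector_normalize_scale_invariant(self, rng):
        a = rng.normal(size=GRID.size)
        out1 = vector_normalize(spec(a))
        out2 = vector_normalize(spec(7.3 * a))
        np.testing.assert_allclose(out1.absorbances, out2.absorbances)

    def test_vector_normalize_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            vector_normalize(spec(np.zeros(GRID.size)))

    @pytest.mark.parametrize("op", [snv, vector_normalize])
    def test_normalizations_idempotent(self, op, rng):
        once = op(spec(rng.normal(size=GRID.size)))
        twice = op(once)
        np.testing.assert_allclose(twice.absorbances, once.absorbances, atol=1e-12)


class TestRegions:
    def test_default_region_point_count_on_trimmed_grid(self):
        trimmed = GRID[4:-4]
        out = select_regions(spec(np.ones(trimmed.size), grid=trimmed))
        # closed intervals on the 4 cm^-1 grid: (3700-2600)/4+1 + (1800-1300)/4+1
        assert out.wavenumbers.size == 276 + 126

    def test_whole_grid_interval_is_identity(self, rng):
        a = rng.normal(size=GRID.size)
        out = select_regions(spec(a), regions=((4000.0, 650.0),))
        np.testing.assert_array_equal(out.absorbances, a)

    def test_disjoint_intervals_stay_descending(self):
        out = select_regions(spec(np.ones(GRID.size)))
        assert np.all(np.diff(out.wavenumbers) < 0)
        assert out.wavenumbers.max() <= 3700 and out.wavenumbers.min() >= 1300

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="no points"):
            select_regions(spec(np.ones(GRID.size)), regions=((100.0, 200.0),))


class TestPreprocessSet:
    def test_smoothing_noise_free_is_edge_trim_only(self):
        q = 0.1 + 1e-4 * GRID + 1e-8 * GRID**2  # quadratic: reproduced exactly
        s = SpectrumSet([spec(q, "a"), spec(q, "b")])
        out = preprocess_set(s, PreprocessConfig(regions=((3984.0, 668.0),)))
        np.testing.assert_allclose(out.spectra[0].absorbances, q[4:-4], rtol=1e-9)

    def test_all_outputs_share_one_grid(self, small_dataset):
        out = preprocess_set(small_dataset.spectra, PRESETS["d2_snv"])
        assert len(out) == len(small_dataset.spectra)

    def test_derivative_then_normalize_differs_from_reverse(self):
        # asymmetric two-band spectrum
        a = np.exp(-((GRID - 3000) ** 2) / (2 * 100**2)) + 0.3 * np.exp(
            -((GRID - 1600) ** 2) / (2 * 40**2)
        )
        # pipeline composition: derivative, then unit-norm scaling
        d_then_n = preprocess_set(SpectrumSet([spec(a)]), PRESETS["d1_vec"]).spectra[0]
        # reversed composition: normalize the raw spectrum, then differentiate
        n_then_d = select_regions(
            apply_savgol(vector_normalize(spec(a)), PRESETS["d1"])
        )
        assert d_then_n.absorbances.shape == n_then_d.absorbances.shape
        assert not np.allclose(d_then_n.absorbances, n_then_d.absorbances)
        # the pipeline output is unit-norm; the reversed one is not
        assert np.linalg.norm(d_then_n.absorbances) == pytest.approx(1.0)
        assert np.linalg.norm(n_then_d.absorbances) != pytest.approx(1.0)


class TestAverageReplicates:
    def test_identical_replicates_average_to_themselves(self):
        a = np.arange(GRID.size, dtype=float)
        out = average_replicates(SpectrumSet([spec(a, "s", 1), spec(a, "s", 2)]))
        assert len(out) == 1
        np.testing.assert_array_equal(out.spectra[0].absorbances, a)

    def test_pointwise_mean(self):
        g = GRID[:3]
        s1 = spec(np.array([0.0, 0.0, 0.0]), "s", 1, g)
        s2 = spec(np.array([2.0, 4.0, 6.0]), "s", 2, g)
        out = average_replicates(SpectrumSet([s1, s2]))
        np.testing.assert_array_equal(out.spectra[0].absorbances, [1.0, 2.0, 3.0])

    def test_region_selection_commutes_with_averaging(self, small_dataset):
        smoothed = preprocess_set(
            small_dataset.spectra, PreprocessConfig(regions=((3984.0, 668.0),))
        )
        a = average_replicates(
            SpectrumSet([select_regions(s, DEFAULT_REGIONS) for s in smoothed])
        )
        b = SpectrumSet(
            [select_regions(s, DEFAULT_REGIONS) for s in average_replicates(smoothed)]
        )
        for x, y in zip(a, b):
            np.testing.assert_allclose(x.absorbances, y.absorbances)
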