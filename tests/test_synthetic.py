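import numpy as np
import pytest

from igspec import (
    Component,
    GaussianBand,
    InstrumentProfile,
    PopulationConfig,
    generate_dataset,
    inject_outlier,
    lab_instrument,
    portable_instrument,
    pure_component_spectrum,
    sample_concentrations,
    synthesize_spectrum,
)
from igspec.synthetic import default_components


def quiet_instrument(**kw):
    return lab_instrument(
        noise_sd=0.0, baseline_offset_sd=0.0, baseline_slope_sd=0.0, scatter_sd=0.0, **kw
    )


class TestConcentrations:
    def test_population_moments_and_low_tail(self):
        """Herd mean/SD and the low-IgG fraction land on the configured values."""
        config = PopulationConfig(n_samples=4000)
        conc, _ = sample_concentrations(config, seed=42)
        igg = conc["IgG"]
        n = igg.size
        assert abs(igg.mean() - 2654) < 3 * 1305 / np.sqrt(n)
        assert abs(igg.std(ddof=1) - 1305) < 3 * 1305 / np.sqrt(2 * n)
        assert abs((igg < 1000).mean() - 0.12) < 0.05
        assert igg.min() >= 394 and igg.max() <= 6327

    def test_zero_reference_cv_gives_exact_reference(self):
        config = PopulationConfig(n_samples=50, reference_cv=0.0)
        conc, ref = sample_concentrations(config, seed=1)
        np.testing.assert_array_equal(ref, conc["IgG"])

    def test_degenerate_truncation_pins_all_values(self):
        config = PopulationConfig(n_samples=20, igg_min=2000, igg_max=2000)
        conc, _ = sample_concentrations(config, seed=1)
        np.testing.assert_array_equal(conc["IgG"], np.full(20, 2000.0))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            PopulationConfig(n_samples=0)
        with pytest.raises(ValueError):
            PopulationConfig(igg_min=5000, igg_max=1000)
        with pytest.raises(ValueError):
            PopulationConfig(reference_cv=-0.1)


class TestPureComponent:
    band = Component("x", (GaussianBand(1650.0, 30.0, 1.0),))

    def test_gaussian_peak_and_shoulder(self):
        grid = np.array([1680.0, 1650.0, 1620.0])
        spec = pure_component_spectrum(self.band, grid)
        assert spec[1] == pytest.approx(1.0)
        assert spec[0] == spec[2] == pytest.approx(np.exp(-0.5))

    def test_two_identical_bands_double(self):
        grid = np.linspace(1800, 1500, 50)
        double = Component("x", (self.band.bands[0], self.band.bands[0]))
        np.testing.assert_allclose(
            pure_component_spectrum(double, grid),
            2 * pure_component_spectrum(self.band, grid),
        )

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pure_component_spectrum(self.band, np.array([]))

    def test_band_invariants(self):
        with pytest.raises(ValueError):
            GaussianBand(1650.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            GaussianBand(5000.0, 30.0, 1.0)


class TestSynthesize:
    def test_beer_lambert_linearity(self):
        comps = default_components()
        conc = {c.name: 1000.0 for c in comps}
        inst = quiet_instrument()
        s1 = synthesize_spectrum(conc, comps, inst, replicate_seed=0)
        s2 = synthesize_spectrum({k: 2 * v for k, v in conc.items()}, comps, inst, replicate_seed=0)
        np.testing.assert_allclose(s2.absorbances, 2 * s1.absorbances)

    def test_path_scale_ratio(self):
        comps = default_components()
        conc = {c.name: 1000.0 for c in comps}
        a = synthesize_spectrum(conc, comps, quiet_instrument(), replicate_seed=0)
        b = synthesize_spectrum(conc, comps, quiet_instrument(path_scale=1.5), replicate_seed=0)
        np.testing.assert_allclose(b.absorbances, 1.5 * a.absorbances)

    def test_fixed_seed_is_bit_identical(self):
        comps = default_components()
        conc = {c.name: 1000.0 for c in comps}
        inst = lab_instrument()
        a = synthesize_spectrum(conc, comps, inst, replicate_seed=7)
        b = synthesize_spectrum(conc, comps, inst, replicate_seed=7)
        np.testing.assert_array_equal(a.absorbances, b.absorbances)

    def test_negative_concentration_rejected(self):
        comps = default_components()
        conc = {c.name: 1000.0 for c in comps}
        conc["IgG"] = -1.0
        with pytest.raises(ValueError, match="negative"):
            synthesize_spectrum(conc, comps, lab_instrument(), replicate_seed=0)


class TestGenerateDataset:
    def test_spectrum_count_matches_replicates(self):
        ds = generate_dataset(PopulationConfig(n_samples=8), seed=0)
        assert len(ds.spectra) == 16  # duplicates per sample
        ds1 = generate_dataset(
            PopulationConfig(n_samples=1), instrument=lab_instrument(replicates=1), seed=0
        )
        assert len(ds1.spectra) == 1 and len(ds1.reference) == 1

    def test_same_seed_identical_datasets(self):
        a = generate_dataset(PopulationConfig(n_samples=5), seed=9)
        b = generate_dataset(PopulationConfig(n_samples=5), seed=9)
        np.testing.assert_array_equal(a.spectra.matrix(), b.spectra.matrix())
        assert a.reference.table.equals(b.reference.table)

    def test_replicates_differ_in_noise(self):
        ds = generate_dataset(PopulationConfig(n_samples=3), seed=2)
        r1, r2 = ds.spectra.spectra[0], ds.spectra.spectra[1]
        assert r1.sample_id == r2.sample_id
        assert not np.array_equal(r1.absorbances, r2.absorbances)

    def test_instruments_have_different_noise_streams(self):
        lab = generate_dataset(PopulationConfig(n_samples=2), instrument=lab_instrument(), seed=4)
        por = generate_dataset(
            PopulationConfig(n_samples=2), instrument=portable_instrument(), seed=4
        )
        assert not np.array_equal(lab.spectra.matrix(), por.spectra.matrix())

    def test_grid_is_descending_with_expected_size(self):
        assert InstrumentProfile().grid().size == 838
        assert InstrumentProfile().grid()[0] == 4000.0


class TestInjectOutlier:
    def test_zero_magnitude_is_identity(self, small_dataset):
        out = inject_outlier(small_dataset, "S01", 1, magnitude=0.0)
        np.testing.assert_array_equal(out.spectra.matrix(), small_dataset.spectra.matrix())

    def test_offset_applied_to_requested_fraction(self, small_dataset):
        out = inject_outlier(small_dataset, "S01", 1, magnitude=1.0, fraction=0.5)
        orig = small_dataset.spectra.spectra[0].absorbances
        mod = out.spectra.spectra[0].absorbances
        n_bad = int(round(0.5 * orig.size))
        np.testing.assert_allclose(mod[:n_bad], orig[:n_bad] + 1.0)
        np.testing.assert_array_equal(mod[n_bad:], orig[n_bad:])

    def test_unknown_replicate_rejected(self, small_dataset):
        with pytest.raises(KeyError):
            inject_outlier(small_dataset, "nope", 1, magnitude=1.0)
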