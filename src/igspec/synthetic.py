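"""Synthetic serum ATR-IR spectra with the statistical structure the pipeline assumes.

The generator is a Beer-Lambert mixture: each serum component (IgG, albumin,
other globulins, a broad matrix background) has a pure-component extinction
spectrum built from Gaussian bands; a sample's absorbance is the
concentration-weighted sum, scaled by an instrument path factor and degraded
by multiplicative scatter, an affine baseline and white detector noise.
Protein bands sit at the amide A / I / II positions (~3300, 1650, 1550 cm^-1)
so that the analytically useful regions are the ones a serum assay would use.
Component bands overlap deliberately: no single wavenumber isolates IgG, so
the calibration problem is genuinely multivariate.

IgG concentrations follow a two-component lognormal mixture truncated to the
population range: a low-IgG subpopulation (the failure-of-passive-transfer
animals, ~12% of the herd) and a main component whose untruncated moments are
solved numerically so that the truncated mixture reproduces the configured
herd mean and SD (2654 / 1305 mg/dL by default).  A single lognormal at those
moments would put only ~3% of animals below 1000 mg/dL; the mixture restores
the observed ~12% low tail.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .io import ReferenceTable, Spectrum, SpectrumSet

__all__ = [
    "GaussianBand",
    "Component",
    "PopulationConfig",
    "InstrumentProfile",
    "SyntheticDataset",
    "default_components",
    "lab_instrument",
    "portable_instrument",
    "sample_concentrations",
    "pure_component_spectrum",
    "synthesize_spectrum",
    "generate_dataset",
    "inject_outlier",
]


@dataclass(frozen=True)
class GaussianBand:
    """One Gaussian absorption band of a pure component.

    ``height`` is absorbance per (mg/dL) of the owning component at band center.
    """

    center: float  # cm^-1
    width: float   # Gaussian sigma, cm^-1
    height: float  # AU per mg/dL

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be > 0")
        if not (650.0 <= self.center <= 4000.0):
            raise ValueError(f"band center {self.center} outside 650-4000 cm^-1")


@dataclass(frozen=True)
class Component:
    name: str
    bands: tuple[GaussianBand, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError(f"component {self.name!r} needs at least one band")


@dataclass(frozen=True)
class PopulationConfig:
    """Population-level concentration model; defaults match an alpaca herd survey."""

    n_samples: int = 175
    igg_mean: float = 2654.0    # mg/dL
    igg_sd: float = 1305.0      # mg/dL
    igg_min: float = 394.0      # mg/dL
    igg_max: float = 6327.0     # mg/dL
    # low-IgG subpopulation (failed passive transfer): mixture weight and moments.
    # A single lognormal at the herd moments puts only ~3% below 1000 mg/dL; the
    # observed herd has ~12% there, i.e. a distinct low tail.
    low_fraction: float = 0.12
    low_mean: float = 700.0     # mg/dL
    low_sd: float = 180.0       # mg/dL
    # interferent marginals: name -> (mean, sd) in mg/dL
    interferent_distributions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "albumin": (3600.0, 450.0),
            "other_globulins": (1600.0, 420.0),
            "matrix": (1000.0, 120.0),
        }
    )
    reference_cv: float = 0.05  # fractional noise of the reference assay

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if not (self.igg_min < self.igg_mean < self.igg_max) and self.igg_min != self.igg_max:
            raise ValueError("require igg_min < igg_mean < igg_max")
        if self.igg_min > self.igg_max:
            raise ValueError("impossible truncation bounds: igg_min > igg_max")
        if self.reference_cv < 0:
            raise ValueError("reference_cv must be >= 0")
        if not (0.0 <= self.low_fraction < 1.0):
            raise ValueError("low_fraction must be in [0, 1)")

    def main_component_moments(self) -> tuple[float, float]:
        """Mean and SD of the non-low mixture component so the overall mixture
        reproduces ``igg_mean``/``igg_sd`` exactly (before truncation)."""
        p, ml, sl = self.low_fraction, self.low_mean, self.low_sd
        if p == 0.0:
            return self.igg_mean, self.igg_sd
        mh = (self.igg_mean - p * ml) / (1.0 - p)
        ex2 = self.igg_sd**2 + self.igg_mean**2
        vh = (ex2 - p * (sl**2 + ml**2)) / (1.0 - p) - mh**2
        if vh <= 0:
            raise ValueError("low-IgG subpopulation incompatible with overall moments")
        return mh, float(np.sqrt(vh))


@dataclass(frozen=True)
class InstrumentProfile:
    """Intensity scaling and noise model of one spectrometer.

    ``path_scale`` multiplies all absorbances (effective optical pathlength);
    the portable unit runs slightly hotter than the benchtop one.  Noise terms
    are drawn per replicate: a multiplicative scatter factor ~N(1, scatter_sd),
    an affine baseline offset + slope*(nu - grid_start), and i.i.d. white noise
    per point.
    """

    name: str = "lab"
    path_scale: float = 1.0
    noise_sd: float = 3.0e-3          # AU per point
    baseline_offset_sd: float = 2.0e-3  # AU
    baseline_slope_sd: float = 1.0e-6   # AU per cm^-1
    # slowly varying (non-affine) baseline wander: random-phase sinusoid amplitude.
    # Off by default; affine wander alone spans two directions that a latent-factor
    # model simply absorbs, so studying baseline-sensitive preprocessing needs this.
    baseline_wave_sd: float = 0.0       # AU
    baseline_wave_period: float = 1200.0  # cm^-1
    scatter_sd: float = 0.01
    grid_start: float = 4000.0
    grid_end: float = 650.0
    grid_step: float = 4.0
    replicates: int = 2

    def __post_init__(self) -> None:
        if self.path_scale <= 0:
            raise ValueError("path_scale must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not (self.grid_start > self.grid_end and self.grid_step > 0):
            raise ValueError("grid must cover grid_start down to grid_end")

    def grid(self) -> np.ndarray:
        """Descending wavenumber grid (grid_start first)."""
        return np.arange(self.grid_start, self.grid_end, -self.grid_step, dtype=float)


def lab_instrument(**overrides) -> InstrumentProfile:
    return replace(InstrumentProfile(name="lab", path_scale=1.0, noise_sd=3.0e-3), **overrides)


def portable_instrument(**overrides) -> InstrumentProfile:
    # longer effective pathlength -> higher raw intensities; the compact detector
    # is noisier, leaving both instruments with comparable calibration quality
    return replace(InstrumentProfile(name="portable", path_scale=1.3, noise_sd=9.0e-3), **overrides)


def default_components() -> tuple[Component, ...]:
    """IgG plus overlapping interferents; heights give ~0.3-0.5 AU peaks at serum levels."""
    return (
        Component(
            "IgG",
            (
                GaussianBand(3300.0, 120.0, 6.0e-5),
                GaussianBand(1650.0, 35.0, 1.1e-4),
                GaussianBand(1550.0, 30.0, 7.5e-5),
            ),
        ),
        Component(
            "albumin",
            (
                GaussianBand(3290.0, 130.0, 5.5e-5),
                GaussianBand(1653.0, 38.0, 1.0e-4),
                GaussianBand(1547.0, 32.0, 7.0e-5),
            ),
        ),
        Component(
            "other_globulins",
            (
                GaussianBand(3310.0, 115.0, 5.0e-5),
                GaussianBand(1648.0, 33.0, 9.0e-5),
                GaussianBand(1553.0, 29.0, 6.5e-5),
            ),
        ),
        Component(
            "matrix",
            (
                GaussianBand(2200.0, 900.0, 2.0e-5),
                GaussianBand(1400.0, 300.0, 1.5e-5),
            ),
        ),
    )


@dataclass
class SyntheticDataset:
    spectra: SpectrumSet
    reference: ReferenceTable
    true_concentrations: dict[str, dict[str, float]]  # sample_id -> component -> mg/dL
    seed: int

    def __post_init__(self) -> None:
        ref_ids = set(self.reference.table["sample_id"])
        for s in self.spectra:
            if s.sample_id not in ref_ids:
                raise ValueError(f"spectrum sample {s.sample_id!r} missing from reference table")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _truncated_lognormal_moments(mu: float, sigma: float, a: float, b: float):
    """(mass inside [a,b], E[X | in], E[X^2 | in]) for lognormal(mu, sigma)."""
    from scipy.stats import norm

    al = (np.log(a) - mu) / sigma
    be = (np.log(b) - mu) / sigma
    z = norm.cdf(be) - norm.cdf(al)
    m1 = np.exp(mu + sigma**2 / 2) * (norm.cdf(be - sigma) - norm.cdf(al - sigma)) / z
    m2 = np.exp(2 * mu + 2 * sigma**2) * (norm.cdf(be - 2 * sigma) - norm.cdf(al - 2 * sigma)) / z
    return float(z), float(m1), float(m2)


def _calibrated_main_moments(config: PopulationConfig) -> tuple[float, float]:
    """Untruncated moments of the main mixture component such that the
    *truncated* mixture reproduces the configured overall mean and SD.

    Truncation to [igg_min, igg_max] trims both tails and would otherwise
    shrink the realized SD below the configured value; a short fixed-point
    iteration on the closed-form truncated-lognormal moments compensates.
    """
    p, a, b = config.low_fraction, config.igg_min, config.igg_max
    target_m, target_s = config.igg_mean, config.igg_sd
    if p > 0:
        mu_l, sig_l = _lognormal_params(config.low_mean, config.low_sd)
        zl, m1l, m2l = _truncated_lognormal_moments(mu_l, sig_l, a, b)
    mh, sh = config.main_component_moments()
    for _ in range(200):
        mu_h, sig_h = _lognormal_params(mh, sh)
        zh, m1h, m2h = _truncated_lognormal_moments(mu_h, sig_h, a, b)
        if p > 0:
            w = p * zl / (p * zl + (1 - p) * zh)
            mean = w * m1l + (1 - w) * m1h
            ex2 = w * m2l + (1 - w) * m2h
        else:
            mean, ex2 = m1h, m2h
        sd = np.sqrt(max(ex2 - mean**2, 1e-12))
        if abs(mean - target_m) < 1e-9 and abs(sd - target_s) < 1e-9:
            break
        mh += target_m - mean
        sh *= target_s / sd
        if mh <= a or sh <= 0:
            raise ValueError("impossible truncation bounds for the configured moments")
    return mh, sh


def sample_concentrations(
    config: PopulationConfig, seed: int
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Draw per-sample component concentrations and noisy reference IgG values.

    Returns ``(concentrations, reference_igg)`` where ``concentrations`` maps
    component name -> vector of true mg/dL (key ``"IgG"`` included) and
    ``reference_igg`` is true IgG perturbed by the reference-assay CV.
    """
    rng = np.random.default_rng([int(seed), 0x1661])
    n = config.n_samples
    if config.igg_min == config.igg_max:
        igg = np.full(n, float(config.igg_min))
    else:
        mh, sh = _calibrated_main_moments(config)
        mu_h, sig_h = _lognormal_params(mh, sh)
        if config.low_fraction > 0:
            mu_l, sig_l = _lognormal_params(config.low_mean, config.low_sd)
        igg = np.empty(n)
        filled = 0
        for _ in range(1000):
            m = 2 * (n - filled) + 16
            draw = rng.lognormal(mu_h, sig_h, size=m)
            if config.low_fraction > 0:
                low = rng.lognormal(mu_l, sig_l, size=m)
                is_low = rng.random(m) < config.low_fraction
                draw = np.where(is_low, low, draw)
            ok = draw[(draw >= config.igg_min) & (draw <= config.igg_max)]
            take = min(ok.size, n - filled)
            igg[filled : filled + take] = ok[:take]
            filled += take
            if filled == n:
                break
        else:
            raise ValueError("impossible truncation bounds: acceptance region too small")
    conc: dict[str, np.ndarray] = {"IgG": igg}
    for name, (mean, sd) in config.interferent_distributions.items():
        draw = rng.normal(mean, sd, size=n)
        conc[name] = np.clip(draw, 0.0, None)
    reference = igg * (1.0 + rng.normal(0.0, config.reference_cv, size=n)) if config.reference_cv > 0 else igg.copy()
    reference = np.clip(reference, 1e-6, None)
    return conc, reference


def pure_component_spectrum(component: Component, grid: np.ndarray) -> np.ndarray:
    """Unit-concentration extinction spectrum: sum of the component's Gaussians."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    if grid.size > 1 and not (np.all(np.diff(grid) < 0) or np.all(np.diff(grid) > 0)):
        raise ValueError("grid must be strictly monotone")
    out = np.zeros_like(grid)
    for band in component.bands:
        out += band.height * np.exp(-((grid - band.center) ** 2) / (2.0 * band.width**2))
    return out


def synthesize_spectrum(
    concentrations: dict[str, float],
    components: tuple[Component, ...],
    instrument: InstrumentProfile,
    replicate_seed,
    sample_id: str = "S0",
    replicate_id: int = 1,
) -> Spectrum:
    """One replicate spectrum: Beer-Lambert mixture + scatter, baseline and noise."""
    names = {c.name for c in components}
    missing = names.difference(concentrations)
    if missing:
        raise ValueError(f"missing concentrations for components: {sorted(missing)}")
    for c in components:
        if concentrations[c.name] < 0:
            raise ValueError(f"negative concentration for {c.name!r}")
    grid = instrument.grid()
    clean = np.zeros_like(grid)
    for c in components:
        clean += concentrations[c.name] * pure_component_spectrum(c, grid)
    rng = np.random.default_rng(replicate_seed)
    scatter = 1.0 + rng.normal(0.0, instrument.scatter_sd) if instrument.scatter_sd > 0 else 1.0
    offset = rng.normal(0.0, instrument.baseline_offset_sd) if instrument.baseline_offset_sd > 0 else 0.0
    slope = rng.normal(0.0, instrument.baseline_slope_sd) if instrument.baseline_slope_sd > 0 else 0.0
    wave = 0.0
    if instrument.baseline_wave_sd > 0:
        amp = rng.normal(0.0, instrument.baseline_wave_sd)
        period = instrument.baseline_wave_period * (1.0 + 0.3 * rng.uniform(-1.0, 1.0))
        phase = rng.uniform(0.0, 2.0 * np.pi)
        wave = amp * np.sin(2.0 * np.pi * grid / period + phase)
    noise = rng.normal(0.0, instrument.noise_sd, size=grid.size) if instrument.noise_sd > 0 else 0.0
    absorbance = (
        scatter * instrument.path_scale * clean
        + offset
        + slope * (grid - instrument.grid_start)
        + wave
        + noise
    )
    return Spectrum(sample_id, replicate_id, instrument.name, grid, absorbance)


def generate_dataset(
    population: PopulationConfig,
    components: tuple[Component, ...] | None = None,
    instrument: InstrumentProfile | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """n_samples x replicates spectra plus a reference table, fully seeded.

    Per-replicate noise seeds derive deterministically from the master seed, so
    the same seed reproduces the dataset bit-for-bit and different replicates
    get independent noise.
    """
    components = default_components() if components is None else components
    instrument = lab_instrument() if instrument is None else instrument
    conc, reference = sample_concentrations(population, seed)
    n = population.n_samples
    width = len(str(n))
    sample_ids = [f"S{i + 1:0{width}d}" for i in range(n)]
    spectra = []
    true_conc: dict[str, dict[str, float]] = {}
    for i, sid in enumerate(sample_ids):
        per_sample = {name: float(v[i]) for name, v in conc.items()}
        true_conc[sid] = per_sample
        for rep in range(1, instrument.replicates + 1):
            spectra.append(
                synthesize_spectrum(
                    per_sample,
                    components,
                    instrument,
                    replicate_seed=[int(seed), 0x5EED, i, rep, zlib.crc32(instrument.name.encode())],
                    sample_id=sid,
                    replicate_id=rep,
                )
            )
    ref_table = ReferenceTable.from_mapping(dict(zip(sample_ids, reference)))
    return SyntheticDataset(SpectrumSet(spectra), ref_table, true_conc, int(seed))


def inject_outlier(
    dataset: SyntheticDataset,
    sample_id: str,
    replicate_id: int,
    magnitude: float,
    fraction: float = 1.0,
) -> SyntheticDataset:
    """Corrupt one replicate with an additive offset over a contiguous block of points.

    ``fraction`` is the fraction of grid points corrupted, starting from the
    high-wavenumber end.  Used as a fixture for the Dixon-Q screen: a
    full-region gross offset should be excluded, a 10%-of-points one should not.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    found = False
    spectra = []
    for s in dataset.spectra:
        if s.sample_id == sample_id and s.replicate_id == replicate_id:
            found = True
            n_bad = int(round(fraction * s.wavenumbers.size))
            a = s.absorbances.copy()
            a[:n_bad] += magnitude
            spectra.append(s.replace(absorbances=a))
        else:
            spectra.append(s)
    if not found:
        raise KeyError(f"no replicate {sample_id}:{replicate_id} in dataset")
    return SyntheticDataset(
        SpectrumSet(spectra), dataset.reference, dataset.true_concentrations, dataset.seed
    )
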