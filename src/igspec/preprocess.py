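"""Spectral pre-processing: Savitzky-Golay smoothing/derivatives, SNV and
vector normalization, analysis-region selection and replicate averaging.

The pipeline order is fixed: base operator (smoothing or derivative), then
normalization over the edge-trimmed grid, then region selection.  Nine named
presets cover the base x normalization combinations used for trial
calibrations (``smooth``, ``smooth_snv``, ``smooth_vec``, ``d1``, ``d1_snv``,
``d1_vec``, ``d2``, ``d2_snv``, ``d2_vec``).

Derivatives are Savitzky-Golay derivatives with respect to wavenumber.  The
grid is stored descending (4000 cm^-1 first), so the derivative weights pick
up a (-1)^order sign relative to the array coordinate.  Edge half-windows are
dropped rather than extrapolated; the retained analysis regions are interior
anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_coeffs

from .io import Spectrum, SpectrumSet

__all__ = [
    "PreprocessConfig",
    "PRESETS",
    "DEFAULT_REGIONS",
    "savgol_weights",
    "apply_savgol",
    "snv",
    "vector_normalize",
    "select_regions",
    "preprocess_set",
    "average_replicates",
]

DEFAULT_REGIONS: tuple[tuple[float, float], ...] = ((3700.0, 2600.0), (1800.0, 1300.0))

_BASES = {"smoothing": 0, "first_derivative": 1, "second_derivative": 2}
_NORMALIZATIONS = ("none", "snv", "vector")


@dataclass(frozen=True)
class PreprocessConfig:
    base: str = "smoothing"
    window: int = 9
    polyorder: int = 2
    normalization: str = "none"
    regions: tuple[tuple[float, float], ...] = DEFAULT_REGIONS

    def __post_init__(self) -> None:
        if self.base not in _BASES:
            raise ValueError(f"unknown base operator {self.base!r}")
        if self.normalization not in _NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.window % 2 == 0 or self.window <= self.polyorder:
            raise ValueError("window must be odd and > polyorder")
        if _BASES[self.base] > self.polyorder:
            raise ValueError("derivative order must be <= polyorder")

    @property
    def deriv_order(self) -> int:
        return _BASES[self.base]


PRESETS: dict[str, PreprocessConfig] = {
    "smooth": PreprocessConfig(base="smoothing", normalization="none"),
    "smooth_snv": PreprocessConfig(base="smoothing", normalization="snv"),
    "smooth_vec": PreprocessConfig(base="smoothing", normalization="vector"),
    "d1": PreprocessConfig(base="first_derivative", normalization="none"),
    "d1_snv": PreprocessConfig(base="first_derivative", normalization="snv"),
    "d1_vec": PreprocessConfig(base="first_derivative", normalization="vector"),
    "d2": PreprocessConfig(base="second_derivative", normalization="none"),
    "d2_snv": PreprocessConfig(base="second_derivative", normalization="snv"),
    "d2_vec": PreprocessConfig(base="second_derivative", normalization="vector"),
}


def savgol_weights(window: int, polyorder: int, deriv_order: int = 0, step: float = 1.0) -> np.ndarray:
    """Convolution weights of the local least-squares polynomial filter.

    ``step`` is the *signed* grid spacing (nu[1] - nu[0]); derivative weights
    are scaled to absorbance per cm^-1 per derivative order and carry the sign
    of the grid orientation.  Smoothing weights sum to 1, derivative weights
    to 0.
    """
    if window % 2 == 0 or not (0 <= deriv_order <= polyorder < window):
        raise ValueError("need odd window and 0 <= deriv_order <= polyorder < window")
    if step == 0:
        raise ValueError("zero grid step")
    w = savgol_coeffs(window, polyorder, deriv=deriv_order, delta=abs(step), use="dot")
    return w * np.sign(step) ** deriv_order


def apply_savgol(spectrum: Spectrum, config: PreprocessConfig) -> Spectrum:
    """Convolve interior points; drop the half-window at each end of the grid."""
    n = spectrum.wavenumbers.size
    if n < config.window:
        raise ValueError(f"spectrum of {n} points shorter than window {config.window}")
    step = spectrum.wavenumbers[1] - spectrum.wavenumbers[0]
    w = savgol_weights(config.window, config.polyorder, config.deriv_order, step)
    # 'valid' correlation == dot product of each window with the 'dot' coefficients
    out = np.correlate(spectrum.absorbances, w, mode="valid")
    half = config.window // 2
    return spectrum.replace(
        wavenumbers=spectrum.wavenumbers[half : n - half].copy(), absorbances=out
    )


def snv(spectrum: Spectrum) -> Spectrum:
    """Standard normal variate: per-spectrum center and scale to unit sample SD."""
    a = spectrum.absorbances
    if a.size < 2:
        raise ValueError("SNV needs at least 2 points")
    sd = a.std(ddof=1)
    if sd == 0:
        raise ValueError("SNV undefined for a constant spectrum")
    return spectrum.replace(absorbances=(a - a.mean()) / sd)


def vector_normalize(spectrum: Spectrum) -> Spectrum:
    """Scale to unit Euclidean norm."""
    a = spectrum.absorbances
    norm = np.linalg.norm(a)
    if norm == 0:
        raise ValueError("vector normalization undefined for an all-zero spectrum")
    return spectrum.replace(absorbances=a / norm)


def region_mask(grid: np.ndarray, regions) -> np.ndarray:
    mask = np.zeros(grid.size, dtype=bool)
    for lo, hi in (sorted(r) for r in regions):
        mask |= (grid >= lo) & (grid <= hi)
    return mask


def select_regions(spectrum: Spectrum, regions=DEFAULT_REGIONS) -> Spectrum:
    """Keep points inside the closed wavenumber intervals; descending order kept."""
    mask = region_mask(spectrum.wavenumbers, regions)
    if not mask.any():
        raise ValueError("region selection leaves no points")
    return spectrum.with_points(mask)


def preprocess_set(spectrum_set: SpectrumSet, config: PreprocessConfig) -> SpectrumSet:
    """Base operator -> normalization -> region selection, per spectrum."""
    out = []
    for s in spectrum_set:
        s = apply_savgol(s, config)
        if config.normalization == "snv":
            s = snv(s)
        elif config.normalization == "vector":
            s = vector_normalize(s)
        s = select_regions(s, config.regions)
        out.append(s)
    return SpectrumSet(out)


def average_replicates(spectrum_set: SpectrumSet) -> SpectrumSet:
    """One spectrum per sample: point-wise mean of its surviving replicates."""
    groups: dict[str, list[Spectrum]] = {}
    for s in spectrum_set:
        groups.setdefault(s.sample_id, []).append(s)
    out = []
    for sid, reps in groups.items():
        if not reps:  # pragma: no cover - empty groups cannot be constructed
            raise ValueError(f"sample {sid!r} has no surviving replicates")
        mean = np.mean([r.absorbances for r in reps], axis=0)
        out.append(
            Spectrum(sid, 0, reps[0].instrument, reps[0].wavenumbers.copy(), mean)
        )
    return SpectrumSet(out)
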