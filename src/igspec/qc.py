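"""Dixon's Q-test spectrum screening.

At every retained wavenumber the cohort of spectra is tested with Dixon's
r10 statistic: the spectrum owning the minimum is flagged when
q_low = (x(2)-x(1))/(x(n)-x(1)) exceeds the critical value, and likewise the
maximum owner via q_high.  A spectrum is excluded when the fraction of
wavenumbers at which it is flagged exceeds ``exclusion_fraction`` (default
0.5) at the chosen confidence (default 95%).

Two-tailed critical values follow the standard r10 table for n = 3..30; for
larger cohorts (the test predates its use on hundreds of spectra) a smooth
monotone curve fitted through the tabulated tail is used and the report marks
the values as extrapolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SpectrumSet

__all__ = ["DixonConfig", "QcReport", "dixon_q", "q_critical", "screen_spectra"]

# Two-tailed r10 critical values (Rorabacher 1991), n = 3..30.
_Q_TABLE = {
    0.90: [
        0.941, 0.765, 0.642, 0.560, 0.507, 0.468, 0.437, 0.412, 0.392, 0.376,
        0.361, 0.349, 0.338, 0.329, 0.320, 0.313, 0.306, 0.300, 0.295, 0.290,
        0.285, 0.281, 0.277, 0.273, 0.269, 0.266, 0.263, 0.260,
    ],
    0.95: [
        0.970, 0.829, 0.710, 0.625, 0.568, 0.526, 0.493, 0.466, 0.444, 0.426,
        0.410, 0.396, 0.384, 0.374, 0.365, 0.356, 0.349, 0.342, 0.337, 0.331,
        0.326, 0.321, 0.317, 0.312, 0.308, 0.305, 0.301, 0.298,
    ],
    0.99: [
        0.994, 0.926, 0.821, 0.740, 0.680, 0.634, 0.598, 0.568, 0.542, 0.522,
        0.503, 0.488, 0.475, 0.463, 0.452, 0.442, 0.433, 0.425, 0.418, 0.411,
        0.404, 0.399, 0.393, 0.388, 0.384, 0.380, 0.376, 0.372,
    ],
}


@dataclass(frozen=True)
class DixonConfig:
    confidence: float = 0.95
    exclusion_fraction: float = 0.5
    scope: str = "cohort"  # or "replicate_group"

    def __post_init__(self) -> None:
        if not (0.0 < self.confidence < 1.0):
            raise ValueError("confidence must be in (0, 1)")
        if not (0.0 < self.exclusion_fraction <= 1.0):
            raise ValueError("exclusion_fraction must be in (0, 1]")
        if self.scope not in ("cohort", "replicate_group"):
            raise ValueError(f"unknown scope {self.scope!r}")


@dataclass
class QcReport:
    """Per-spectrum flag fractions and exclusion decisions."""

    table: pd.DataFrame  # columns: key, sample_id, replicate_id, flagged_fraction, excluded
    confidence: float
    exclusion_fraction: float
    scope: str
    n_group: int
    critical_extrapolated: bool
    skipped: bool = False

    def excluded_keys(self) -> list[str]:
        return list(self.table.loc[self.table["excluded"], "key"])


def dixon_q(values) -> tuple[float, float]:
    """(q_low, q_high) of Dixon's r10 statistic; (0, 0) signals no outlier for zero range."""
    x = np.sort(np.asarray(values, dtype=float))
    if x.size < 3:
        raise ValueError("Dixon's Q needs at least 3 values")
    rng = x[-1] - x[0]
    if rng == 0:
        return 0.0, 0.0
    return float((x[1] - x[0]) / rng), float((x[-1] - x[-2]) / rng)


def _fit_tail(confidence: float) -> np.ndarray:
    """Quadratic-in-1/n fit through the n = 10..30 table entries."""
    table = np.asarray(_Q_TABLE[confidence])
    n = np.arange(3, 31)
    sel = n >= 10
    A = np.vander(1.0 / n[sel], 3)  # columns 1/n^2, 1/n, 1
    coef, *_ = np.linalg.lstsq(A, table[sel], rcond=None)
    return coef


_TAIL_COEF = {c: _fit_tail(c) for c in _Q_TABLE}


def q_critical(n: int, confidence: float = 0.95) -> float:
    """Two-tailed r10 critical value; extrapolated beyond the n = 30 table."""
    if n < 3:
        raise ValueError("Dixon's Q needs n >= 3")
    if confidence not in _Q_TABLE:
        raise ValueError(f"confidence must be one of {sorted(_Q_TABLE)}")
    if n <= 30:
        return _Q_TABLE[confidence][n - 3]
    coef = _TAIL_COEF[confidence]
    val = float(np.polyval(coef, 1.0 / n))
    # never above the last tabulated value (monotone decreasing in n)
    return min(val, _Q_TABLE[confidence][-1])


def _screen_group(matrix: np.ndarray, critical: float) -> np.ndarray:
    """Boolean flags, shape (n_spectra, n_points): Dixon flag per wavenumber."""
    n, p = matrix.shape
    order_min = np.argmin(matrix, axis=0)
    order_max = np.argmax(matrix, axis=0)
    part = np.partition(matrix, (0, 1, n - 2, n - 1), axis=0)
    x1, x2, xn1, xn = part[0], part[1], part[-2], part[-1]
    rng = xn - x1
    ok = rng > 0
    q_low = np.zeros(p)
    q_high = np.zeros(p)
    q_low[ok] = (x2[ok] - x1[ok]) / rng[ok]
    q_high[ok] = (xn[ok] - xn1[ok]) / rng[ok]
    flags = np.zeros((n, p), dtype=bool)
    cols = np.arange(p)
    low_hit = q_low > critical
    high_hit = q_high > critical
    flags[order_min[low_hit], cols[low_hit]] = True
    flags[order_max[high_hit], cols[high_hit]] = True
    return flags


def screen_spectra(
    spectrum_set: SpectrumSet, config: DixonConfig = DixonConfig()
) -> tuple[SpectrumSet, QcReport]:
    """Run the per-wavenumber screen; return the filtered set and the report.

    With fewer than 3 spectra in a scope group the screen is skipped with a
    warning (the statistic is undefined), never failed.
    """
    spectra = list(spectrum_set)
    if config.scope == "cohort":
        groups = {"cohort": list(range(len(spectra)))}
    else:
        groups = {}
        for i, s in enumerate(spectra):
            groups.setdefault(s.sample_id, []).append(i)

    frac = np.zeros(len(spectra))
    skipped_any = False
    extrapolated = False
    for name, idx in groups.items():
        if len(idx) < 3:
            warnings.warn(
                f"Dixon-Q screen skipped for group {name!r}: only {len(idx)} spectra (< 3)",
                stacklevel=2,
            )
            skipped_any = True
            continue
        crit = q_critical(len(idx), config.confidence)
        extrapolated = extrapolated or len(idx) > 30
        matrix = np.vstack([spectra[i].absorbances for i in idx])
        flags = _screen_group(matrix, crit)
        frac[idx] = flags.mean(axis=1)

    excluded = frac > config.exclusion_fraction
    table = pd.DataFrame(
        {
            "key": [s.key for s in spectra],
            "sample_id": [s.sample_id for s in spectra],
            "replicate_id": [s.replicate_id for s in spectra],
            "flagged_fraction": frac,
            "excluded": excluded,
        }
    )
    report = QcReport(
        table=table,
        confidence=config.confidence,
        exclusion_fraction=config.exclusion_fraction,
        scope=config.scope,
        n_group=max(len(i) for i in groups.values()),
        critical_extrapolated=extrapolated,
        skipped=skipped_any,
    )
    kept = [s for s, drop in zip(spectra, excluded) if not drop]
    if not kept:
        raise ValueError("Dixon-Q screen excluded every spectrum")
    return SpectrumSet(kept), report
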