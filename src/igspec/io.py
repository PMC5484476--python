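"""Plain-text I/O for spectra and reference IgG tables.

One CSV dialect for multi-spectrum absorbance tables: the first column is the
wavenumber grid (descending, cm^-1), every further column is one replicate
spectrum with header ``<sample_id>:<replicate_id>:<instrument>``.  Reference
tables are two-column CSV (``sample_id,igg_mg_dl``).  Floats are written with
17 significant digits so a write/read round-trip is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectrumSet",
    "ReferenceTable",
    "read_spectra",
    "write_spectra",
    "read_reference",
    "write_reference",
]

VALID_INSTRUMENTS = ("lab", "portable")


@dataclass
class Spectrum:
    """One replicate's absorbance vector on a strictly descending wavenumber grid."""

    sample_id: str
    replicate_id: int
    instrument: str
    wavenumbers: np.ndarray
    absorbances: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbances = np.asarray(self.absorbances, dtype=float)
        if self.wavenumbers.ndim != 1 or self.absorbances.ndim != 1:
            raise ValueError("wavenumbers and absorbances must be 1-D")
        if self.wavenumbers.size != self.absorbances.size:
            raise ValueError(
                f"length mismatch: {self.wavenumbers.size} wavenumbers vs "
                f"{self.absorbances.size} absorbances"
            )
        if self.wavenumbers.size == 0:
            raise ValueError("empty spectrum")
        if not np.all(np.diff(self.wavenumbers) < 0):
            raise ValueError("non-monotone grid: wavenumbers must be strictly descending")
        if not (np.all(np.isfinite(self.wavenumbers)) and np.all(np.isfinite(self.absorbances))):
            raise ValueError("non-finite values in spectrum")
        if self.instrument not in VALID_INSTRUMENTS:
            raise ValueError(f"unknown instrument {self.instrument!r}")
        self.replicate_id = int(self.replicate_id)

    @property
    def key(self) -> str:
        return f"{self.sample_id}:{self.replicate_id}:{self.instrument}"

    def with_points(self, mask_or_index: np.ndarray, absorbances: np.ndarray | None = None) -> "Spectrum":
        """Copy restricted to a subset of grid points (order preserved)."""
        a = self.absorbances if absorbances is None else absorbances
        return Spectrum(
            sample_id=self.sample_id,
            replicate_id=self.replicate_id,
            instrument=self.instrument,
            wavenumbers=self.wavenumbers[mask_or_index],
            absorbances=np.asarray(a)[mask_or_index],
        )

    def replace(self, wavenumbers: np.ndarray | None = None, absorbances: np.ndarray | None = None) -> "Spectrum":
        return Spectrum(
            sample_id=self.sample_id,
            replicate_id=self.replicate_id,
            instrument=self.instrument,
            wavenumbers=self.wavenumbers if wavenumbers is None else wavenumbers,
            absorbances=self.absorbances if absorbances is None else absorbances,
        )


@dataclass
class SpectrumSet:
    """A list of spectra sharing one wavenumber grid."""

    spectra: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError("empty SpectrumSet")
        grid = self.spectra[0].wavenumbers
        for s in self.spectra[1:]:
            if s.wavenumbers.size != grid.size or not np.array_equal(s.wavenumbers, grid):
                raise ValueError(f"inconsistent grid for spectrum {s.key}")
        seen: set[str] = set()
        for s in self.spectra:
            if s.key in seen:
                raise ValueError(f"duplicate replicate key {s.key}")
            seen.add(s.key)

    @property
    def grid(self) -> np.ndarray:
        return self.spectra[0].wavenumbers

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def matrix(self) -> np.ndarray:
        """Spectra stacked row-wise, shape (n_spectra, n_points)."""
        return np.vstack([s.absorbances for s in self.spectra])

    def sample_ids(self) -> list[str]:
        """Unique sample ids, in first-appearance order."""
        out: list[str] = []
        for s in self.spectra:
            if s.sample_id not in out:
                out.append(s.sample_id)
        return out

    def subset(self, keep: Iterable[str]) -> "SpectrumSet":
        """Spectra whose key is in ``keep`` (order preserved)."""
        keys = set(keep)
        return SpectrumSet([s for s in self.spectra if s.key in keys])


@dataclass
class ReferenceTable:
    """sample_id -> reference IgG concentration (mg/dL)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table)
        if list(df.columns) != ["sample_id", "igg_mg_dl"]:
            raise ValueError("reference table must have columns sample_id,igg_mg_dl")
        df = df.assign(
            sample_id=df["sample_id"].astype(str),
            igg_mg_dl=pd.to_numeric(df["igg_mg_dl"], errors="raise").astype(float),
        )
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id {dup!r} in reference table")
        if not (df["igg_mg_dl"] > 0).all():
            raise ValueError("reference IgG concentrations must be > 0 mg/dL")
        self.table = df.reset_index(drop=True)

    @classmethod
    def from_mapping(cls, mapping: dict[str, float]) -> "ReferenceTable":
        return cls(pd.DataFrame({"sample_id": list(mapping), "igg_mg_dl": list(mapping.values())}))

    def __len__(self) -> int:
        return len(self.table)

    def lookup(self, sample_ids: Sequence[str]) -> np.ndarray:
        ser = self.table.set_index("sample_id")["igg_mg_dl"]
        missing = [sid for sid in sample_ids if sid not in ser.index]
        if missing:
            raise KeyError(f"sample ids missing from reference table: {missing[:5]}")
        return ser.loc[list(sample_ids)].to_numpy()


def _parse_column_header(header: str) -> tuple[str, int, str]:
    parts = header.split(":")
    if len(parts) != 3:
        raise ValueError(
            f"bad spectrum column header {header!r}: expected <sample_id>:<replicate_id>:<instrument>"
        )
    sample_id, rep, instrument = parts
    try:
        rep_i = int(rep)
    except ValueError as exc:
        raise ValueError(f"bad replicate id in column header {header!r}") from exc
    return sample_id, rep_i, instrument


def read_spectra(path: str | Path) -> SpectrumSet:
    """Read a multi-spectrum CSV; validates the grid and replicate keys."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError("spectra file needs a wavenumber column and at least one spectrum")
    if df.columns[0] != "wavenumber_cm1":
        raise ValueError(f"first column must be 'wavenumber_cm1', got {df.columns[0]!r}")
    if df.isna().any().any():
        raise ValueError("missing or non-numeric cell in spectra file")
    grid = df["wavenumber_cm1"].to_numpy(dtype=float)
    if not np.all(np.diff(grid) < 0):
        raise ValueError("non-monotone grid (wavenumbers must be strictly descending)")
    spectra = []
    for col in df.columns[1:]:
        sample_id, rep, instrument = _parse_column_header(col)
        spectra.append(
            Spectrum(sample_id, rep, instrument, grid.copy(), df[col].to_numpy(dtype=float))
        )
    return SpectrumSet(spectra)


def write_spectra(spectrum_set: SpectrumSet, path: str | Path) -> None:
    """Write the dialect above with full (17 significant digit) precision."""
    cols = {"wavenumber_cm1": spectrum_set.grid}
    for s in spectrum_set:
        cols[s.key] = s.absorbances
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_reference(path: str | Path) -> ReferenceTable:
    df = pd.read_csv(path, float_precision="round_trip")
    return ReferenceTable(df)


def write_reference(reference: ReferenceTable, path: str | Path) -> None:
    reference.table.to_csv(path, index=False, float_format="%.17g")
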