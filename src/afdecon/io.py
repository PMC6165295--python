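"""Spectrum and cohort-manifest I/O in plain delimited-text formats.

One emission spectrum per file, two columns (wavelength in nm, intensity in
arbitrary units), comma- or tab-delimited, optional header.  Cohort metadata
travels in a separate CSV manifest with one row per sample.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

Tissue = Literal["serum", "liver", "other"]
Group = Literal["sham", "bdl24", "bdl48", "bdl72", "other"]

WAVELENGTH_BOUNDS_NM = (380.0, 780.0)


class SpectrumValidationError(ValueError):
    """A spectrum violated a structural invariant (grid, range, finiteness)."""


class SpectrumParseError(ValueError):
    """A spectrum file could not be parsed; the message names the bad line."""


@dataclasses.dataclass
class Spectrum:
    """Single-channel emission spectrum on a strictly increasing nm grid.

    Parameters
    ----------
    wavelengths_nm : array-like
        Strictly increasing wavelength grid within 380-780 nm.
    intensities : array-like
        Non-negative emission intensities, arbitrary units, same length.
    sample_id, tissue, group
        Acquisition metadata; ``tissue`` and ``group`` are free enums used
        downstream to route tissue-specific metrics.
    total_area_au : float, optional
        Integrated raw emission of the *unnormalized* acquisition (a.u.),
        used to convert relative contributions back to absolute emission.
    provenance : dict
        Free-form processing history (scale factors, crop window, ...).
    """

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    sample_id: str = ""
    tissue: Tissue = "other"
    group: Group = "other"
    total_area_au: float | None = None
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.validate()

    def validate(self) -> None:
        wl, it = self.wavelengths_nm, self.intensities
        if wl.ndim != 1 or it.ndim != 1 or wl.size != it.size:
            raise SpectrumValidationError(
                f"wavelengths and intensities must be equal-length 1-D arrays, "
                f"got shapes {wl.shape} and {it.shape}"
            )
        if wl.size < 2:
            raise SpectrumValidationError("a spectrum needs at least 2 points")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(it))):
            raise SpectrumValidationError("non-finite values in spectrum")
        if np.any(np.diff(wl) <= 0):
            bad = int(np.argmax(np.diff(wl) <= 0))
            raise SpectrumValidationError(
                f"wavelength grid not strictly increasing near index {bad} "
                f"(λ={wl[bad]:g} nm)"
            )
        lo, hi = WAVELENGTH_BOUNDS_NM
        if wl[0] < lo or wl[-1] > hi:
            raise SpectrumValidationError(
                f"wavelengths [{wl[0]:g}, {wl[-1]:g}] nm outside [{lo:g}, {hi:g}] nm"
            )
        if np.any(it < 0):
            raise SpectrumValidationError("negative intensities")

    @property
    def n_points(self) -> int:
        return int(self.wavelengths_nm.size)

    def integrated_area(self) -> float:
        """Trapezoidal integral of the intensities over the nm grid (a.u.·nm)."""
        return float(np.trapezoid(self.intensities, self.wavelengths_nm))

    def replace(self, **changes) -> "Spectrum":
        return dataclasses.replace(self, **changes)


@dataclasses.dataclass
class SampleMeta:
    """Per-sample cohort metadata row."""

    sample_id: str
    group: str
    tissue: str
    replicate: int = 0
    covariates: dict = dataclasses.field(default_factory=dict)


def read_spectrum(
    path: str | Path,
    dialect: Literal["auto", "csv", "tsv"] = "auto",
    **meta,
) -> Spectrum:
    """Read a two-column (wavelength_nm, intensity_au) delimited text file.

    A single header line is tolerated and skipped; any other non-numeric row
    raises :class:`SpectrumParseError` naming the offending line.  Extra
    keyword arguments (``sample_id``, ``tissue``, ...) are forwarded to
    :class:`Spectrum`.
    """
    path = Path(path)
    sep = {"csv": ",", "tsv": "\t", "auto": None}[dialect]
    wl, it = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if sep is None:
                sep = "\t" if "\t" in line else ","
            fields = [f.strip() for f in line.split(sep)]
            if len(fields) < 2:
                raise SpectrumParseError(
                    f"{path}:{lineno}: expected 2 delimited columns, got {len(fields)}"
                )
            try:
                wl.append(float(fields[0]))
                it.append(float(fields[1]))
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise SpectrumParseError(
                    f"{path}:{lineno}: non-numeric row {line!r}"
                ) from None
    if len(wl) < 2:
        raise SpectrumParseError(f"{path}: fewer than 2 data rows")
    meta.setdefault("sample_id", path.stem)
    return Spectrum(np.array(wl), np.array(it), **meta)


def write_spectrum(s: Spectrum, path: str | Path, dialect: Literal["csv", "tsv"] = "csv") -> None:
    """Write a spectrum as two-column delimited text with a header line."""
    sep = "," if dialect == "csv" else "\t"
    with open(path, "w") as fh:
        fh.write(f"wavelength_nm{sep}intensity_au\n")
        for w, i in zip(s.wavelengths_nm, s.intensities):
            fh.write(f"{w:.10g}{sep}{i:.10g}\n")


MANIFEST_COLUMNS = ["sample_id", "group", "tissue", "replicate", "filename"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV; requires unique ``sample_id`` values."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("sample_id", "group", "tissue") if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"manifest {path}: duplicated sample_id {dup!r}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
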