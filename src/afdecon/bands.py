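"""Half-Gaussian modified Gaussian (GMG) bands and the additive spectral model.

Each endogenous fluorophore is represented by one or more GMG bands: the
convolution of a Gaussian (width ``sigma_g``, cm⁻¹) with a one-sided
half-Gaussian (width ``sigma_h``, cm⁻¹), an asymmetric peak evaluated in
wavenumber space where emission line broadening is closest to symmetric.
The convolution has the closed skew-normal form

    f(ν) = (2/ω) φ((ν−ν_c)/ω) Φ(s·α·(ν−ν_c)/ω),
    ω² = σ_g² + σ_h²,  α = σ_h/σ_g,

with φ/Φ the standard normal density/CDF and s = ±1 the skew direction
(``red`` skews toward longer wavelength, i.e. lower wavenumber).  f has unit
area, so a band's single free amplitude parameter is its spectral *area*;
the composed spectrum is a linear combination of fixed band shapes.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator
from scipy.optimize import minimize_scalar
from scipy.special import ndtr

__all__ = [
    "GMGBand",
    "Fluorophore",
    "BandLibrary",
    "BandLibraryError",
    "gmg_profile",
    "compose",
    "band_peak_wavelength",
    "nm_to_wavenumber",
    "read_band_library",
    "write_band_library",
    "default_library",
]

SQRT_2PI = np.sqrt(2.0 * np.pi)


def nm_to_wavenumber(lam_nm):
    """ν (cm⁻¹) = 10⁷ / λ (nm)."""
    return 1.0e7 / np.asarray(lam_nm, dtype=float)


class BandLibraryError(ValueError):
    """Band library file failed schema validation."""


class GMGBand(BaseModel):
    """One asymmetric emission band.

    ``center_nm`` is the location parameter of the underlying Gaussian in nm
    (converted to wavenumber for evaluation); for a skewed band the profile
    maximum is displaced from it (see :func:`band_peak_wavelength`).
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    center_nm: float = Field(gt=0)
    sigma_g_cm1: float = Field(gt=0)
    sigma_h_cm1: float = Field(ge=0)
    skew: Literal["red", "blue"] = "red"
    area: float = Field(default=1.0, ge=0)

    @property
    def center_wavenumber(self) -> float:
        return 1.0e7 / self.center_nm

    @property
    def omega(self) -> float:
        """Scale of the convolved profile, cm⁻¹."""
        return float(np.hypot(self.sigma_g_cm1, self.sigma_h_cm1))

    @property
    def alpha(self) -> float:
        """Signed skew-normal shape parameter in wavenumber space."""
        a = self.sigma_h_cm1 / self.sigma_g_cm1
        # red skew = toward longer λ = toward lower ν
        return -a if self.skew == "red" else a


class Fluorophore(BaseModel):
    """A named emitter, possibly with several bands reported as one group."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str
    report_group: str = ""
    bands: tuple[GMGBand, ...] = Field(min_length=1)

    @model_validator(mode="after")
    def _default_group(self):
        if not self.report_group:
            object.__setattr__(self, "report_group", self.name)
        return self


class BandLibrary(BaseModel):
    """Ordered set of fluorophores for one tissue context."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    tissue: Literal["serum", "liver", "other"]
    fluorophores: tuple[Fluorophore, ...] = Field(min_length=1)
    provenance: str = ""

    @field_validator("fluorophores")
    @classmethod
    def _check(cls, v):
        names = [f.name for f in v]
        if len(set(names)) != len(names):
            raise ValueError("duplicate fluorophore names")
        for f in v:
            for b in f.bands:
                if not (400.0 <= b.center_nm <= 770.0):
                    raise ValueError(
                        f"{f.name}: band center {b.center_nm} nm outside 400-770 nm"
                    )
        return v

    def iter_bands(self) -> Iterator[tuple[Fluorophore, GMGBand]]:
        for f in self.fluorophores:
            for b in f.bands:
                yield f, b

    @property
    def n_bands(self) -> int:
        return sum(len(f.bands) for f in self.fluorophores)

    @property
    def band_labels(self) -> list[str]:
        out = []
        for f in self.fluorophores:
            if len(f.bands) == 1:
                out.append(f.name)
            else:
                out.extend(f"{f.name}[{i}]" for i in range(len(f.bands)))
        return out


def gmg_profile(nu_grid, band: GMGBand) -> np.ndarray:
    """Evaluate ``band.area`` × unit-area GMG profile on a wavenumber grid.

    The unit-area shape is the exact Gaussian ⊛ half-Gaussian convolution in
    its closed skew-normal form; ``sigma_h_cm1 = 0`` degenerates to a pure
    Gaussian of width ``sigma_g_cm1``.
    """
    nu = np.asarray(nu_grid, dtype=float)
    if band.sigma_g_cm1 <= 0:
        raise ValueError("sigma_g must be > 0")
    om = band.omega
    z = (nu - band.center_wavenumber) / om
    dens = np.exp(-0.5 * z * z) / (SQRT_2PI * om)
    return band.area * 2.0 * dens * ndtr(band.alpha * z)


def compose(library: BandLibrary, nu_grid, areas=None) -> np.ndarray:
    """Pointwise sum of all band profiles; linear in every band's area.

    ``areas``, if given, overrides the areas stored on the bands (one value
    per band, in :meth:`BandLibrary.iter_bands` order).
    """
    nu = np.asarray(nu_grid, dtype=float)
    total = np.zeros_like(nu)
    bands = [b for _, b in library.iter_bands()]
    if areas is None:
        areas = [b.area for b in bands]
    if len(areas) != len(bands):
        raise ValueError(f"expected {len(bands)} areas, got {len(areas)}")
    for a, b in zip(areas, bands):
        total += a * gmg_profile(nu, b.model_copy(update={"area": 1.0}))
    return total


def basis_matrix(library: BandLibrary, nu_grid) -> np.ndarray:
    """(n_points × n_bands) matrix of unit-area band profiles."""
    nu = np.asarray(nu_grid, dtype=float)
    cols = [
        gmg_profile(nu, b.model_copy(update={"area": 1.0}))
        for _, b in library.iter_bands()
    ]
    return np.column_stack(cols)


def band_peak_wavelength(band: GMGBand) -> float:
    """Wavelength (nm) of the profile maximum.

    For a symmetric band this is ``center_nm``; skew displaces the mode in
    the skew direction.  Found numerically (the skew-normal mode has no
    closed form).
    """
    if band.sigma_h_cm1 == 0:
        return band.center_nm
    unit = band.model_copy(update={"area": 1.0})
    nc, om = band.center_wavenumber, band.omega
    res = minimize_scalar(
        lambda nu: -gmg_profile(np.array([nu]), unit)[0],
        bounds=(nc - 3 * om, nc + 3 * om),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(1.0e7 / res.x)


# ---------------------------------------------------------------------------
# library I/O

def read_band_library(path: str | Path) -> BandLibrary:
    """Load and validate a band-library JSON file; unknown keys are rejected."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise BandLibraryError(f"{path}: invalid JSON ({exc})") from exc
    try:
        return BandLibrary.model_validate(payload)
    except ValidationError as exc:
        raise BandLibraryError(f"{path}: {exc}") from exc


def write_band_library(lib: BandLibrary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(lib.model_dump(), indent=2) + "\n")


def default_library(tissue: Literal["serum", "liver"]) -> BandLibrary:
    """Packaged default band library for serum or liver."""
    fname = {"serum": "serum_bands.json", "liver": "liver_bands.json"}[tissue]
    payload = json.loads(resources.files("afdecon.data").joinpath(fname).read_text())
    return BandLibrary.model_validate(payload)
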