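"""Preprocessing: peak normalization, wavenumber conversion, cropping, QC.

The fitting pipeline expects spectra that are (i) cropped to the 400-750 nm
acquisition window, (ii) peak-normalized to 100 a.u., (iii) converted to
wavenumber (ν = 10⁷/λ) with intensities carried over unchanged, and
(iv) free of deoxyhemoglobin reabsorption artifacts, which appear as a dip
in the 530-585 nm region and disqualify a spectrum from band fitting.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import savgol_filter

from .io import Spectrum

DEFAULT_HB_WINDOW_NM = (530.0, 585.0)
DEFAULT_HB_THRESHOLD = 0.05


@dataclasses.dataclass
class WavenumberSpectrum:
    """A spectrum re-expressed on a wavenumber abscissa (cm⁻¹).

    Stored in source order, so the grid is strictly decreasing when the
    source wavelength grid is increasing.  Intensities are identical to the
    source (abscissa-only conversion, no Jacobian rescaling).
    """

    wavenumbers_cm1: np.ndarray
    intensities: np.ndarray
    source: Spectrum

    def __post_init__(self):
        self.wavenumbers_cm1 = np.asarray(self.wavenumbers_cm1, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers_cm1.shape != self.intensities.shape:
            raise ValueError("grid/intensity length mismatch")

    def to_spectrum(self) -> Spectrum:
        """Convert back to a wavelength-domain :class:`Spectrum`."""
        lam = 1.0e7 / self.wavenumbers_cm1
        order = np.argsort(lam)
        return self.source.replace(
            wavelengths_nm=lam[order], intensities=self.intensities[order]
        )


@dataclasses.dataclass
class QCResult:
    """Outcome of an artifact screen; ``passed`` iff score < threshold."""

    passed: bool
    artifact_score: float
    reason: str = ""


def normalize_peak(s: Spectrum, target: float = 100.0) -> Spectrum:
    """Scale a spectrum so its maximum equals ``target`` (default 100 a.u.).

    Shape-preserving (single multiplicative factor); the factor is recorded
    in provenance.  Raises on an all-zero spectrum.
    """
    peak = float(np.max(s.intensities))
    if peak <= 0:
        raise ValueError("cannot peak-normalize an all-zero spectrum")
    factor = target / peak
    prov = dict(s.provenance)
    prov["peak_norm_factor"] = prov.get("peak_norm_factor", 1.0) * factor
    return s.replace(intensities=s.intensities * factor, provenance=prov)


def to_wavenumber(s: Spectrum) -> WavenumberSpectrum:
    """ν_i = 10⁷/λ_i; intensities carried over unchanged."""
    if np.any(s.wavelengths_nm <= 0):
        raise ValueError("wavelengths must be positive")
    return WavenumberSpectrum(1.0e7 / s.wavelengths_nm, s.intensities.copy(), s)


def crop(s: Spectrum, lo_nm: float = 400.0, hi_nm: float = 750.0) -> Spectrum:
    """Restrict to wavelengths in [lo_nm, hi_nm]."""
    if lo_nm >= hi_nm:
        raise ValueError(f"invalid crop window [{lo_nm}, {hi_nm}]")
    mask = (s.wavelengths_nm >= lo_nm) & (s.wavelengths_nm <= hi_nm)
    if mask.sum() < 10:
        raise ValueError(
            f"crop to [{lo_nm}, {hi_nm}] nm leaves {int(mask.sum())} points (< 10)"
        )
    prov = dict(s.provenance)
    prov["crop_nm"] = (float(lo_nm), float(hi_nm))
    return s.replace(
        wavelengths_nm=s.wavelengths_nm[mask],
        intensities=s.intensities[mask],
        provenance=prov,
    )


def detect_hb_reabsorption(
    s: Spectrum,
    window_nm: tuple[float, float] = DEFAULT_HB_WINDOW_NM,
    threshold: float = DEFAULT_HB_THRESHOLD,
    library=None,
) -> QCResult:
    """Screen for a deoxyhemoglobin reabsorption dip inside ``window_nm``.

    A reabsorption notch is a profile alteration the additive fluorophore
    model cannot explain, and the 530-585 nm region legitimately contains a
    between-band valley, so the reference here is model-based: the band
    library is fitted to the (lightly smoothed) spectrum with the window
    *excluded*, and the artifact score is the maximum 11-point rolling mean
    of the relative dip of the data below the model prediction inside the
    window.  Leave-window-out fitting keeps the dip from biasing the
    reference.  ``library`` defaults to the packaged library matching
    ``s.tissue``.  ``passed`` requires ``score < threshold`` strictly, so a
    dip exactly at threshold fails.
    """
    from scipy.optimize import nnls

    from .bands import basis_matrix, default_library

    lo, hi = window_nm
    wl = s.wavelengths_nm
    if wl[0] > lo or wl[-1] < hi:
        raise ValueError(
            f"QC window [{lo}, {hi}] nm outside spectrum range "
            f"[{wl[0]:g}, {wl[-1]:g}] nm"
        )
    if library is None:
        if s.tissue not in ("serum", "liver"):
            raise ValueError(
                "no packaged band library for tissue "
                f"{s.tissue!r}; pass `library` explicitly"
            )
        library = default_library(s.tissue)

    it = s.intensities
    if it.size >= 21:
        it = np.clip(savgol_filter(it, 21, 3), 0.0, None)
    wn = standard_preprocess(s.replace(intensities=it))
    lam = 1.0e7 / wn.wavenumbers_cm1
    inside = (lam >= lo) & (lam <= hi)
    if inside.sum() < 3 or (~inside).sum() < library.n_bands:
        raise ValueError("too few points in or around the QC window")
    B = basis_matrix(library, wn.wavenumbers_cm1)
    areas, _ = nnls(B[~inside], wn.intensities[~inside])
    predicted = B[inside] @ areas
    rel_dip = (predicted - wn.intensities[inside]) / np.maximum(predicted, 1e-9)
    rel_dip = rel_dip[np.argsort(lam[inside])]
    roll = min(11, rel_dip.size)
    smoothed = np.convolve(rel_dip, np.ones(roll) / roll, mode="valid")
    score = float(max(0.0, smoothed.max()))
    passed = score < threshold
    reason = "" if passed else (
        f"reabsorption dip {score:.3f} ≥ threshold {threshold:g} in "
        f"{lo:g}-{hi:g} nm"
    )
    return QCResult(passed=passed, artifact_score=score, reason=reason)


def standard_preprocess(
    s: Spectrum,
    lo_nm: float = 400.0,
    hi_nm: float = 750.0,
    target: float = 100.0,
) -> WavenumberSpectrum:
    """Crop → peak-normalize → wavenumber: the canonical pre-fit chain."""
    return to_wavenumber(normalize_peak(crop(s, lo_nm, hi_nm), target))
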