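"""Synthetic serum and liver autofluorescence cohorts.

Forward model: a sample's spectrum is the additive composition of the band
library's GMG shapes with areas proportional to the sample's fluorophore
contributions, peak-scaled to 100 a.u., plus i.i.d. Gaussian noise (clipped
at zero), then rescaled to a per-sample total emission area.  Per-sample
contributions are drawn around published group means (truncated normal with
sd = SE·√n, renormalized onto the 100 % simplex).  An optional multiplicative
Gaussian notch at 555 nm emulates deoxyhemoglobin reabsorption artifacts for
QC testing, and a piecewise-linear saturating response maps bilirubin molar
concentration to relative AF amplitude.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import reference
from .bands import BandLibrary, basis_matrix, default_library
from .io import Spectrum, write_manifest, write_spectrum

DEFAULT_GRID = (400.0, 750.0, 1.0)
DEFAULT_NOISE_SIGMA = 0.5


class BilirubinResponse(BaseModel):
    """Saturating AF-vs-concentration response of bilirubin in solution.

    Zero below the detection floor, linear up to the saturation onset,
    constant above it; ``smooth_knee`` (fraction of the linear span) rounds
    both corners with quadratic blends when > 0.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    detection_floor_M: float = Field(default=1e-6, gt=0)
    saturation_M: float = Field(default=5e-5, gt=0)
    smooth_knee: float = Field(default=0.0, ge=0.0, le=0.4)

    @model_validator(mode="after")
    def _ordered(self):
        if self.saturation_M <= self.detection_floor_M:
            raise ValueError("saturation_M must exceed detection_floor_M")
        return self


def bilirubin_response(conc_M: float, resp: BilirubinResponse | None = None) -> float:
    """Relative AF amplitude (0-1) for a bilirubin concentration in mol/L.

    The detection floor is the inclusive onset of the linear rise: response
    is 0 at and below the floor, 1 at and above saturation.
    """
    if conc_M < 0:
        raise ValueError("concentration must be non-negative")
    resp = resp or BilirubinResponse()
    lo, hi = resp.detection_floor_M, resp.saturation_M
    x = (conc_M - lo) / (hi - lo)
    if resp.smooth_knee > 0:
        k = resp.smooth_knee
        if x <= -k:
            return 0.0
        if x < k:  # quadratic blend at the floor
            return float((x + k) ** 2 / (4 * k))
        if x < 1 - k:
            return float(x)
        if x < 1 + k:  # quadratic blend at saturation
            return float(1 - (1 + k - x) ** 2 / (4 * k))
        return 1.0
    return float(min(max(x, 0.0), 1.0))


class GroupSpec(BaseModel):
    """Generating distribution for one cohort group.

    ``contributions`` maps fluorophore name → (mean %, SE %); per-sample
    values are drawn with sd = SE·√n and renormalized to sum 100.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str
    n: int = Field(default=5, ge=2)
    contributions: dict[str, tuple[float, float]]
    total_area: tuple[float, float] = (5000.0, 250.0)

    @model_validator(mode="after")
    def _check(self):
        total = sum(m for m, _ in self.contributions.values())
        if not (90.0 <= total <= 110.0):
            raise ValueError(
                f"group {self.name!r}: mean contributions sum to {total:.2f}, "
                "expected ≈100"
            )
        if any(m < 0 or s < 0 for m, s in self.contributions.values()):
            raise ValueError(f"group {self.name!r}: negative mean or SE")
        if self.total_area[0] <= 0:
            raise ValueError("total_area mean must be positive")
        return self


class CohortSpec(BaseModel):
    """Full recipe for a synthetic cohort."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    tissue: Literal["serum", "liver"]
    groups: tuple[GroupSpec, ...] = Field(min_length=1)
    noise_sigma: float = Field(default=DEFAULT_NOISE_SIGMA, ge=0)
    grid: tuple[float, float, float] = DEFAULT_GRID
    seed: int = 0
    artifact_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    artifact_depth: float = Field(default=0.2, gt=0.0, lt=1.0)

    def wavelength_grid(self) -> np.ndarray:
        lo, hi, step = self.grid
        return np.arange(lo, hi + 0.5 * step, step)


def default_cohort_spec(
    tissue: Literal["serum", "liver"],
    n: int = reference.N_PER_GROUP,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    seed: int = 0,
    artifact_rate: float = 0.0,
) -> CohortSpec:
    """Cohort spec whose generating targets are the published group tables."""
    contribs = (
        reference.SERUM_CONTRIBUTIONS
        if tissue == "serum"
        else reference.LIVER_CONTRIBUTIONS
    )
    areas = (
        reference.SERUM_TOTAL_AREAS
        if tissue == "serum"
        else reference.LIVER_TOTAL_AREAS
    )
    groups = tuple(
        GroupSpec(name=g, n=n, contributions=contribs[g], total_area=areas[g])
        for g in reference.GROUP_ORDER
    )
    return CohortSpec(
        tissue=tissue,
        groups=groups,
        noise_sigma=noise_sigma,
        seed=seed,
        artifact_rate=artifact_rate,
    )


def generate_spectrum(
    lib: BandLibrary,
    contributions: dict[str, float],
    total_area: float = 5000.0,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    seed: int | np.random.Generator = 0,
    grid: tuple[float, float, float] = DEFAULT_GRID,
    sample_id: str = "synthetic",
    group: str = "other",
) -> Spectrum:
    """Compose one synthetic spectrum from contribution percentages.

    A fluorophore's area share is split equally across its bands.  Noise is
    i.i.d. Gaussian with ``noise_sigma`` on the peak-100 scale, clipped at
    zero; the final spectrum is rescaled so its integrated nm-domain area is
    ``total_area``.  Deterministic for a given seed.
    """
    missing = [f.name for f in lib.fluorophores if f.name not in contributions]
    if missing:
        raise ValueError(f"contributions missing fluorophores {missing}")
    vals = np.array([contributions[f.name] for f in lib.fluorophores], dtype=float)
    if np.any(vals < 0):
        raise ValueError("contributions must be non-negative")
    if not (90.0 <= vals.sum() <= 110.0):
        raise ValueError(f"contributions sum to {vals.sum():.2f}, expected ≈100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    lam = np.arange(grid[0], grid[1] + 0.5 * grid[2], grid[2])
    nu = 1.0e7 / lam
    areas = []
    for f, v in zip(lib.fluorophores, vals):
        areas.extend([v / len(f.bands)] * len(f.bands))
    y = basis_matrix(lib, nu) @ np.asarray(areas)

    peak = y.max()
    if peak <= 0:
        raise ValueError("composed spectrum is identically zero")
    y = y * (100.0 / peak)
    if noise_sigma > 0:
        y = y + rng.normal(0.0, noise_sigma, size=y.size)
    y = np.clip(y, 0.0, None)

    area_now = np.trapezoid(y, lam)
    y = y * (total_area / area_now)
    return Spectrum(
        lam,
        y,
        sample_id=sample_id,
        tissue=lib.tissue,
        group=group,  # type: ignore[arg-type]
        total_area_au=float(np.trapezoid(y, lam)),
        provenance={"synthetic": True, "noise_sigma": noise_sigma},
    )


def _truncated_normal(rng, mean, sd, size=None, max_tries=100):
    """Normal(mean, sd) truncated at 0 by resampling (clip as last resort)."""
    x = rng.normal(mean, sd, size=size)
    for _ in range(max_tries):
        bad = x < 0
        if not np.any(bad):
            break
        x = np.where(bad, rng.normal(mean, sd, size=size), x)
    return np.clip(x, 0.0, None)


def generate_cohort(
    spec: CohortSpec,
    lib: BandLibrary | None = None,
    seed: int | None = None,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Draw a full cohort; returns (spectra, ground-truth manifest).

    The manifest carries, per sample: group, replicate, measured total area,
    artifact flag, and the generating ('true') contributions — everything
    needed to score recovery without re-reading this module.
    """
    lib = lib or default_library(spec.tissue)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    fluor_names = [f.name for f in lib.fluorophores]

    spectra: list[Spectrum] = []
    rows = []
    for gs in spec.groups:
        unknown = [k for k in gs.contributions if k not in fluor_names]
        if unknown:
            raise ValueError(f"group {gs.name!r}: unknown fluorophores {unknown}")
        for rep in range(gs.n):
            means = np.array([gs.contributions[f][0] for f in fluor_names])
            sds = np.array(
                [gs.contributions[f][1] * np.sqrt(gs.n) for f in fluor_names]
            )
            vals = _truncated_normal(rng, means, sds)
            if vals.sum() <= 0:
                raise ValueError("degenerate contribution draw (all zero)")
            vals = vals / vals.sum() * 100.0
            ta = float(
                _truncated_normal(
                    rng, gs.total_area[0], gs.total_area[1] * np.sqrt(gs.n)
                )
            )
            if ta <= 0:
                ta = gs.total_area[0]
            sid = f"{spec.tissue}_{gs.name}_{rep:02d}"
            s = generate_spectrum(
                lib,
                dict(zip(fluor_names, vals)),
                total_area=ta,
                noise_sigma=spec.noise_sigma,
                seed=rng,
                grid=spec.grid,
                sample_id=sid,
                group=gs.name,
            )
            artifact = bool(rng.random() < spec.artifact_rate)
            if artifact:
                s = inject_hb_artifact(s, spec.artifact_depth)
            spectra.append(s)
            row = {
                "sample_id": sid,
                "group": gs.name,
                "tissue": spec.tissue,
                "replicate": rep,
                "total_area_au": s.total_area_au,
                "has_artifact": artifact,
            }
            row.update({f"true_{f}": v for f, v in zip(fluor_names, vals)})
            rows.append(row)
    return spectra, pd.DataFrame(rows)


def inject_hb_artifact(
    s: Spectrum,
    depth: float,
    center_nm: float = 555.0,
    width_nm: float = 15.0,
) -> Spectrum:
    """Multiply by (1 − depth·Gaussian notch): a reabsorption-like dip.

    ``depth`` is the fractional dip at the notch center; 0 is the identity,
    values ≥ 1 are rejected (full extinction is non-physical here).
    """
    if not (0.0 <= depth < 1.0):
        raise ValueError(f"depth must be in [0, 1), got {depth}")
    if depth == 0.0:
        return s
    notch = 1.0 - depth * np.exp(
        -0.5 * ((s.wavelengths_nm - center_nm) / width_nm) ** 2
    )
    prov = dict(s.provenance)
    prov["hb_artifact"] = {"depth": depth, "center_nm": center_nm, "width_nm": width_nm}
    return s.replace(intensities=s.intensities * notch, provenance=prov)


def write_cohort(
    spectra: list[Spectrum], manifest: pd.DataFrame, outdir: str | Path
) -> pd.DataFrame:
    """Write per-sample spectrum CSVs plus the manifest; returns the manifest
    with a ``filename`` column added."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    filenames = []
    for s in spectra:
        fname = f"{s.sample_id}.csv"
        write_spectrum(s, outdir / fname)
        filenames.append(fname)
    manifest["filename"] = filenames
    write_manifest(manifest, outdir / "manifest.csv")
    return manifest
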