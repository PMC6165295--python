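"""Constrained least-squares spectral decomposition.

The model: a preprocessed emission spectrum y(ν) is a non-negative linear
combination of fixed GMG band shapes,

    y(ν) = Σ_b a_b f_b(ν) + ε,   a_b ≥ 0,

fitted by trust-region Levenberg–Marquardt-type nonlinear least squares
(`scipy.optimize.least_squares`) minimizing the unweighted sum of squared
deviations χ².  Band centers and widths are fixed by default (areas-only
fit, a well-posed inverse problem); optionally centers may float within a
small bound.  Multi-start with jittered initial areas guards against
spurious local minima when centers float.

Usage follows the model/results idiom::

    model = SpectralDecomposition(wn_spectrum, library)
    res = model.fit()
    res.summary()
    res.contributions()
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .bands import BandLibrary, basis_matrix, gmg_profile
from .io import Spectrum
from .preprocess import WavenumberSpectrum, standard_preprocess

DEFAULT_RESTARTS = 5
DEFAULT_SEED = 0
DEFAULT_TOL = 1e-10
DEFAULT_MAX_NFEV = 2000


class FitConfigurationError(ValueError):
    """Library and spectrum are incompatible (e.g. no spectral overlap)."""


@dataclasses.dataclass
class DecompositionResults:
    """Fitted band areas with goodness-of-fit diagnostics.

    Attributes
    ----------
    areas : pandas.Series
        Fitted area per band (a.u.·cm⁻¹), indexed by band label.
    chi2 : float
        Sum of squared residuals at the optimum.
    rsquared : float
        1 − χ²/TSS with TSS the total sum of squares about the data mean.
    resid : ndarray
        Per-point residuals, model − data.
    converged : bool
        True only if the optimizer met its gradient/step tolerances on at
        least one restart.
    bse : pandas.Series
        Asymptotic standard errors of the areas from the Gauss–Newton
        covariance s²(JᵀJ)⁻¹ (NaN where the design is rank-deficient).
    """

    model: "SpectralDecomposition"
    areas: pd.Series
    center_shifts_nm: pd.Series | None
    chi2: float
    rsquared: float
    resid: np.ndarray
    converged: bool
    n_iter: int
    options: dict
    bse: pd.Series = None

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.endog + self.resid

    def contributions(self) -> pd.Series:
        """Relative contribution (%) per fluorophore report group.

        100 × (summed area of the group's bands) / (total fitted area); see
        :func:`afdecon.quantify.relative_contributions`.
        """
        from .quantify import relative_contributions

        return relative_contributions(self)

    def goodness(self, r2_threshold: float = 0.99) -> dict:
        """Diagnostics dict: r², χ², residual summaries, poor-fit flag."""
        resid = self.resid
        signs = np.sign(resid[resid != 0])
        n = signs.size
        runs = int(1 + np.sum(signs[1:] != signs[:-1])) if n else 0
        expected = 1 + (n - 1) / 2.0 if n else 0.0
        return {
            "r2": self.rsquared,
            "chi2": self.chi2,
            "max_abs_resid": float(np.max(np.abs(resid))) if resid.size else 0.0,
            "sign_runs_ratio": runs / expected if expected else float("nan"),
            "poor_fit": bool(self.rsquared < r2_threshold),
        }

    def summary(self) -> str:
        """Plain-text summary table in the statsmodels spirit."""
        lines = [
            "Spectral decomposition (non-negative least squares, fixed GMG shapes)",
            f"  tissue: {self.model.library.tissue}   n points: {self.model.endog.size}"
            f"   n bands: {len(self.areas)}",
            f"  chi2: {self.chi2:.6g}   r2: {self.rsquared:.6f}   "
            f"converged: {self.converged}   nfev: {self.n_iter}",
            "",
            f"  {'band':<22}{'area':>12}{'SE':>12}{'contrib %':>12}",
        ]
        total = float(self.areas.sum())
        for name, a in self.areas.items():
            se = self.bse[name] if self.bse is not None else float("nan")
            pct = 100.0 * a / total if total > 0 else float("nan")
            lines.append(f"  {name:<22}{a:>12.4g}{se:>12.3g}{pct:>12.2f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "areas": {k: float(v) for k, v in self.areas.items()},
            "chi2": float(self.chi2),
            "r2": float(self.rsquared),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "options": self.options,
            "tissue": self.model.library.tissue,
        }
        if self.center_shifts_nm is not None:
            d["center_shifts_nm"] = {
                k: float(v) for k, v in self.center_shifts_nm.items()
            }
        return d

    def plot(self, ax=None):
        """Overlay data, fitted model and residuals (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lam = 1.0e7 / self.model.exog_grid
        ax.plot(lam, self.model.endog, label="data", lw=1)
        ax.plot(lam, self.fittedvalues, label="model", lw=1)
        ax.plot(lam, self.resid, label="residuals", lw=0.8)
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("intensity (a.u.)")
        ax.legend()
        return ax


class SpectralDecomposition:
    """Decompose one preprocessed spectrum into fluorophore band areas.

    Parameters
    ----------
    spectrum : WavenumberSpectrum
        Peak-normalized, cropped spectrum on a wavenumber grid (use
        :func:`afdecon.preprocess.standard_preprocess` or
        :meth:`from_spectrum`).
    library : BandLibrary
        Fixed band shapes; every library band must overlap the grid.
    restarts, seed
        Multi-start count and RNG seed for the ×U(0.5, 2) jitter of initial
        areas; the lowest-χ² restart wins.
    vary_centers, center_bound_nm
        If set, band centers float within ±bound nm of their library values.
    """

    def __init__(
        self,
        spectrum: WavenumberSpectrum,
        library: BandLibrary,
        restarts: int = DEFAULT_RESTARTS,
        seed: int = DEFAULT_SEED,
        vary_centers: bool = False,
        center_bound_nm: float = 5.0,
        tol: float = DEFAULT_TOL,
        max_nfev: int = DEFAULT_MAX_NFEV,
    ):
        self.spectrum = spectrum
        self.library = library
        self.restarts = int(restarts)
        self.seed = int(seed)
        self.vary_centers = bool(vary_centers)
        self.center_bound_nm = float(center_bound_nm)
        self.tol = float(tol)
        self.max_nfev = int(max_nfev)

        self.exog_grid = np.asarray(spectrum.wavenumbers_cm1, dtype=float)
        self.endog = np.asarray(spectrum.intensities, dtype=float)
        self._bands = [b for _, b in library.iter_bands()]
        self._labels = library.band_labels
        self._check_overlap()

    @classmethod
    def from_spectrum(cls, s: Spectrum, library: BandLibrary, **kwargs):
        """Build from a raw wavelength-domain spectrum via the standard
        crop → normalize → wavenumber preprocessing chain."""
        return cls(standard_preprocess(s), library, **kwargs)

    def _check_overlap(self):
        nu_lo, nu_hi = self.exog_grid.min(), self.exog_grid.max()
        for lab, b in zip(self._labels, self._bands):
            if not (nu_lo - 3 * b.omega <= b.center_wavenumber <= nu_hi + 3 * b.omega):
                raise FitConfigurationError(
                    f"band {lab!r} (center {b.center_nm:g} nm) does not overlap "
                    f"the spectrum grid"
                )

    # -- model evaluation ---------------------------------------------------

    def _basis(self, center_shifts_nm: Sequence[float] | None = None) -> np.ndarray:
        if center_shifts_nm is None:
            return basis_matrix(self.library, self.exog_grid)
        cols = []
        for b, d in zip(self._bands, center_shifts_nm):
            shifted = b.model_copy(
                update={"center_nm": b.center_nm + float(d), "area": 1.0}
            )
            cols.append(gmg_profile(self.exog_grid, shifted))
        return np.column_stack(cols)

    def predict(self, areas, center_shifts_nm=None) -> np.ndarray:
        return self._basis(center_shifts_nm) @ np.asarray(areas, dtype=float)

    # -- fitting ------------------------------------------------------------

    def fit(self) -> DecompositionResults:
        y = self.endog
        nb = len(self._bands)
        # equal split of total spectral area (in ν domain) across bands
        total_area = abs(np.trapezoid(y, self.exog_grid))
        a0 = np.full(nb, max(total_area, 1e-12) / nb)

        rng = np.random.default_rng(self.seed)
        starts = [a0]
        for _ in range(max(0, self.restarts - 1)):
            starts.append(a0 * rng.uniform(0.5, 2.0, size=nb))

        fixed_B = None if self.vary_centers else self._basis()
        best = None
        for x0_areas in starts:
            res = self._fit_once(x0_areas, fixed_B)
            if best is None or res.cost < best.cost:
                best = res
        assert best is not None

        areas = np.maximum(best.x[:nb], 0.0)
        shifts = best.x[nb:] if self.vary_centers else None
        B = self._basis(shifts) if self.vary_centers else fixed_B
        resid = B @ areas - y
        chi2 = float(resid @ resid)
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - chi2 / tss if tss > 0 else float("nan")

        bse = self._standard_errors(B, chi2, y.size, nb)
        options = {
            "restarts": self.restarts,
            "seed": self.seed,
            "vary_centers": self.vary_centers,
            "center_bound_nm": self.center_bound_nm if self.vary_centers else 0.0,
            "tol": self.tol,
            "max_nfev": self.max_nfev,
            "fixed_shapes": not self.vary_centers,
        }
        return DecompositionResults(
            model=self,
            areas=pd.Series(areas, index=self._labels, name="area"),
            center_shifts_nm=(
                pd.Series(shifts, index=self._labels, name="center_shift_nm")
                if shifts is not None
                else None
            ),
            chi2=chi2,
            rsquared=r2,
            resid=resid,
            converged=bool(best.status > 0),
            n_iter=int(best.nfev),
            options=options,
            bse=bse,
        )

    def _fit_once(self, a0, fixed_B):
        nb = len(self._bands)
        y = self.endog
        if not self.vary_centers:
            B = fixed_B

            def fun(a):
                return B @ a - y

            def jac(a):
                return B

            return least_squares(
                fun,
                a0,
                jac=jac,
                bounds=(np.zeros(nb), np.full(nb, np.inf)),
                method="trf",
                xtol=self.tol,
                ftol=self.tol,
                gtol=self.tol,
                max_nfev=self.max_nfev,
            )
        x0 = np.concatenate([a0, np.zeros(nb)])
        lo = np.concatenate([np.zeros(nb), -np.full(nb, self.center_bound_nm)])
        hi = np.concatenate([np.full(nb, np.inf), np.full(nb, self.center_bound_nm)])

        def fun(x):
            return self._basis(x[nb:]) @ x[:nb] - y

        return least_squares(
            fun,
            x0,
            bounds=(lo, hi),
            method="trf",
            xtol=self.tol,
            ftol=self.tol,
            gtol=self.tol,
            max_nfev=self.max_nfev,
        )

    def _standard_errors(self, B, chi2, npts, nb) -> pd.Series:
        dof = max(npts - nb, 1)
        s2 = chi2 / dof
        try:
            cov = s2 * np.linalg.inv(B.T @ B)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(nb, np.nan)
        return pd.Series(se, index=self._labels, name="bse")


def fit_spectrum(
    spectrum: WavenumberSpectrum | Spectrum,
    library: BandLibrary,
    **options,
) -> DecompositionResults:
    """Convenience wrapper: build a :class:`SpectralDecomposition` and fit.

    Accepts either a preprocessed :class:`WavenumberSpectrum` or a raw
    :class:`Spectrum` (standard preprocessing is applied to the latter).
    """
    if isinstance(spectrum, Spectrum):
        return SpectralDecomposition.from_spectrum(spectrum, library, **options).fit()
    return SpectralDecomposition(spectrum, library, **options).fit()
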