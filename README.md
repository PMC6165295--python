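# afdecon

Spectral decomposition of tissue and serum **autofluorescence (AF)** emission
spectra into endogenous-fluorophore bands, with the derived optical biomarkers
of cholestatic liver injury.

Under 366 nm excitation, serum and liver emit a broad 400–750 nm AF signal that
superimposes the emissions of albumin, bilirubin, porphyrins, NAD(P)H (free and
enzyme-bound), flavins, vitamin A, fatty acids and lipofuscin-like lipopigments.
`afdecon` separates these contributions by fitting each fluorophore with one or
more **half-Gaussian modified Gaussian (GMG)** bands — the convolution of a
Gaussian with a one-sided half-Gaussian, evaluated in wavenumber space
(ν = 10⁷/λ) where line broadening is closest to symmetric:

    f(ν) = (2/ω) φ((ν − ν_c)/ω) Φ(α (ν − ν_c)/ω),   ω² = σ_g² + σ_h²,  α = ±σ_h/σ_g

Each band has unit area, so a spectrum y(ν) is modelled as a non-negative
linear combination of fixed band shapes, y(ν) = Σ_b a_b f_b(ν), fitted by
bounded Levenberg–Marquardt-type least squares minimising the unweighted χ²,
with goodness of fit reported as residuals and r². From the fitted areas the
package derives the quantities used to track bile-duct-ligation (BDL)
cholestasis:

- **relative contributions** (% of the total fitted area over 400–750 nm),
- **bilirubin bichromophore metrics** — the (517–530 nm)/(570 nm) band-area
  ratio, the summed bilirubin contribution, and the absolute "real AF"
  emission rescaled by the measured spectrum area,
- **liver energy metrics** — NAD(P)H total, NAD(P)H free/bound ratio, and the
  **optical redox ratio** = flavins / (NAD(P)H bound + free + flavins),
- group statistics (mean ± SE, one-way ANOVA, Tukey HSD).

Because no raw spectra are publicly deposited for this model system, the
package ships a synthetic-cohort generator whose generating targets are the
published group tables (sham and 24/48/72 h BDL, n = 5), so every stage of the
pipeline is testable end to end.

Intended users: biophotonics / experimental-hepatology groups doing
fibre-optic AF spectroscopy who need a reproducible, scriptable alternative to
interactive peak-fitting software.

## Worked example

Compose a realistic noisy liver spectrum, decompose it, and derive the energy
metrics:

```python
import afdecon as af

lib = af.default_library("liver")
spectrum = af.generate_spectrum(
    lib,
    {"proteins": 3.74, "nadph_bound": 13.13, "nadph_free": 39.44,
     "flavins": 3.96, "vitamin_a": 21.18, "fatty_acids": 12.50,
     "lipopigments": 6.04},
    total_area=5000.0, noise_sigma=0.5, seed=42,
)
res = af.fit_spectrum(spectrum, lib, seed=0)
print(res.summary())

m = af.energy_metrics(res.contributions())
print(f"NAD(P)H total:      {m.nadph_total:.2f} %")
print(f"free/bound ratio:   {m.free_over_bound:.2f}")
print(f"optical redox ratio:{m.redox_ratio: .3f}")
```

Output:

```
Spectral decomposition (non-negative least squares, fixed GMG shapes)
  tissue: liver   n points: 351   n bands: 8
  chi2: 76.707   r2: 0.999705   converged: True   nfev: 15

  band                          area          SE   contrib %
  proteins                 1.131e+04         305        3.81
  nadph_bound              3.884e+04         750       13.10
  nadph_free               1.169e+05    1.55e+03       39.41
  fatty_acids              3.734e+04         594       12.59
  vitamin_a[0]             3.105e+04         495       10.47
  vitamin_a[1]             3.147e+04         383       10.61
  flavins                   1.17e+04         264        3.94
  lipopigments             1.795e+04         201        6.05

NAD(P)H total:      56.45 %
free/bound ratio:   3.01
optical redox ratio: 0.070
```

The fitted contributions recover the generating percentages to a few tenths of
a percentage point at this noise level (σ = 0.5 a.u. on the peak-100 scale);
a sham-like liver yields a free/bound ratio near 3.0 and a redox ratio near
0.070, while 72 h post-ligation profiles shift toward ≈4.0 and ≈0.10 — the
oxidised, mitochondria-impaired signature.

The same stages are available from the shell:

```sh
afdecon simulate --tissue liver --out cohort/ --seed 0
afdecon run --config config.json        # QC → fit → quantify → group report
afdecon fit --tissue serum --in sample.csv --out fit.json
```

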