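# Methods

## Spectral model

An emission spectrum acquired in the 400–750 nm window is treated as an
additive superposition of fluorophore bands plus noise. Band shapes are
half-Gaussian modified Gaussians (GMG): the convolution of a Gaussian of
width σ_g with a one-sided half-Gaussian of width σ_h, both in wavenumber
(cm⁻¹). The convolution has an exact skew-normal closed form,

    f(ν) = (2/ω) φ((ν − ν_c)/ω) Φ(s α (ν − ν_c)/ω),
    ω² = σ_g² + σ_h²,  α = σ_h/σ_g,  s = ±1,

which is what the package evaluates (a brute-force numerical convolution is
retained in the test suite as an independent oracle). `s = −1` ("red" skew)
skews the band toward longer wavelengths. Each shape integrates to one, so a
band's only free parameter during fitting is its **area**; this matches the
convention of reporting fluorophore contributions as fractions of total
spectral area.

Wavelength→wavenumber conversion is abscissa-only (I(ν) = I(λ), no Jacobian
rescaling), the standard convention of peak-fitting practice for emission
band shapes; the choice is recorded in fit provenance so a λ²-rescaled
variant could be added unambiguously later.

## Preprocessing

1. **Crop** to the 400–750 nm acquisition window.
2. **Peak-normalize** to 100 a.u. (shape-preserving; factor recorded). The
   raw integrated area is kept separately for absolute ("real AF")
   quantities.
3. **Convert** to wavenumber.
4. **QC** for deoxyhemoglobin reabsorption (below).

### Reabsorption QC

Deoxyhemoglobin reabsorption carves a dip into the 530–585 nm region, and
affected spectra must be discarded before fitting. A purely geometric
detector (smooth envelope or polynomial reference across the window) turned
out to be non-discriminative here: liver spectra contain a genuine
between-band valley in exactly that region (flavins at ~532 nm vs
lipopigments at ~595 nm), and a realistic reabsorption notch (σ ≈ 15 nm) is
nearly as wide as the window, so a local smooth reference either flags
healthy liver spectra or swallows the notch.

The detector therefore asks the model, not the geometry: the band library is
fitted to the lightly smoothed spectrum with the QC window **excluded** from
the objective (non-negative linear least squares), and the model is then
evaluated inside the window. The artifact score is the maximum 11-point
rolling mean of the relative dip of the data below that prediction. An
additive, non-negative band model cannot produce a multiplicative notch, so
smooth spectra score ≈ 0 while a 20 %-deep notch scores ≈ 0.17 regardless of
tissue. A spectrum passes iff score < threshold (default 0.05, strict). On
noisy spectra (σ = 0.5 a.u.) a few percent of artifact-free spectra can
exceed the threshold and be discarded — deliberate behaviour, mirroring the
acquisition practice of dropping ambiguous profiles rather than fitting
them.

## Fitting

The decomposition minimises the unweighted χ² between the composed model and
the preprocessed spectrum with all band areas bound at ≥ 0, using a
trust-region Levenberg–Marquardt-type solver (`scipy.optimize.least_squares`,
TRF; the classical LM variant cannot enforce bounds). Tolerances are 1e-10
(step, gradient and cost), max 2000 evaluations — the problem is cheap, so
the settings favour reproducibility. Initialisation splits the total
spectral area equally across bands; 5 multi-start restarts jitter the start
by ×U(0.5, 2) (seeded, default 0) and the lowest-χ² solution is kept. With
fixed shapes the problem is a convex bounded linear fit and every restart
converges to the same optimum; the restarts matter only in the optional
mode where band centers float within a ±5 nm bound. Centers and widths are
otherwise **fixed**: the library shapes are treated as known per-compound
parameters, which keeps the inverse problem well posed.

Results carry χ², r² (about the data mean), per-point residuals, asymptotic
standard errors from s²(JᵀJ)⁻¹, a convergence flag, and the option echo. A
fit with r² < 0.99 is flagged as poor.

## Band-library defaults

The packaged serum and liver libraries are literature-informed defaults, not
measured ground truth, and every parameter is user-configurable. Centers:
serum — albumin blue band 455 nm, bilirubin bichromophore bands 523 and
570 nm, two porphyrin red bands (635, 700 nm) reported as one group; liver —
proteins 426, NAD(P)H bound 444, NAD(P)H free 468, fatty acids 476,
vitamin A 484 + 514 (two vibronic sub-bands, one reported contribution),
flavins 532, lipopigments 595 nm. Widths are differentiated per band
(σ_g 450–1600, σ_h 500–1700 cm⁻¹, all red-skewed). Width differentiation is
essential: with one common width for all liver bands the 444–488 nm
neighbours become nearly collinear and per-spectrum contribution errors grow
to several percentage points; the shipped widths were chosen by a
conditioning analysis of the design matrix so that, at SNR ≈ 100, every
fluorophore's contribution is recoverable with sub-percentage-point error.

## Derived quantities

- Contribution of fluorophore F = 100 × (area of F's bands)/(total area);
  rows sum to 100 by construction.
- Bilirubin: band ratio c₅₂₃/c₅₇₀; total contribution c₅₂₃ + c₅₇₀; real AF =
  (total/100) × (measured raw spectral area)/100. The ratio is withheld when
  either band contributes < 0.5 % (unreliable at the near-zero levels of
  healthy serum).
- Energy metrics: NAD(P)H_total = bound + free + flavins; free/bound ratio;
  optical redox ratio = flavins/(bound + free + flavins). The flavin term is
  included in the total because only the full optical coenzyme pool
  reproduces the published summary values; the alternative literal reading
  (bound + free only) does not.
- percent_change(a, b) = 100 (b − a)/a.
- Group statistics: mean ± SE (sd/√n); one-way ANOVA; Tukey HSD
  (scipy implementations, cross-checked in tests against statsmodels).
  Where several measurements per organ exist, per-organ means are the
  statistical unit (n = animals).

## Synthetic cohorts

The generator emulates the four-group BDL design (sham, 24, 48, 72 h; n = 5
per group). Per-sample contributions are drawn from normals truncated at 0
around the published group means with sd = SE·√n, then renormalized onto the
100 % simplex (between-fluorophore independence is assumed — a simplifying
choice, as real covariances are unknown). Spectra are composed on a 1 nm
grid (400–750 nm; instrument resolution is not published, 1 nm is finer than
any band), peak-scaled to 100 a.u., perturbed with i.i.d. Gaussian noise
(default σ = 0.5 a.u., i.e. SNR ≈ 200 at the peak), clipped at zero and
rescaled to a per-sample total emission area (serum areas use the published
group values; liver areas are a nominal 5000 ± 250 a.u., as none are
published). Optional artifacts: a multiplicative Gaussian notch at 555 nm
(default depth 0.2, σ 15 nm). A piecewise-linear saturating response maps
bilirubin molar concentration to relative AF amplitude (zero at/below
1 × 10⁻⁶ M, saturated at/above 5 × 10⁻⁵ M, optional smoothed knee).

What passing on synthetic cohorts does **not** show: correctness of the
band-library shape parameters for real tissue (real spectra may contain
fluorophores or baseline structure outside the library, instrument response,
and wavelength-dependent noise, none of which are modelled), nor robustness
to between-fluorophore correlation. What it does show: the unmixing,
quantification, QC and statistics are internally correct and numerically
stable under the published group structure and realistic noise.

## Numerical choices and degenerate inputs

- Band profile maxima (for reporting peak wavelengths of skewed bands) are
  located by bounded scalar optimisation; no closed form exists.
- All-zero spectra, non-monotone grids, duplicated wavelengths, inverted
  crop windows, empty libraries, unknown config keys and zero-size groups
  are rejected with named errors rather than coerced.
- QC threshold comparison is strict (score exactly at threshold fails);
  the bilirubin detection floor is inclusive (response 0 at the floor).
- Reports round to 2 decimals (3 for the redox ratio).
- Pipeline outputs embed a SHA-256 hash of the analysis configuration
  (excluding the output directory), making reruns byte-identical.

## Problem sizes

Default test and acceptance workloads: 351-point spectra, 4 groups × 5
samples per cohort, 100-spectrum recovery simulations, 2000-replicate null
calibration of the ANOVA — sizes chosen to exercise every code path while
keeping the whole suite interactive-fast.

## Known limitations

- Shape parameters fixed during fitting; no per-sample center/width
  adaptation beyond the optional ±5 nm center bound, and no cross-cohort
  global fitting.
- No instrument-response, photobleaching or photon-transport modelling; the
  reabsorption artifact is a phenomenological notch.
- Absolute concentrations are out of scope; the bilirubin response curve is
  a forward-model convenience, not a calibration.
- The power analysis behind the n = 5 group size is not reproduced (its test
  family and effect-size metric are not identifiable); n = 5 is taken as
  given.
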