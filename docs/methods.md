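# Methods

## The measurement model

Partial-wave spectroscopic (PWS) microscopy records, at every pixel of a
bright-field image, a reflectance spectrum R(λ) over a visible band (by
default 200 wavelengths, 500–699 nm at 1 nm).  The specimen — a cell on a
substrate whose refractive index matches the cell's mean index n₀ — reflects
a reference wave from its mismatched front surface; light scattered by the
internal refractive-index fluctuations δn(z) interferes with that reference
and makes R(λ) oscillate.  Refractive index tracks macromolecular mass
density ρ through n = n_water + αρ with α = 0.18 ml/g, so the statistics of
δn are the statistics of density packing at sub-diffractional (20–200 nm)
length scales — in nuclei, chromatin compaction.

The per-pixel statistic is Σ, the standard deviation over wavelength of the
fluctuating part of R(λ).  For weakly scattering media with short-range
correlated fluctuations (SD σ_n, correlation length l_c, thickness L), the
ensemble spectral variance obeys the Born-regime scaling

    Σ² ∝ σ_n² · l_c · L · k̄²,      k̄ = 2π / λ̄ .

Disorder strength removes the thickness dependence:

* **variance convention** (default): L_d = c · Σ² / (k̄² L).  Dimensionally a
  length; when calibrated against the simulator, L_d estimates σ_n²·l_c.
* **linear convention**: L_d = c · Σ / L, mirroring the common verbal
  statement Σ ∝ σ·l_c·L.

Both are exposed; all validation names its convention.  The calibration
constant c defaults to 1 (arbitrary units).  Cohort statistics use effect
sizes, which are invariant under common affine rescaling of all L_d values,
so arbitrary units carry every group-level claim; `calibrate_ld` supplies a
physical constant when absolute numbers are wanted.

## Spectral processing

Per pixel: (1) zero-phase low-pass denoising along λ (6th-order Butterworth,
forward–backward, so the amplitude gain at the cutoff is |H|² = 1/2); (2)
least-squares polynomial baseline removal; (3) sample SD (ddof = 1) over λ.

* **Filter cutoff** defaults to 0.08 cycles/nm.  The interference signal of a
  1–4 µm cell sits at 2n₀L/λ² ≈ 0.01–0.04 cycles/nm, well inside the
  passband; white detector noise above the cutoff is suppressed.  The cutoff
  must lie below the Nyquist frequency of the λ grid, and the grid must be
  uniform within 1% (else the pipeline demands resampling rather than
  silently filtering a warped axis).
* **Baseline order** defaults to 1 for measured cubes (tolerates residual
  lamp/detector drift).  For simulated ensembles the summary uses order 0:
  the simulated background is a flat Fresnel constant, and any extra
  detrending needlessly absorbs signal (next paragraph).
* **Noise floor**: optionally a known noise variance is subtracted from Σ²
  (clamped at zero).  Off by default.

### Finite-band estimator bias

Estimating Σ² from a single spectrum over a finite band is biased low: the
199 nm band resolves optical path differences no finer than ~1/Δk ≈ 1.7 µm,
and the baseline/mean removal absorbs roughly one such resolution cell of
low-delay signal.  Because interference delays are spread uniformly over
[0, 2n₀L], the *absorbed amount* is roughly constant in L while the total
grows with L, so ratios of Σ² across thicknesses are biased away from the
ideal Σ² ∝ L (measured: L=4 µm vs 2 µm gives ≈2.2 rather than 2.0 with mean
removal, and ≈2.6 with linear detrending — hence the order-0 default for
ensemble summaries; the per-λ ensemble variance across realizations, which
is free of this bias, measures 2.09).  Calibration is immune: all grid
points share one thickness, so the bias folds into the constant.

## The 1D wave-optics oracle

`transfer_matrix_reflectance` implements the exact characteristic-matrix
solution for a stack of homogeneous layers at normal incidence between an
ambient half-space (default n = 1.0, the mismatched surface) and a substrate
(default matched to n₀ = 1.38).  It is exact, not perturbative: Born scaling
is an *outcome* we test, not an assumption.  Verified against the Airy
closed form to ~1e-14 relative and energy-conserving (R + T = 1 to 1e-10).
A 3D, NA-resolved vectorial treatment is deliberately out of scope; the 1D
scalar model at normal incidence matches the low-NA illumination geometry
(NAᵢ = 0.15) and suffices to arbitrate every scaling law used here.

Random media: δn(z) is a zero-mean stationary Gaussian process with Gaussian
autocorrelation σ_n² exp(−(τ/l_c)²) (1/e half-width l_c), generated by
circular convolution of white noise with a Gaussian kernel of width l_c/2 on
a grid of step dz ≤ min(l_c/4, 10 nm); the amplitude normalization is
analytic, so target statistics hold in the ensemble sense, not per
realization.  An exponential-ACF variant is not currently provided.

### Regime bounds and calibration grid

The Born spectral density of Gaussian-correlated disorder carries a factor
exp(−(n₀ k̄ l_c)²) at the backscattering wavevector: Σ² is linear in l_c only
while n₀ k̄ l_c ≪ 1, i.e. l_c ≲ 35 nm at λ̄ = 600 nm (at l_c = 50–80 nm the
factor departs by 25–50%).  The calibration grid therefore spans
σ_n ∈ {0.005, 0.01, 0.02} × l_c ∈ {16, 24, 32} nm at L = 2 µm, inside the
small-l_c regime, and `calibrate_ld` refuses (R² < 0.9) grids where the
through-origin model fails.  A weak-scattering advisory warns when
σ_n·k̄·L > 2.  Held-out parameter recovery on this grid measures within a
few percent (tolerance 15%, dominated by the ~5% seed-to-seed scatter of the
fitted constant at 100 realizations/point).

## Phantoms

2D phantoms place K non-touching elliptical nuclei (axis ratio 0.85–1.15,
radius 3–4.5 µm at 0.5 µm pixels) on a cytoplasm background.  Each pixel
gets an independent 1D medium drawn with its class parameters — nucleus
default (σ_n = 0.03, l_c = 40 nm, L = 1.5 µm), cytoplasm (σ_n = 0.015, same
l_c, L) — solved exactly, plus white reflectance noise (SD 5e-4, S/N ≈ 10
against a typical Σ of 5e-3).  The transmission image renders nuclei dark
(0.35 vs 0.8), blurred by a Gaussian PSF of σ = 0.5 px: the collection
optics (NA_c = 0.6, λ ≈ 600 nm) resolve ≈ λ/2NA = 0.5 µm FWHM, i.e.
σ ≈ 0.21 µm ≈ 0.4 px at 0.5 µm pixels.  Intensity noise SD 0.02.

What the phantoms do *not* emulate: intra-class texture (cytoplasmic
granularity, nucleoli), uneven illumination, overlapping or touching cells,
thickness gradients, absorption/staining dispersion, and spatial correlation
of disorder between neighbouring pixels.  Passing phantom tests therefore
demonstrates the correctness of the algorithms under the stated model, not
robustness to every artifact of clinical smears.

## Segmentation

Pipeline on transmission images: polarity normalization (dark nuclei by
default) → Kapur maximum-entropy threshold (256 bins; ties to the lowest
qualifying bin edge; foreground = feature ≥ threshold) → hole filling and
1-px morphological opening → watershed on the negated Euclidean distance
transform, seeded at maxima of the lightly smoothed (σ = 1 px) distance map
separated by ≥ 5 px → area gate 20–500 µm² → labels renumbered in raster
order of centroids.  The cleanup step between threshold and watershed is an
implementation addition (raw thresholded masks over-fragment); the distance
transform rather than image intensity seeds the watershed.  "Cellular" L_d
is averaged over the nucleus united with a perinuclear annulus (default
width 10 px), excluding other nuclei.

## Cohort statistics

The patient is the statistical unit.  Effect size is
|mean_A − mean_B| / SD, with SD the *combined-sample* SD (ddof = 1) by
default — the literal reading of the "cumulative SD" convention — and the
classical pooled within-group SD (Cohen's d) as the alternative, since the
cumulative convention is nonstandard.  Significance defaults to a two-sided
Welch t-test on patient means (cross-checked against a permutation test to
within 0.02 in p, and type-I calibrated at ~5% over 1000 null cohorts);
Mann–Whitney U is available for heavy-tailed cohorts.  Compartment coupling
is the Pearson correlation of nuclear vs cellular patient means.  Reports
render effect sizes as percentages (1.04 → "104").

## Problem sizes and determinism

Validation runs use: 160 realizations per σ_n point for Born linearity, 600
per thickness for the doubling ratio, 100 per calibration grid point (150
held-out), a 220×220 25-nucleus phantom, 1000 null cohorts for test
calibration, and 100 synthetic cohorts of 20 patients × 30 nuclei-equivalents
for end-to-end power — sizes chosen so that Monte-Carlo error is small
against each stated tolerance while a full run stays in the minutes range on
one core.  Every stochastic component accepts a seed (or SeedSequence) and
is bit-reproducible given it; all CLI runs write a manifest with config,
seed and library versions.

## Known limitations

* No thickness estimator: L(x, y) is user input (scalar or map); the
  variance-convention L_d is only as good as that thickness.
* The proportionality constant linking Σ to physical disorder is fixed only
  through the 1D simulator; absolute L_d values are not comparable with
  instruments calibrated otherwise.
* The linear convention (L_d = Σ/L) and the variance convention give the
  same rank orderings in-regime but different units; effect sizes computed
  under a fixed convention are comparable only within that convention.
* Kapur thresholding assumes a bimodal-ish histogram; on images whose
  foreground is absent it returns an empty mask with a warning.
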