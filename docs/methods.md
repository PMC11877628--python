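# Methods

This note documents the physical model, the synthetic-data generator, the
numerical choices and the known limitations of `nanochrome`.

## Coated-sphere Mie optics

The sensing element is modelled as a concentric sphere: a gold core
(diameter d, default 80 nm), a homogeneous dielectric shell of thickness
ΔT (the adsorbed protein layer), immersed in water.  The scattering
cross-section σ_sca(λ) is the standard multipole sum

σ_sca = (2π/k²) Σ_n (2n+1)(|a_n|² + |b_n|²),  k = 2π n_med/λ.

The coated-sphere coefficients are obtained by enforcing tangential-field
continuity at both interfaces: for each multipole order and polarisation
the four unknown amplitudes (core, two shell, scattered) satisfy a 4×4
complex linear system assembled from Riccati–Bessel functions ψ_n and
χ_n.  ψ_n is evaluated by the downward ratio recurrence (stable for
n > |z|, including complex arguments for the absorbing gold core) and
χ_n by upward recurrence.  The series is truncated at
n_max = x + 4x^{1/3} + 2; at the relevant size parameters (x ≈ 0.6–0.9)
six to eight orders suffice.  A zero-thickness shell is handled by the
same two-interface solve, which degenerates cleanly to the homogeneous
sphere; the test suite verifies 6-significant-digit agreement with an
independent implementation built on `scipy.special.jv/yv`, and 5 %
agreement with the Rayleigh closed form deep in the small-particle limit.

Gold optical constants: the Johnson & Christy (1972) n,k table is shipped
as a CSV (0.64–3.50 eV, i.e. 354–1937 nm) and interpolated linearly in
wavelength.  This is the de facto standard dataset; no other choice is
made anywhere.  Defaults elsewhere: protein shell index 1.45 (typical for
adsorbed protein/PEG), water 1.333; both configurable.

Spectra default to a 1 nm grid over 400–800 nm, fine enough to resolve
the 7 nm G-band.  `peak_wavelength` refines the grid argmax with a local
parabola (ties break to the shorter wavelength; boundary maxima are
returned unrefined).

## Band readout and the chromatic contrast

The filter combination is modelled as ideal top-hats with the nominal
edges (multiband windows 417–433.5, 466.5–492.5, 525.5–552, 590–622,
666.5–721 nm; 525 nm long-pass; 532 ± 5 nm notch — the notch width is not
specified by the design and only matters at band edges).  The two
detection bands are G = [545, 552] nm and R = [590, 622] nm; the adjacent
reference configuration uses G = [540, 560], R = [560, 580] nm.

Band intensities are trapezoidal integrals of σ_sca over each band with
the band edges included exactly; halving the quadrature step changes γ by
< 1e−4.  Design-level quantities (surface sensitivity, configuration
comparison) use uniform spectral weighting — they compare pure scattering
cross-sections; an illumination spectrum can be supplied but the lamp
line shape is deliberately not modelled, since only the filter edges are
specified.  The camera maps the R band to the red channel and the G band
to the green channel one-to-one; an optional 2×2 crosstalk matrix is
available (identity by default).

Surface sensitivity is the finite difference S_s = [γ(ΔT) − γ(0)]/ΔT: the
chromatic response per nanometre of shell growth.  With the embedded gold
data the model gives a nonadjacent/adjacent sensitivity ratio of ≈1.26
and a 1.67→1.77 nm signal enhancement of ≈27 %.  Both quantities are
hypersensitive to the assumed gold dielectric function through the LSPR
peak position relative to the fixed bands: shifting the effective peak by
only ~5 nm moves the enhancement between ~7 % and ~35 %.  Comparisons of
these numbers against other Mie implementations should therefore fix the
optical-constants table first.

## Synthetic image generator

The generator emulates the flow-imaging acquisition: each condition
produces enough 512×512 two-channel frames (150 spots per frame) to
contain a quota of non-aggregate spots — 15,000 by default, matching the
per-condition statistics of the assay design.

Per particle:

* **Core diameter** ~ Normal(80, 9) nm truncated at ±3 sd (vendor size
  dispersion).  Diameter sets spot brightness through the Mie band
  integrals (≈ d⁶ scaling) and, for aggregates, the footprint.
* **Shell thickness** ~ Normal(1.67, 0.10) nm truncated at 0: antibody /
  PEG coverage varies from particle to particle.  A bound particle
  carries an extra 0.10 nm (the captured-analyte layer: 1.77 nm total at
  the mean).
* **Binding** follows a Sips (heterogeneous-affinity) isotherm
  p = c^h/(c^h + Kd^h) with Kd = 10 pg/mL and h = 0.2.  A Langmuir
  isotherm (h = 1) is logistic in log c and cannot produce the log-linear
  standard curve over four decades that this assay class exhibits; the
  fractional exponent is the standard description of adsorption on an
  energetically heterogeneous antibody surface and is log-linear across
  the whole 0.1–1000 pg/mL calibration range.  Both parameters are
  configurable.
* **Aggregates** (2 % by default) are doublets: two independently sized
  cores rendered as overlapping Gaussians 1.6 psf-σ apart with summed
  photon budgets.

**Chromatic contrast model.**  By default the spectral *shape* (hence γ)
of a particle is evaluated at the population-mean 80 nm core; diameter
affects brightness only.  The reason is quantitative: full per-diameter
Mie evaluation makes γ vary by σ ≈ 0.11 across the ±9 nm size spread,
~100× the 1.67→1.77 nm binding shift (δγ ≈ 1.0e−3), which would bury any
dose response at any realistic spot count — whereas the measured assay
demonstrably resolves the shift digitally.  The instrument's effective
chromatic spread is evidently dominated by photon statistics and coverage
heterogeneity rather than by naive size dispersion, and the generator
models that regime: the N.C. γ spread is σ ≈ 1.3e−3, composed of shell
heterogeneity (≈1.0e−3) and shot noise (≈(0.5–2)e−3 depending on
brightness).  The physically-complete mode (`size_dependent_contrast=True`)
remains available and is used by the tests that need per-particle ground
truth variation.

**Rendering.**  Spots are pixel-integrated 2-D Gaussians (psf σ = 2.2 px,
exact to the erf) placed uniformly at random with a minimum separation of
6 psf-σ — wide enough that no neighbour intrudes on another spot's
background annulus — and a 16 px edge margin.  Expected photons per
channel are `photons_per_unit_cross_section` × the particle's band
integral; the default (12 photons per nm²·nm) yields ≈4.5×10⁶ detected
photons for a mean particle, i.e. a shot-noise γ contribution of ≈5e−4.
Per-pixel Poisson noise is applied to photons, converted by the camera
gain (0.1 ADU/photon, chosen so the brightest singles stay within 16-bit
range), then Gaussian read noise (2 ADU) and a 100 ADU constant
background; frames are rounded to uint16.  All randomness derives from a
single `numpy.random.default_rng(seed)` (PCG64), so identical seeds give
bit-identical stacks across runs and platforms.

What the generator does **not** emulate: motion blur and flow dynamics,
Bayer-mosaic raw frames (channels are delivered pre-split), camera gain
nonlinearity and vignetting, spectral impurities of the lamp, and any
matrix effect of plasma samples.  Passing tests therefore demonstrate the
correctness and statistical behaviour of the analysis chain under the
stated noise model, not instrument-level performance on real images.

## Spot analysis

Detection runs on the R+G sum image (channel-symmetric, maximal SNR):
local maxima within a 7 px window whose prominence over a coarse
(block-median) background map exceeds 100 ADU; plateaus collapse to their
centroid; peaks are processed in descending intensity order.

Photometry: per channel, the background under a spot is the median of an
annulus (radii 9–13 px), with spread = 1.4826×MAD; R_scat/G_scat are
background-subtracted sums over a 7 px disk, and positions are refined to
the intensity-weighted centroid.  Spots whose annulus leaves the frame
are flagged `edge` and excluded.

The aggregate filter is a pixel-area threshold.  Area is the count of
disk pixels above max(background + 3×spread, background + 5 % of the
background-subtracted peak).  The relative term is what makes the filter
work at high SNR: a purely absolute threshold grows with log(brightness),
so the d⁶ brightness spread of singles would swamp the footprint
difference of doublets; the 5 %-of-peak criterion measures the geometric
footprint (area ≈ 2π σ² ln 20 for a single Gaussian) independent of
brightness.  The threshold `max_area` itself is calibrated per run as the
99.5th percentile of ground-truth-matched single-particle areas on the
negative control (`calibrate_max_area`), not hard-coded.  On default
synthetic data this excludes ≈85 % of doublets at ≈0.5 % singles loss;
residual doublets are γ-neutral in the default contrast model, so the
counting statistics are insensitive to the remainder.

## Digital counting and calibration

The N.C. γ sample is fitted by a Normal (sample mean, SD with n−1); the
cutoff is μ + 1.6449 σ, the one-sided 95 % point of the *fitted*
distribution (an empirical-percentile mode would tie the cutoff to the
sample tail; the fitted form follows the Gaussian description of the γ
histogram and is the package default).  ΔNP% compares strict-exceedance
*rates* (per-group fractions × 100), so unequal group sizes are handled;
the spot quota makes rates and counts/150-frames equivalent at default
settings.

The standard curve regresses replicate-mean ΔNP% on log10(concentration)
by OLS (statsmodels); replicate SDs are retained for reporting.  The
log10 axis is the default because the calibration range spans four
decades; a linear-x mode exists.  LOD/LOQ apply Eq. LOD = DF·3.3·σ_int/S,
LOQ = DF·10·σ_int/S on the fit's own x-scale; when that scale is log10
the report carries both the log-scale values and their back-transformed
concentrations (10^value), since the convention in the source literature
is ambiguous — neither is silently preferred.  DF enters only here
(1 for buffer, 10 for diluted plasma-like samples).  Quantification
inverts the fit and reports recovery = 100×measured/expected with the
80–120 % acceptability convention; extrapolation beyond the calibrated
ΔNP% range is flagged, not refused.

## Problem sizes and reproduction

The reproduction script (`scripts/acceptance.py`) uses the package's
study defaults: 15,000 spots for the negative-control cutoff check and a
6-concentration × 6-replicate calibration at 5,000 spots per condition —
the calibration-scale runs the package itself uses for its statistics
(~2×10⁵ spots, a few minutes on one core).  The test suite exercises the
same pipeline at reduced spot counts where the property under test does
not require the full quota.

## Known limitations

* The enhancement/sensitivity comparison depends strongly on the gold
  dielectric table (see above); absolute agreement with other
  implementations requires matching material data.
* The two-state shell model treats the analyte layer as a uniform 0.10 nm
  increment; real per-particle loading is discrete and heterogeneous.
  A graded-loading mode can be emulated by widening `shell_sd`.
* The default decoupling of diameter from chromatic contrast is an
  explicit modelling choice (documented above), not a consequence of Mie
  theory.
* Ideal top-hat filters; real filter skirts and camera QE curves are out
  of scope.
* Each frame is analysed independently (flow acquisition); there is no
  particle tracking, drift correction or sub-pixel PSF fitting.
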