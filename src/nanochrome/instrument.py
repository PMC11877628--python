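"""Dual-band readout model: filter stack, band integrals, chromatic contrast.

The microscope illuminates with a metal-halide lamp through a filter
combination (multiband bandpass + 525 nm long-pass + 532 nm notch) whose net
transmission leaves two nonadjacent windows in the visible: a narrow G-band
(545-552 nm) just blue of the 80 nm particle's LSPR peak and a wide R-band
(590-622 nm) covering the long-wavelength half-maximum flank.  The color
camera records the two windows in its green and red channels.

Per particle, the readout is the spectral chromatic contrast

    gamma = (R_scat - G_scat) / (R_scat + G_scat)

where R_scat and G_scat are the band-integrated scattering intensities.
A thicker molecular shell red-shifts the LSPR, raising R_scat relative to
G_scat, so gamma increases monotonically with binding.  Design-level
quantities (surface sensitivity, band-configuration comparison) integrate
pure Mie cross-sections with uniform spectral weight; the lamp spectrum
enters only the image simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optics import OpticalConstants, ParticleModel, Spectrum, scattering_spectrum

__all__ = [
    "BandSet",
    "FilterStack",
    "BandIntensities",
    "SensitivityResult",
    "NONADJACENT_BANDS",
    "ADJACENT_BANDS",
    "DEFAULT_FILTER_STACK",
    "filter_transmission",
    "band_intensities",
    "gamma_contrast",
    "surface_sensitivity",
    "configuration_comparison",
]


@dataclass(frozen=True)
class BandSet:
    """The two detection windows, as (lo, hi) wavelength intervals in nm.

    The G-band must lie entirely below the R-band (nonoverlapping)."""

    g_band: tuple[float, float] = (545.0, 552.0)
    r_band: tuple[float, float] = (590.0, 622.0)

    def __post_init__(self):
        for lo, hi in (self.g_band, self.r_band):
            if not lo < hi:
                raise ValueError("band edges must satisfy lo < hi")
        if self.g_band[1] > self.r_band[0]:
            raise ValueError("G-band must not overlap the R-band")


#: Dual-segment nonadjacent configuration (multiband filter + color camera).
NONADJACENT_BANDS = BandSet((545.0, 552.0), (590.0, 622.0))
#: Adjacent configuration centred on the 560 nm LSPR peak (dual-view system).
ADJACENT_BANDS = BandSet((540.0, 560.0), (560.0, 580.0))


@dataclass(frozen=True)
class FilterStack:
    """Ideal top-hat model of the illumination/detection filter combination."""

    multiband_pass: tuple = (
        (417.0, 433.5),
        (466.5, 492.5),
        (525.5, 552.0),
        (590.0, 622.0),
        (666.5, 721.0),
    )
    longpass_cutoff: float = 525.0
    notch_center: float = 532.0
    notch_width: float = 10.0

    def __post_init__(self):
        prev_hi = -np.inf
        for lo, hi in self.multiband_pass:
            if not lo < hi or lo < prev_hi:
                raise ValueError("multiband intervals must be disjoint and ascending")
            prev_hi = hi


DEFAULT_FILTER_STACK = FilterStack()


@dataclass(frozen=True)
class BandIntensities:
    """Band-integrated scattering intensities (arbitrary linear units)."""

    r_scat: float
    g_scat: float

    def __post_init__(self):
        if self.r_scat < 0 or self.g_scat < 0:
            raise ValueError("band intensities must be non-negative")


@dataclass(frozen=True)
class SensitivityResult:
    """Surface sensitivity S_s: gamma change per nm of shell growth (1/nm)."""

    s_s: float
    band_set: BandSet
    delta_t: float


def filter_transmission(wavelength: float, stack: FilterStack = DEFAULT_FILTER_STACK) -> float:
    """Net transmission of the ideal filter combination at one wavelength:
    1 inside a multiband window, above the long-pass cutoff and outside the
    notch; otherwise 0."""
    wl = float(wavelength)
    if wl <= 0:
        raise ValueError("wavelength must be positive")
    if wl < stack.longpass_cutoff:
        return 0.0
    half = stack.notch_width / 2.0
    if stack.notch_center - half <= wl <= stack.notch_center + half:
        return 0.0
    for lo, hi in stack.multiband_pass:
        if lo <= wl <= hi:
            return 1.0
    return 0.0


def _band_integral(spectrum: Spectrum, lo: float, hi: float, weight: Spectrum | None) -> float:
    wl, v = spectrum.wavelengths, spectrum.values
    if lo < wl[0] or hi > wl[-1]:
        raise ValueError(
            f"band [{lo}, {hi}] nm outside spectrum support [{wl[0]}, {wl[-1]}] nm"
        )
    inner = wl[(wl > lo) & (wl < hi)]
    grid = np.concatenate([[lo], inner, [hi]])
    vals = np.interp(grid, wl, v)
    if weight is not None:
        vals = vals * np.interp(grid, weight.wavelengths, weight.values)
    return float(np.trapezoid(vals, grid))


def band_intensities(
    spectrum: Spectrum, bands: BandSet = NONADJACENT_BANDS, source_weight: Spectrum | None = None
) -> BandIntensities:
    """Integrate a scattering spectrum over the two bands (trapezoidal rule,
    band edges included exactly).  ``source_weight`` multiplies the spectrum
    by an illumination spectrum; the default (None) is uniform weight, the
    convention used for all design calculations."""
    r = _band_integral(spectrum, *bands.r_band, source_weight)
    g = _band_integral(spectrum, *bands.g_band, source_weight)
    return BandIntensities(r_scat=r, g_scat=g)


def gamma_contrast(intensities: BandIntensities) -> float:
    """Spectral chromatic contrast gamma = (R - G)/(R + G), in [-1, 1]."""
    r, g = intensities.r_scat, intensities.g_scat
    total = r + g
    if total <= 0:
        raise ValueError("undefined contrast: r_scat + g_scat must be > 0")
    return (r - g) / total


def apply_crosstalk(intensities: BandIntensities, matrix) -> BandIntensities:
    """Optional 2x2 camera channel crosstalk: rows map (R, G) -> (R', G')."""
    m = np.asarray(matrix, dtype=float)
    if m.shape != (2, 2):
        raise ValueError("crosstalk matrix must be 2x2")
    r, g = m @ np.array([intensities.r_scat, intensities.g_scat])
    return BandIntensities(r_scat=float(r), g_scat=float(g))


def _gamma_of_model(
    model: ParticleModel,
    shell: float,
    bands: BandSet,
    constants: OpticalConstants | None,
    step: float,
) -> float:
    from dataclasses import replace

    m = replace(model, shell_thickness=shell)
    lo = bands.g_band[0] - 2.0
    hi = bands.r_band[1] + 2.0
    grid = np.arange(lo, hi + step / 2, step)
    spec = scattering_spectrum(m, grid, constants)
    return gamma_contrast(band_intensities(spec, bands))


def surface_sensitivity(
    model: ParticleModel,
    bands: BandSet = NONADJACENT_BANDS,
    delta_t: float = 1.77,
    constants: OpticalConstants | None = None,
    step: float = 0.25,
) -> SensitivityResult:
    """Surface sensitivity S_s = [gamma(dT) - gamma(0)] / dT (per nm):
    the finite-difference chromatic response to growing a shell of
    ``delta_t`` nm on the bare core."""
    if delta_t <= 0:
        raise ValueError("delta_t must be > 0")
    g1 = _gamma_of_model(model, delta_t, bands, constants, step)
    g0 = _gamma_of_model(model, 0.0, bands, constants, step)
    return SensitivityResult(s_s=(g1 - g0) / delta_t, band_set=bands, delta_t=delta_t)


def configuration_comparison(
    model: ParticleModel,
    nonadjacent: BandSet = NONADJACENT_BANDS,
    adjacent: BandSet = ADJACENT_BANDS,
    t1: float = 1.67,
    t2: float = 1.77,
    constants: OpticalConstants | None = None,
    step: float = 0.25,
) -> dict:
    """Compare the two band configurations.

    Returns ``sensitivity_ratio`` = S_s(nonadjacent)/S_s(adjacent) at shell
    thickness ``t2``, and ``enhancement_percent`` = the percent excess of the
    nonadjacent gamma change over the adjacent one between shells ``t1`` and
    ``t2`` (the antibody/PEG layer vs that layer plus captured analyte).
    """
    if not 0 < t1 < t2:
        raise ValueError("require 0 < t1 < t2")
    ss_non = surface_sensitivity(model, nonadjacent, t2, constants, step).s_s
    ss_adj = surface_sensitivity(model, adjacent, t2, constants, step).s_s
    if ss_adj == 0:
        raise ZeroDivisionError(
            "adjacent configuration has zero surface sensitivity; ratio undefined"
        )
    g_non = {t: _gamma_of_model(model, t, nonadjacent, constants, step) for t in (t1, t2)}
    g_adj = {t: _gamma_of_model(model, t, adjacent, constants, step) for t in (t1, t2)}
    d_non = g_non[t2] - g_non[t1]
    d_adj = g_adj[t2] - g_adj[t1]
    if d_adj == 0:
        raise ZeroDivisionError("adjacent configuration shows no gamma change")
    return {
        "sensitivity_ratio": ss_non / ss_adj,
        "enhancement_percent": 100.0 * (d_non / d_adj - 1.0),
    }
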