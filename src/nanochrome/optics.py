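"""Coated-sphere Mie scattering for protein-coated gold nanoparticles.

The sensing element is an ~80 nm gold sphere carrying a thin dielectric
(protein) shell, immersed in water.  Its far-field observable is the
scattering cross-section spectrum sigma_sca(lambda); molecular binding
thickens the shell and red-shifts the localized surface plasmon resonance
(LSPR), which downstream modules read out as a two-band chromatic contrast.

The core/shell ("coated sphere") Mie series is evaluated by enforcing the
tangential-field continuity conditions at both interfaces as a small linear
system per multipole order, using Riccati-Bessel functions computed by
downward (psi) and upward (chi) recurrence.  Size parameters here are small
(x ~ 0.6 at 560 nm), so the series is short; it is truncated with the
standard Bohren-Huffman rule n_max = x + 4 x^(1/3) + 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "OpticalConstants",
    "ParticleModel",
    "Spectrum",
    "load_gold_constants",
    "gold_refractive_index",
    "coated_sphere_cross_section",
    "scattering_spectrum",
    "peak_wavelength",
]

_GOLD_FILE = "gold_johnson_christy_1972.csv"


class MieConvergenceError(RuntimeError):
    """Raised when the multipole series cannot be evaluated."""


@dataclass(frozen=True)
class OpticalConstants:
    """Tabulated complex refractive index of a material vs wavelength.

    wavelengths are in nanometers, strictly increasing, and must cover at
    least 400-800 nm; the imaginary part (absorption) is non-negative.
    """

    wavelengths: np.ndarray
    complex_index: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        m = np.asarray(self.complex_index, dtype=complex)
        if wl.ndim != 1 or wl.shape != m.shape:
            raise ValueError("wavelengths and complex_index must be 1-D and equal length")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(m.imag < 0):
            raise ValueError("imaginary part of the refractive index must be >= 0")
        if wl[0] > 400.0 or wl[-1] < 800.0:
            raise ValueError("optical constants must cover at least 400-800 nm")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "complex_index", m)


@dataclass(frozen=True)
class ParticleModel:
    """Concentric gold core + dielectric shell in a host medium.

    core_diameter and shell_thickness (the protein layer thickness, often
    written dT) are in nanometers; shell_index and medium_index are real
    refractive indices (default 1.45 for an adsorbed protein/PEG layer and
    1.333 for water).
    """

    core_diameter: float
    shell_thickness: float = 0.0
    shell_index: float = 1.45
    medium_index: float = 1.333

    def __post_init__(self):
        if self.core_diameter <= 0:
            raise ValueError("core_diameter must be > 0")
        if self.shell_thickness < 0:
            raise ValueError("shell_thickness must be >= 0")
        if self.shell_index < 1 or self.medium_index < 1:
            raise ValueError("refractive indices must be >= 1")


@dataclass(frozen=True)
class Spectrum:
    """A scattering cross-section spectrum: sigma_sca (nm^2) on an ascending
    wavelength grid (nm)."""

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if wl.shape != v.shape or wl.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if wl.size and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(v < -1e-12):
            raise ValueError("cross-sections must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", np.maximum(v, 0.0))

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.wavelengths, self.values])
        np.savetxt(path, arr, delimiter=",", header="wavelength_nm,sigma_sca_nm2", comments="")


def load_gold_constants() -> OpticalConstants:
    """Load the packaged Johnson & Christy (1972) gold n,k table."""
    ref = resources.files("nanochrome.data") / _GOLD_FILE
    raw = np.loadtxt(str(ref), delimiter=",", skiprows=1)
    return OpticalConstants(raw[:, 0], raw[:, 1] + 1j * raw[:, 2])


def gold_refractive_index(wavelength, constants: OpticalConstants | None = None):
    """Complex refractive index at ``wavelength`` (nm) by linear interpolation
    of the tabulated real and imaginary parts.

    Raises ValueError if the wavelength falls outside the tabulated range.
    Accepts scalars or arrays.
    """
    if constants is None:
        constants = load_gold_constants()
    wl = np.asarray(wavelength, dtype=float)
    tab = constants.wavelengths
    if np.any(wl < tab[0]) or np.any(wl > tab[-1]):
        raise ValueError(
            f"wavelength outside tabulated range [{tab[0]:.1f}, {tab[-1]:.1f}] nm"
        )
    m = np.interp(wl, tab, constants.complex_index.real) + 1j * np.interp(
        wl, tab, constants.complex_index.imag
    )
    return m if wl.ndim else complex(m)


# ----------------------------------------------------------------------------
# Riccati-Bessel machinery (vectorised over wavelength)

def _riccati_psi(nmax: int, z: np.ndarray):
    """psi_n(z) = z j_n(z) and derivative, n = 0..nmax, complex-safe.

    Uses the downward ratio recurrence r_n = psi_n/psi_{n-1} (stable for
    n > |z|) seeded well above nmax, then rebuilds from psi_0 = sin z.
    """
    z = np.atleast_1d(np.asarray(z, dtype=complex))
    nstart = nmax + 15
    r = np.empty((nstart + 1,) + z.shape, dtype=complex)
    r[nstart] = z / (2 * nstart + 1)
    for n in range(nstart - 1, 0, -1):
        r[n] = 1.0 / ((2 * n + 1) / z - r[n + 1])
    psi = np.empty((nmax + 1,) + z.shape, dtype=complex)
    psi[0] = np.sin(z)
    for n in range(1, nmax + 1):
        psi[n] = psi[n - 1] * r[n]
    dpsi = np.empty_like(psi)
    dpsi[0] = np.cos(z)
    for n in range(1, nmax + 1):
        dpsi[n] = psi[n - 1] - (n / z) * psi[n]
    return psi, dpsi


def _riccati_chi(nmax: int, z: np.ndarray):
    """chi_n(z) = -z y_n(z) and derivative; upward recurrence (stable)."""
    z = np.atleast_1d(np.asarray(z, dtype=complex))
    chi = np.empty((nmax + 1,) + z.shape, dtype=complex)
    chi[0] = np.cos(z)
    if nmax >= 1:
        chi[1] = np.cos(z) / z + np.sin(z)
    for n in range(1, nmax):
        chi[n + 1] = (2 * n + 1) / z * chi[n] - chi[n - 1]
    dchi = np.empty_like(chi)
    dchi[0] = -np.sin(z)
    for n in range(1, nmax + 1):
        dchi[n] = chi[n - 1] - (n / z) * chi[n]
    return chi, dchi


def _coated_coefficients(m1, m2, x, y, nmax):
    """Scattering coefficients a_n, b_n of a coated sphere.

    m1, m2: core and shell refractive indices relative to the medium
    (arrays over wavelength); x, y: core and outer size parameters.
    Tangential-field continuity at each interface is solved as a 4x4 linear
    system per order and polarisation (unknowns: core amplitude, the two
    shell amplitudes, and the scattering coefficient).
    """
    p1, dp1 = _riccati_psi(nmax, m1 * x)
    p2x, dp2x = _riccati_psi(nmax, m2 * x)
    c2x, dc2x = _riccati_chi(nmax, m2 * x)
    p2y, dp2y = _riccati_psi(nmax, m2 * y)
    c2y, dc2y = _riccati_chi(nmax, m2 * y)
    py, dpy = _riccati_psi(nmax, y)
    cy, dcy = _riccati_chi(nmax, y)
    xy, dxy = py - 1j * cy, dpy - 1j * dcy

    nwl = np.atleast_1d(x * (1 + 0j)).shape[0]
    zeros = np.zeros(nwl, dtype=complex)
    a = np.empty((nmax, nwl), dtype=complex)
    b = np.empty((nmax, nwl), dtype=complex)
    m1v = np.broadcast_to(np.atleast_1d(np.asarray(m1, dtype=complex)), (nwl,))
    m2v = np.broadcast_to(np.atleast_1d(np.asarray(m2, dtype=complex)), (nwl,))

    for n in range(1, nmax + 1):
        # TE (b_n): u and du/d(kr) continuous at both interfaces
        A = np.stack(
            [
                np.stack([p1[n], -p2x[n], -c2x[n], zeros], axis=-1),
                np.stack([m1v * dp1[n], -m2v * dp2x[n], -m2v * dc2x[n], zeros], axis=-1),
                np.stack([zeros, p2y[n], c2y[n], xy[n]], axis=-1),
                np.stack([zeros, m2v * dp2y[n], m2v * dc2y[n], dxy[n]], axis=-1),
            ],
            axis=-2,
        )
        rhs = np.stack([zeros, zeros, py[n], dpy[n]], axis=-1)
        b[n - 1] = np.linalg.solve(A, rhs[..., None])[..., 3, 0]
        # TM (a_n): u'/m and m*u continuous at both interfaces
        A = np.stack(
            [
                np.stack([dp1[n], -dp2x[n], -dc2x[n], zeros], axis=-1),
                np.stack([m1v * p1[n], -m2v * p2x[n], -m2v * c2x[n], zeros], axis=-1),
                np.stack([zeros, dp2y[n], dc2y[n], dxy[n]], axis=-1),
                np.stack([zeros, m2v * p2y[n], m2v * c2y[n], xy[n]], axis=-1),
            ],
            axis=-2,
        )
        rhs = np.stack([zeros, zeros, dpy[n], py[n]], axis=-1)
        a[n - 1] = np.linalg.solve(A, rhs[..., None])[..., 3, 0]
    return a, b


def _cross_section_array(model: ParticleModel, wavelengths, constants: OpticalConstants):
    wl = np.atleast_1d(np.asarray(wavelengths, dtype=float))
    m_core = np.atleast_1d(gold_refractive_index(wl, constants))
    n_med = model.medium_index
    k = 2.0 * np.pi * n_med / wl
    radius_core = model.core_diameter / 2.0
    radius_out = radius_core + model.shell_thickness
    x = k * radius_core
    y = k * radius_out
    m1 = m_core / n_med
    nmax = int(np.ceil(np.max(y) + 4.0 * np.max(y) ** (1.0 / 3.0) + 2.0))
    # a zero-thickness shell is handled by the same two-interface solve
    # (the shell layer degenerates cleanly), so one code path serves both
    m2 = np.full_like(m1, model.shell_index / n_med)
    a, b = _coated_coefficients(m1, m2, x, y, nmax)
    n = np.arange(1, nmax + 1)[:, None]
    sigma = (2.0 * np.pi / k**2) * np.sum(
        (2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2), axis=0
    )
    if not np.all(np.isfinite(sigma)):
        raise MieConvergenceError(
            f"Mie series did not evaluate to finite values (nmax={nmax}, "
            f"x={np.max(x):.3g}); check the particle model"
        )
    return sigma


def coated_sphere_cross_section(
    model: ParticleModel, wavelength: float, constants: OpticalConstants | None = None
) -> float:
    """Scattering cross-section (nm^2) of the core-shell particle at one
    wavelength (nm).  With shell_thickness 0 this reduces exactly to the
    homogeneous gold sphere."""
    if constants is None:
        constants = load_gold_constants()
    return float(_cross_section_array(model, wavelength, constants)[0])


def scattering_spectrum(
    model: ParticleModel, grid, constants: OpticalConstants | None = None
) -> Spectrum:
    """Evaluate the scattering cross-section on an ascending wavelength grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("wavelength grid must be non-empty")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("wavelength grid must be strictly increasing")
    if constants is None:
        constants = load_gold_constants()
    return Spectrum(grid, _cross_section_array(model, grid, constants))


def default_grid(lo: float = 400.0, hi: float = 800.0, step: float = 1.0) -> np.ndarray:
    return np.arange(lo, hi + step / 2, step)


def peak_wavelength(spectrum: Spectrum, refine: bool = True) -> float:
    """Wavelength of the global spectral maximum.

    Ties break toward the shorter wavelength.  With ``refine`` (default) a
    parabola through the maximum and its neighbours gives a sub-grid-step
    estimate; boundary maxima are returned unrefined.
    """
    if spectrum.wavelengths.size == 0:
        raise ValueError("empty spectrum")
    v = spectrum.values
    if np.all(v == 0):
        raise ValueError("degenerate all-zero spectrum has no peak")
    i = int(np.argmax(v))
    wl = spectrum.wavelengths
    if not refine or i == 0 or i == len(wl) - 1:
        return float(wl[i])
    y0, y1, y2 = v[i - 1], v[i], v[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(wl[i])
    delta = 0.5 * (y0 - y2) / denom
    # local grid may be non-uniform; use the mean neighbour spacing
    h = 0.5 * (wl[i + 1] - wl[i - 1])
    return float(wl[i] + np.clip(delta, -1, 1) * h)
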