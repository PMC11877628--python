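"""Independent reference implementations used only by the tests.

These deliberately avoid the package's Riccati-Bessel recurrences: the
homogeneous-sphere Mie oracle evaluates half-integer-order Bessel functions
through scipy.special.jv/yv directly, and the Rayleigh formula is a closed
form.  They provide dual-route checks of the package's coated-sphere code.
"""

import numpy as np
import scipy.special as sp


def _psi(n, z):
    return np.sqrt(np.pi * z / 2.0) * sp.jv(n + 0.5, z)


def _chi(n, z):
    return -np.sqrt(np.pi * z / 2.0) * sp.yv(n + 0.5, z)


def mie_homogeneous_cross_section(diameter, wavelength, m_particle, n_medium=1.333):
    """Scattering cross-section (nm^2) of a homogeneous sphere via the
    classic a_n/b_n coefficient formulas and scipy Bessel functions."""
    m = complex(m_particle) / n_medium
    k = 2.0 * np.pi * n_medium / wavelength
    x = k * diameter / 2.0
    nmax = int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))
    total = 0.0
    for n in range(1, nmax + 1):
        pmx, pmx1 = _psi(n, m * x), _psi(n - 1, m * x)
        px, px1 = _psi(n, x), _psi(n - 1, x)
        cx, cx1 = _chi(n, x), _chi(n - 1, x)
        xix, xix1 = px - 1j * cx, px1 - 1j * cx1
        dpmx = pmx1 - n / (m * x) * pmx
        dpx = px1 - n / x * px
        dxix = xix1 - n / x * xix
        a = (m * pmx * dpx - px * dpmx) / (m * pmx * dxix - xix * dpmx)
        b = (pmx * dpx - m * px * dpmx) / (pmx * dxix - m * xix * dpmx)
        total += (2 * n + 1) * (abs(a) ** 2 + abs(b) ** 2)
    return 2.0 * np.pi / k**2 * total


def rayleigh_cross_section(diameter, wavelength, m_particle, n_medium=1.333):
    """Rayleigh (electrostatic dipole) scattering cross-section in nm^2:
    sigma = (8 pi / 3) k^4 |alpha|^2 with alpha = a^3 (m^2-1)/(m^2+2)."""
    m = complex(m_particle) / n_medium
    k = 2.0 * np.pi * n_medium / wavelength
    a = diameter / 2.0
    alpha = a**3 * (m**2 - 1.0) / (m**2 + 2.0)
    return (8.0 * np.pi / 3.0) * k**4 * abs(alpha) ** 2
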