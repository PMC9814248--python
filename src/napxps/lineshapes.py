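"""Voigt line shapes for core-level photoemission peaks.

The true Voigt profile (Gaussian instrumental broadening convolved with the
Lorentzian lifetime width) is evaluated through the scaled complex error
function.  Widths are full widths at half maximum (FWHM) in eV throughout;
profiles are unit-area normalized before scaling by the requested area, so
``area`` is in counts*eV on a counts-vs-eV spectrum.
"""

from __future__ import annotations

import numpy as np
from scipy.special import voigt_profile as _scipy_voigt

__all__ = ["voigt_profile", "pseudo_voigt_profile", "voigt_fwhm", "DegenerateProfileError"]

_SQRT_8LN2 = np.sqrt(8.0 * np.log(2.0))


class DegenerateProfileError(ValueError):
    """Both widths zero: the profile degenerates to a delta function."""


def voigt_profile(
    x: np.ndarray,
    center: float,
    area: float,
    gaussian_width: float,
    lorentzian_width: float,
) -> np.ndarray:
    """True Voigt profile with unit-area normalization scaled by ``area``.

    ``gaussian_width`` and ``lorentzian_width`` are FWHM in eV; at least one
    must be positive.  Limiting cases reduce to the pure Gaussian /
    Lorentzian closed forms.
    """
    if gaussian_width < 0 or lorentzian_width < 0:
        raise ValueError("widths must be nonnegative")
    if gaussian_width == 0 and lorentzian_width == 0:
        raise DegenerateProfileError(
            "both Gaussian and Lorentzian FWHM are zero"
        )
    x = np.asarray(x, dtype=float)
    sigma = gaussian_width / _SQRT_8LN2
    gamma = lorentzian_width / 2.0
    return area * _scipy_voigt(x - center, sigma, gamma)


def pseudo_voigt_profile(
    x: np.ndarray,
    center: float,
    area: float,
    gaussian_width: float,
    lorentzian_width: float,
) -> np.ndarray:
    """Linear-combination pseudo-Voigt (config alternative to the true Voigt).

    Uses the standard single-width approximation: an effective FWHM and
    mixing parameter eta from the Thompson-Cox-Hastings expressions, then
    ``eta * Lorentzian + (1 - eta) * Gaussian``, each unit-area normalized.
    """
    if gaussian_width == 0 and lorentzian_width == 0:
        raise DegenerateProfileError("both widths are zero")
    x = np.asarray(x, dtype=float)
    fg, fl = gaussian_width, lorentzian_width
    f = (fg**5 + 2.69269 * fg**4 * fl + 2.42843 * fg**3 * fl**2
         + 4.47163 * fg**2 * fl**3 + 0.07842 * fg * fl**4 + fl**5) ** 0.2
    r = fl / f
    eta = 1.36603 * r - 0.47719 * r**2 + 0.11116 * r**3
    sigma = f / _SQRT_8LN2
    gauss = np.exp(-0.5 * ((x - center) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
    hwhm = f / 2.0
    lor = hwhm / (np.pi * ((x - center) ** 2 + hwhm**2))
    return area * (eta * lor + (1 - eta) * gauss)


def voigt_fwhm(gaussian_width: float, lorentzian_width: float) -> float:
    """Accurate (0.02 %) approximation to the Voigt FWHM (Olivero-Longbothum)."""
    fg, fl = gaussian_width, lorentzian_width
    return 0.5346 * fl + np.sqrt(0.2166 * fl**2 + fg**2)
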