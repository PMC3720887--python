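"""Closed-form optics for sinusoidal-grid structured illumination.

A sinusoidal grid of absolute spatial frequency ``nu`` (mm^-1 at the
sample plane), projected through an objective of numerical aperture NA
and imaged at emission wavelength ``lambda``, defocuses according to the
Stokseth approximation of the incoherent optical transfer function.  The
axial response of the grid contrast is

    I(u) = | 2 J1(a) / a |,      a = u * M,    M = nu_n * (1 - nu_n / 2)

with ``nu_n = nu * lambda / NA`` the normalized grid frequency,
``u = 4 k z sin^2(alpha / 2)`` the normalized defocus distance
(``k = 2 pi / lambda``, ``alpha = arcsin(NA)``) and ``z`` the real axial
distance.  The optical section thickness is the defocus at which I(u)
falls to 50 % of its focal-plane value; because the half-maximum
argument of ``2 J1(a)/a`` is a fixed constant (a0 = 2.2151), the
thickness scales as ``lambda / M`` and is minimized at ``nu_n = 1``.

The z-independent Stokseth polynomial ``1 - 0.69 nu_n + 0.0076 nu_n^2 +
0.043 nu_n^3`` gives the absolute (in-focus) modulation transfer of the
grid; it cancels in the peak-normalized axial profile and therefore does
not affect section thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import j1

__all__ = [
    "OpticalConfig",
    "GridFrequency",
    "AxialModel",
    "normalized_frequency",
    "absolute_frequency",
    "stokseth_axial_response",
    "stokseth_modulation_transfer",
    "predicted_section_thickness",
    "usaf_lp_per_mm",
    "usaf_resolution",
    "rayleigh_resolution",
]

#: One-sided defocus convention used throughout: u = 4 k z sin^2(alpha/2),
#: thickness = first z with response 0.5 (not a full width).
DEFOCUS_CONVENTION = "one-sided-u=4kz.sin2(alpha/2)"

#: Argument at which 2 J1(a)/a = 1/2 (first half-maximum of the jinc).
JINC_HALF_MAX_ARG = 2.215089367724233


@dataclass(frozen=True)
class OpticalConfig:
    """Objective and detection geometry.

    Parameters
    ----------
    na : numerical aperture, 0 < NA < 1.
    wavelength_em : emission wavelength in nm.
    magnification : objective magnification (metadata only).
    pixel_size : sample-plane pixel pitch in um/pixel.
    """

    na: float = 0.1
    wavelength_em: float = 520.0
    magnification: float = 4.0
    pixel_size: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 < self.na < 1.0:
            raise ValueError(f"NA must lie in (0, 1), got {self.na}")
        if self.wavelength_em <= 0:
            raise ValueError("wavelength_em must be positive (nm)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (um/pixel)")
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")

    @property
    def wavelength_mm(self) -> float:
        return self.wavelength_em * 1e-6

    @property
    def wavelength_um(self) -> float:
        return self.wavelength_em * 1e-3


def normalized_frequency(nu_abs: float, config: OpticalConfig) -> float:
    """Normalized grid frequency nu_n = nu * lambda / NA (dimensionless).

    ``nu_abs`` is the absolute grid frequency at the sample plane in
    mm^-1.  nu_n = 1 yields the thinnest optical section.
    """
    if nu_abs < 0:
        raise ValueError("grid frequency must be non-negative")
    return nu_abs * config.wavelength_mm / config.na


def absolute_frequency(nu_norm: float, config: OpticalConfig) -> float:
    """Inverse of :func:`normalized_frequency`; returns mm^-1."""
    if nu_norm < 0:
        raise ValueError("normalized frequency must be non-negative")
    return nu_norm * config.na / config.wavelength_mm


@dataclass(frozen=True)
class GridFrequency:
    """Absolute (mm^-1) and normalized grid frequency of the pattern."""

    nu_abs: float
    nu_norm: float

    def __post_init__(self) -> None:
        if self.nu_abs < 0:
            raise ValueError("nu_abs must be non-negative")
        if not 0.0 <= self.nu_norm < 2.0:
            raise ValueError(f"nu_norm must lie in [0, 2), got {self.nu_norm}")

    @classmethod
    def from_absolute(cls, nu_abs: float, config: OpticalConfig) -> "GridFrequency":
        return cls(nu_abs=nu_abs, nu_norm=normalized_frequency(nu_abs, config))

    @classmethod
    def from_normalized(cls, nu_norm: float, config: OpticalConfig) -> "GridFrequency":
        return cls(nu_abs=absolute_frequency(nu_norm, config), nu_norm=nu_norm)


def _grid_factor(nu_norm: float) -> float:
    """M = nu_n (1 - nu_n/2); maximal (1/2) at nu_n = 1."""
    return nu_norm * (1.0 - nu_norm / 2.0)


def _defocus_rate(config: OpticalConfig) -> float:
    """du/dz = 4 k sin^2(alpha/2) in um^-1, with alpha = arcsin(NA) exact."""
    alpha = np.arcsin(config.na)
    k = 2.0 * np.pi / config.wavelength_um
    return 4.0 * k * np.sin(alpha / 2.0) ** 2


@dataclass(frozen=True)
class AxialModel:
    """Stokseth axial response of a grid at fixed frequency and optics."""

    config: OpticalConfig
    frequency: GridFrequency
    convention: str = DEFOCUS_CONVENTION

    def __post_init__(self) -> None:
        if not 0.0 < self.frequency.nu_norm < 2.0:
            raise ValueError(
                "axial response requires 0 < nu_norm < 2 "
                f"(got {self.frequency.nu_norm}); an unmodulated grid has no "
                "sectioning profile"
            )

    def response(self, z):
        """Peak-normalized axial response |2 J1(a)/a| at defocus z (um)."""
        z = np.asarray(z, dtype=float)
        a = _defocus_rate(self.config) * _grid_factor(self.frequency.nu_norm) * np.abs(z)
        out = np.ones_like(a)
        nz = a > 1e-12
        out[nz] = np.abs(2.0 * j1(a[nz]) / a[nz])
        if out.ndim == 0:
            return float(out)
        return out


def stokseth_axial_response(z, model: AxialModel):
    """Axial sectioning response I(u) at real defocus ``z`` in um.

    Returns values in [0, 1], exactly 1 at z = 0, even in z.
    """
    return model.response(z)


def stokseth_modulation_transfer(nu_norm: float) -> float:
    """In-focus Stokseth OTF polynomial: absolute grid-contrast transfer.

    ``1 - 0.69 nu_n + 0.0076 nu_n^2 + 0.043 nu_n^3`` clipped to [0, 1];
    monotonically attenuates higher grid frequencies, reaching 0 at the
    incoherent cutoff nu_n = 2.
    """
    if not 0.0 <= nu_norm < 2.0:
        raise ValueError(f"nu_norm must lie in [0, 2), got {nu_norm}")
    p = 1.0 - 0.69 * nu_norm + 0.0076 * nu_norm**2 + 0.043 * nu_norm**3
    return float(np.clip(p, 0.0, 1.0))


def predicted_section_thickness(frequency: GridFrequency, config: OpticalConfig) -> float:
    """Optical section thickness (um) at the 50 % axial-response criterion.

    Locates the first defocus at which the Stokseth response drops to
    half its focal-plane value by bracketing (doubling) and Brent root
    refinement; equals ``a0 / (4 k sin^2(alpha/2) M)`` with a0 the jinc
    half-maximum argument.  Strictly decreasing in nu_norm on (0, 1].
    """
    if not 0.0 < frequency.nu_norm < 2.0:
        raise ValueError(
            f"section thickness requires 0 < nu_norm < 2, got {frequency.nu_norm}"
        )
    model = AxialModel(config=config, frequency=frequency)
    z_hi = 1.0
    while model.response(z_hi) > 0.5:
        z_hi *= 2.0
        if z_hi > 1e8:  # pragma: no cover - unreachable for valid nu_norm
            raise RuntimeError("failed to bracket the 50% crossing")
    z = brentq(lambda zz: model.response(zz) - 0.5, z_hi / 2.0, z_hi, xtol=1e-9)
    return float(z)


def usaf_lp_per_mm(group: int, element: int) -> float:
    """Spatial frequency (line pairs / mm) of a 1951 USAF target element."""
    if not 1 <= element <= 6:
        raise ValueError(f"USAF element must be in 1..6, got {element}")
    return float(2.0 ** (group + (element - 1) / 6.0))


def usaf_resolution(group: int, element: int) -> float:
    """One line-pair period (um) of a 1951 USAF target element."""
    return 1000.0 / usaf_lp_per_mm(group, element)


def rayleigh_resolution(config: OpticalConfig) -> float:
    """Rayleigh lateral resolution limit 0.61 lambda / NA, in um."""
    return 0.61 * config.wavelength_um / config.na
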