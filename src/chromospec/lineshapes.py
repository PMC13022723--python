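"""Skewed-Gaussian lineshape algebra shared by every fitting stage.

An electronic transition is modelled as a skew-normal band in wavenumber
space,

    A(nu) = A0 / (sqrt(2 pi) sigma) * exp(-(nu - nu0)^2 / (2 sigma^2))
            * {1 + erf[gamma (nu - nu0) / (sqrt(2) sigma)]},

which integrates to the band area ``A0`` for any skewness ``gamma`` and
reduces to a plain Gaussian at ``gamma = 0``.  Electroabsorption analysis
needs the "reduced" derivatives ``nu * d^k/dnu^k (A(nu)/nu)`` (k = 0, 1, 2);
these are computed analytically (chain rule through erf) so the nonlinear
fits see smooth gradients, with finite differences kept as a test oracle.

All model evaluation happens on a wavenumber (cm^-1) axis; nanometres are an
I/O convention mapped through the involution ``nu = 1e7 / lambda``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "SkewedGaussianBand",
    "Spectrum",
    "band_profile",
    "band_derivatives",
    "absorption_model",
    "reduced_derivative",
    "convert_axis",
    "nm_to_wavenumber",
    "wavenumber_to_nm",
    "default_grid",
]

AxisConvention = Literal["nm", "cm-1"]

_SQRT2PI = np.sqrt(2.0 * np.pi)
_SQRT2 = np.sqrt(2.0)


class InvalidParameterError(ValueError):
    """A lineshape or model parameter violates its physical constraint."""


@dataclass(frozen=True)
class SkewedGaussianBand:
    """One electronic transition's lineshape parameters.

    Parameters
    ----------
    area : float
        Integrated band intensity ``A0`` (absorbance x cm^-1).
    center : float
        Band position ``nu0`` in cm^-1.
    width : float
        Gaussian width parameter ``sigma`` in cm^-1 (must be positive).
    skewness : float
        Dimensionless asymmetry ``gamma``; 0 gives a symmetric Gaussian.
    """

    area: float
    center: float
    width: float
    skewness: float = 0.0

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise InvalidParameterError(f"band width must be > 0, got {self.width}")
        if not self.center > 0:
            raise InvalidParameterError(f"band center must be > 0, got {self.center}")

    @property
    def center_nm(self) -> float:
        return 1e7 / self.center


@dataclass
class Spectrum:
    """A sampled curve (optical density or field-induced dA) on a tagged axis."""

    axis: np.ndarray
    values: np.ndarray
    convention: AxisConvention = "cm-1"
    label: str = ""

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.axis.shape != self.values.shape or self.axis.ndim != 1:
            raise ValueError("axis and values must be 1-D arrays of equal length")
        if self.axis.size >= 2:
            d = np.diff(self.axis)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError("spectrum axis must be strictly monotone")
        if self.convention not in ("nm", "cm-1"):
            raise ValueError(f"unknown axis convention {self.convention!r}")

    def to_wavenumber(self) -> "Spectrum":
        return convert_axis(self, "cm-1")

    def to_nm(self) -> "Spectrum":
        return convert_axis(self, "nm")

    def ascending(self) -> "Spectrum":
        """Return a copy with the axis sorted ascending."""
        if self.axis.size >= 2 and self.axis[1] < self.axis[0]:
            return replace(self, axis=self.axis[::-1].copy(), values=self.values[::-1].copy())
        return self


def nm_to_wavenumber(axis_nm: np.ndarray) -> np.ndarray:
    axis_nm = np.asarray(axis_nm, dtype=float)
    if np.any(axis_nm <= 0):
        raise ValueError("wavelength axis must be strictly positive for nm <-> cm-1 conversion")
    return 1e7 / axis_nm


wavenumber_to_nm = nm_to_wavenumber  # the conversion is an involution


def convert_axis(spectrum: Spectrum, target: AxisConvention) -> Spectrum:
    """Map a spectrum between nm and cm^-1 axes; values are untouched."""
    if target not in ("nm", "cm-1"):
        raise ValueError(f"unknown axis convention {target!r}")
    if spectrum.convention == target:
        return replace(spectrum)
    return replace(spectrum, axis=nm_to_wavenumber(spectrum.axis), convention=target)


def _band_terms(band: SkewedGaussianBand, nu: np.ndarray):
    """Gaussian envelope g, erf factor E and their first two derivatives."""
    sigma = band.width
    gamma = band.skewness
    u = (nu - band.center) / sigma
    g = band.area / (_SQRT2PI * sigma) * np.exp(-0.5 * u * u)
    dg = -(u / sigma) * g
    d2g = (u * u - 1.0) / sigma**2 * g
    E = 1.0 + erf(gamma * u / _SQRT2)
    # dE/dnu = gamma/sigma * sqrt(2/pi) * exp(-gamma^2 u^2 / 2)
    ee = np.sqrt(2.0 / np.pi) * np.exp(-0.5 * gamma * gamma * u * u)
    dE = gamma / sigma * ee
    d2E = -(gamma**3) * u / sigma**2 * ee
    return g, dg, d2g, E, dE, d2E


def band_profile(band: SkewedGaussianBand, grid: np.ndarray) -> Spectrum:
    """Evaluate one skewed-Gaussian band on a wavenumber grid."""
    nu = np.asarray(grid, dtype=float)
    if nu.size == 0:
        return Spectrum(nu, np.empty(0), "cm-1", label="band")
    g, _, _, E, _, _ = _band_terms(band, nu)
    return Spectrum(nu, g * E, "cm-1", label="band")


def band_derivatives(band: SkewedGaussianBand, grid: np.ndarray):
    """Return (A, dA/dnu, d2A/dnu2) of one band, all analytic."""
    nu = np.asarray(grid, dtype=float)
    g, dg, d2g, E, dE, d2E = _band_terms(band, nu)
    A = g * E
    dA = dg * E + g * dE
    d2A = d2g * E + 2.0 * dg * dE + g * d2E
    return A, dA, d2A


def absorption_model(bands: Iterable[SkewedGaussianBand], grid: np.ndarray) -> Spectrum:
    """Pointwise sum of band profiles: the multi-band absorption model."""
    nu = np.asarray(grid, dtype=float)
    total = np.zeros_like(nu)
    for band in bands:
        total += band_profile(band, nu).values
    return Spectrum(nu, total, "cm-1", label="absorption model")


def _reduced_from_derivatives(nu, A, dA, d2A, order: int) -> np.ndarray:
    if order == 0:
        return A
    if order == 1:
        # nu * d/dnu (A/nu) = dA/dnu - A/nu
        return dA - A / nu
    if order == 2:
        # nu * d2/dnu2 (A/nu) = d2A/dnu2 - 2 dA/dnu / nu + 2 A / nu^2
        return d2A - 2.0 * dA / nu + 2.0 * A / nu**2
    raise ValueError(f"reduced-derivative order must be 0, 1 or 2, got {order}")


def reduced_derivative(
    source: Spectrum | SkewedGaussianBand | Sequence[SkewedGaussianBand],
    order: int,
    grid: np.ndarray | None = None,
) -> Spectrum:
    """The reduced derivative ``nu * d^k/dnu^k (A(nu)/nu)`` of a band or sum.

    For band inputs the derivatives are analytic; for a sampled ``Spectrum``
    (which must be on a wavenumber axis) central finite differences of
    ``A/nu`` are used.
    """
    if order not in (0, 1, 2):
        raise ValueError(f"reduced-derivative order must be 0, 1 or 2, got {order}")
    if isinstance(source, SkewedGaussianBand):
        source = [source]
    if isinstance(source, Spectrum):
        if source.convention != "cm-1":
            raise ValueError("reduced derivatives are defined on a wavenumber axis")
        nu = source.axis
        if order == 0:
            return replace(source, label=f"D0[{source.label}]")
        over_nu = source.values / nu
        d1 = np.gradient(over_nu, nu)
        if order == 1:
            return Spectrum(nu, nu * d1, "cm-1", label=f"D1[{source.label}]")
        d2 = np.gradient(d1, nu)
        return Spectrum(nu, nu * d2, "cm-1", label=f"D2[{source.label}]")
    nu = np.asarray(grid, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("wavenumber grid must be strictly positive")
    total = np.zeros_like(nu)
    for band in source:
        A, dA, d2A = band_derivatives(band, nu)
        total += _reduced_from_derivatives(nu, A, dA, d2A, order)
    return Spectrum(nu, total, "cm-1", label=f"D{order}")


def default_grid(lo_nm: float = 625.0, hi_nm: float = 770.0, spacing: float = 5.0) -> np.ndarray:
    """Uniform wavenumber grid over a wavelength window.

    5 cm^-1 spacing resolves the narrowest (~150 cm^-1) bands with >30
    points per sigma.
    """
    lo = 1e7 / hi_nm
    hi = 1e7 / lo_nm
    n = int(np.floor((hi - lo) / spacing)) + 1
    return lo + spacing * np.arange(n)
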