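"""Liptay analysis of electroabsorption (Stark) spectra.

The field-induced change in absorbance of an immobilized, isotropic sample
is expanded in the reduced derivatives of the absorption band,

    dA(nu) = (f F)^2 { A_chi A(nu) + B_chi nu d/dnu (A/nu)
                       + C_chi nu d^2/dnu^2 (A/nu) },

with F the applied field, f the (unknown) internal-field correction and
chi the angle between the light polarization and the field.  At the magic
angle chi = arccos(1/sqrt(3)) ~ 54.7 deg the transition-polarizability term
A_chi becomes negligible and the remaining weights carry the molecular
parameters:

    B = Tr(dAlpha) / (6 h c),        C = dMu^2 / (6 h^2 c^2),

i.e. the trace of the polarizability change and the magnitude of the
dipole-moment change between ground and excited state.  A large dMu flags
charge-transfer character of the transition.

Units: the model works in CGS — nu in cm^-1, F converted from the V/cm the
instrument reports to statvolt/cm, B in cm^2/erg, C in cm/erg — and the
molecular parameters are reported the way the field prints them, in
f-scaled units: Tr(dAlpha) in A^3 f^-2 and dMu in Debye f^-1 (the local
field factor is unknown, so f stays symbolic with default 1).

The central operation, :func:`fit_simultaneous`, fits the absorption
spectrum and the Stark spectrum jointly: band parameters are shared between
the two channels while each band additionally carries (Tr(dAlpha), dMu^2)
for the Stark response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy import constants
from scipy.optimize import least_squares

from .lineshapes import (
    SkewedGaussianBand,
    Spectrum,
    absorption_model,
    band_derivatives,
    reduced_derivative,
)

__all__ = [
    "FieldConditions",
    "StarkBandCoefficients",
    "MolecularStarkParams",
    "StarkFitResult",
    "magic_angle",
    "stark_model",
    "molecular_from_coefficients",
    "coefficients_from_molecular",
    "fit_absorption",
    "fit_simultaneous",
    "zero_crossings",
]

# CGS constants: erg s, cm/s; 1 statvolt = c * 1e-8 V = 299.792458 V.
H_CGS = constants.h * 1e7
C_CGS = constants.c * 1e2
HC_CGS = H_CGS * C_CGS  # erg cm
VOLT_PER_STATVOLT = constants.c * 1e-8 * 100.0  # 299.792458
CM3_PER_A3 = 1e-24
STATC_CM_PER_DEBYE = 1e-18


class NonPhysicalWarning(UserWarning):
    """Fitted Stark coefficients imply an impossible molecular parameter."""


def magic_angle() -> float:
    """The polarization/field angle (degrees) at which A_chi vanishes."""
    return float(np.degrees(np.arccos(1.0 / np.sqrt(3.0))))


@dataclass(frozen=True)
class FieldConditions:
    """Electric-field geometry of a Stark measurement.

    applied_field: external field F in V/cm (e.g. 2.2e5 V/cm).
    field_factor: internal (local) field correction f, dimensionless;
        defaults to 1 so outputs are in f-scaled units.
    angle_deg: angle chi between light polarization and field, degrees.
    """

    applied_field: float = 2.2e5
    field_factor: float = 1.0
    angle_deg: float = dc_field(default_factory=magic_angle)

    def __post_init__(self) -> None:
        if not self.applied_field > 0:
            raise ValueError("applied field must be positive")
        if not self.field_factor > 0:
            raise ValueError("internal field factor must be positive")
        if not 0.0 <= self.angle_deg <= 90.0:
            raise ValueError("polarization angle must lie in [0, 90] degrees")

    @property
    def at_magic_angle(self) -> bool:
        return abs(self.angle_deg - magic_angle()) < 0.5

    @property
    def field_cgs(self) -> float:
        """Effective local field f*F in statvolt/cm."""
        return self.field_factor * self.applied_field / VOLT_PER_STATVOLT


@dataclass(frozen=True)
class StarkBandCoefficients:
    """Per-band weights on the reduced derivatives (CGS working units).

    a_chi is dimensionless-per-field-squared bookkeeping for the
    transition-polarizability term; b_chi is in cm^2/erg, c_chi in cm/erg.
    At the magic angle a_chi is negligible and defaults to 0.
    """

    a_chi: float = 0.0
    b_chi: float = 0.0
    c_chi: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a_chi", "b_chi", "c_chi"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class MolecularStarkParams:
    """Molecular parameters extracted from magic-angle Stark coefficients.

    tr_dalpha: trace of the polarizability change, A^3 f^-2 (may be negative).
    dmu: dipole-moment change magnitude, D f^-1 (non-negative).
    physical: False when the fitted C coefficient was negative, in which
        case dmu is reported as 0.
    """

    tr_dalpha: float
    dmu: float
    physical: bool = True

    def __post_init__(self) -> None:
        if self.dmu < 0:
            raise ValueError("dmu is a magnitude and must be >= 0")


def molecular_from_coefficients(
    b_chi: float, c_chi: float, at_magic_angle: bool = True
) -> MolecularStarkParams:
    """Convert fitted (B, C) weights to Tr(dAlpha) [A^3 f^-2] and dMu [D f^-1].

    Valid only at the magic angle, where B = Tr(dAlpha)/(6hc) and
    C = dMu^2/(6 h^2 c^2).  A negative C is non-physical (dMu^2 < 0): it is
    reported as dmu = 0 with ``physical=False`` and a warning, rather than
    being clamped silently.
    """
    if not at_magic_angle:
        raise ValueError(
            "B/C -> molecular-parameter relations hold only at the magic angle"
        )
    tr_dalpha = 6.0 * HC_CGS * b_chi / CM3_PER_A3
    if c_chi < 0:
        warnings.warn(
            f"negative C coefficient ({c_chi:.3e}) implies dMu^2 < 0; "
            "reporting dMu = 0",
            NonPhysicalWarning,
            stacklevel=2,
        )
        return MolecularStarkParams(tr_dalpha=tr_dalpha, dmu=0.0, physical=False)
    dmu_cgs = HC_CGS * np.sqrt(6.0 * c_chi)
    return MolecularStarkParams(tr_dalpha=tr_dalpha, dmu=dmu_cgs / STATC_CM_PER_DEBYE)


def coefficients_from_molecular(params: MolecularStarkParams) -> tuple[float, float]:
    """Exact algebraic inverse of :func:`molecular_from_coefficients`."""
    b_chi = params.tr_dalpha * CM3_PER_A3 / (6.0 * HC_CGS)
    dmu_cgs = params.dmu * STATC_CM_PER_DEBYE
    c_chi = dmu_cgs**2 / (6.0 * HC_CGS**2)
    return b_chi, c_chi


def stark_model(
    bands: Sequence[SkewedGaussianBand],
    coefficients: Sequence[StarkBandCoefficients],
    field: FieldConditions,
    grid: np.ndarray,
) -> Spectrum:
    """Field-induced dA(nu) as the per-band derivative mixture."""
    if len(bands) != len(coefficients):
        raise ValueError(
            f"{len(bands)} bands but {len(coefficients)} coefficient sets"
        )
    nu = np.asarray(grid, dtype=float)
    pref = field.field_cgs**2
    total = np.zeros_like(nu)
    for band, coef in zip(bands, coefficients):
        A, dA, d2A = band_derivatives(band, nu)
        d0 = A
        d1 = dA - A / nu
        d2 = d2A - 2.0 * dA / nu + 2.0 * A / nu**2
        total += coef.a_chi * d0 + coef.b_chi * d1 + coef.c_chi * d2
    return Spectrum(nu, pref * total, "cm-1", label="stark model")


def zero_crossings(spectrum: Spectrum) -> np.ndarray:
    """Axis positions where the trace changes sign (linear interpolation)."""
    x = spectrum.axis
    y = spectrum.values
    s = np.sign(y)
    out = []
    # exact zeros count once; sign products < 0 bracket a crossing
    for i in np.nonzero(s[:-1] * s[1:] < 0)[0]:
        out.append(x[i] - y[i] * (x[i + 1] - x[i]) / (y[i + 1] - y[i]))
    out.extend(x[np.nonzero(y == 0.0)[0]])
    return np.sort(np.asarray(out, dtype=float))


# ---------------------------------------------------------------------------
# fitting

_BAND_FIELDS = ("area", "center", "width", "skewness")


def _default_band_bounds(grid: np.ndarray) -> dict:
    lo, hi = float(np.min(grid)), float(np.max(grid))
    margin = 0.05 * (hi - lo)
    return {
        "area": (0.0, np.inf),
        "center": (lo - margin, hi + margin),
        "width": (10.0, 2000.0),
        "skewness": (-5.0, 5.0),
    }


def _pack(values: list[float], fixed: list[bool]) -> np.ndarray:
    return np.asarray([v for v, f in zip(values, fixed) if not f], dtype=float)


def _unpack(x: np.ndarray, template: list[float], fixed: list[bool]) -> list[float]:
    out = list(template)
    it = iter(x)
    for i, f in enumerate(fixed):
        if not f:
            out[i] = next(it)
    return out


def _normalize_fixed_mask(mask, n_bands: int, defaults: dict) -> dict:
    norm = {k: list(v) for k, v in defaults.items()}
    if mask:
        for key, flags in mask.items():
            if key not in norm:
                raise ValueError(f"unknown fixed-mask key {key!r}")
            flags = list(np.broadcast_to(flags, (n_bands,)))
            norm[key] = [bool(f) for f in flags]
    return norm


@dataclass
class StarkFitResult:
    """Outcome of a simultaneous absorption + Stark fit.

    Bands are reported sorted by ascending center wavenumber, each paired
    with its derivative weights and the molecular parameters they imply.
    """

    bands: list[SkewedGaussianBand]
    coefficients: list[StarkBandCoefficients]
    molecular: list[MolecularStarkParams]
    field: FieldConditions
    absorption_residual_norm: float
    stark_residual_norm: float
    converged: bool
    absorption_model: Spectrum | None = None
    stark_model: Spectrum | None = None

    def band_near(self, nm: float) -> int:
        """Index of the band whose center is closest to a wavelength in nm."""
        centers = np.array([1e7 / b.center for b in self.bands])
        return int(np.argmin(np.abs(centers - nm)))


def fit_absorption(
    spectrum: Spectrum,
    init: Sequence[SkewedGaussianBand],
    bounds: dict | None = None,
    fixed_mask: dict | None = None,
) -> tuple[list[SkewedGaussianBand], bool]:
    """Least-squares multi-band fit of an absorption spectrum.

    ``fixed_mask`` maps band-parameter names ('area', 'center', 'width',
    'skewness') to per-band booleans; skewness is fixed by default.
    Returns the fitted bands (sorted by center) and a convergence flag.
    """
    if len(init) < 1:
        raise ValueError("at least one initial band is required")
    spec = spectrum.to_wavenumber().ascending()
    n = len(init)
    mask = _normalize_fixed_mask(
        fixed_mask, n, {k: [k == "skewness"] * n for k in _BAND_FIELDS}
    )
    b = bounds or _default_band_bounds(spec.axis)

    template, fixed, lo, hi = [], [], [], []
    for i, band in enumerate(init):
        for key in _BAND_FIELDS:
            template.append(getattr(band, key))
            fixed.append(mask[key][i])
            if not mask[key][i]:
                lo.append(b[key][0])
                hi.append(b[key][1])

    def to_bands(x):
        vals = _unpack(x, template, fixed)
        return [
            SkewedGaussianBand(*vals[4 * i : 4 * i + 4]) for i in range(n)
        ]

    def resid(x):
        return absorption_model(to_bands(x), spec.axis).values - spec.values

    x0 = _pack(template, fixed)
    sol = least_squares(
        resid, x0, bounds=(np.asarray(lo), np.asarray(hi)), method="trf",
        x_scale="jac", xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    bands = sorted(to_bands(sol.x), key=lambda bb: bb.center)
    return bands, bool(sol.success)


def fit_simultaneous(
    absorption: Spectrum,
    stark: Spectrum,
    field: FieldConditions,
    init: Sequence[SkewedGaussianBand],
    init_molecular: Sequence[MolecularStarkParams] | None = None,
    weights: tuple[float, float] = (1.0, 1.0),
    fixed_mask: dict | None = None,
    bounds: dict | None = None,
    free_a_chi: bool = False,
    point_weights: str = "uniform",
) -> StarkFitResult:
    """Joint Liptay fit of one absorption and one Stark spectrum.

    Band parameters (area, center, width, skewness) are shared between both
    channels; each band additionally carries (Tr(dAlpha), dMu^2), which are
    linear in the Stark channel.  Each channel's residual is normalized by
    its peak absolute value, then scaled by the user weights (absorption,
    stark); with the Stark weight at 0 the fit degenerates to
    :func:`fit_absorption`.

    At the magic angle A_chi is fixed at 0 (``free_a_chi`` releases it for
    diagnostics).  A negative fitted dMu^2 is reported as a non-physical
    band (dmu = 0, warning), not clamped during optimization.

    ``point_weights`` selects the per-point weighting within each channel:
    "uniform" (default) or "proportional" — inverse of |data| with a floor
    at 5% of the channel peak, the inverse-variance weighting appropriate
    when the noise is multiplicative.  Uniform weighting carries a small
    noise-squared bias on weak overlapped bands under multiplicative noise;
    proportional weighting removes most of it.
    """
    abs_spec = absorption.to_wavenumber().ascending()
    stark_spec = stark.to_wavenumber().ascending()
    if abs_spec.axis.size != stark_spec.axis.size or not np.allclose(
        abs_spec.axis, stark_spec.axis
    ):
        raise ValueError("absorption and Stark spectra must share one window/grid")
    if not field.at_magic_angle:
        raise ValueError(
            "simultaneous fitting supports the magic-angle configuration only"
        )

    grid = abs_spec.axis
    n = len(init)
    if init_molecular is None:
        init_molecular = [MolecularStarkParams(0.0, 0.0)] * n
    if len(init_molecular) != n:
        raise ValueError("one molecular-parameter init per band required")

    mask_defaults = {k: [k == "skewness"] * n for k in _BAND_FIELDS}
    mask_defaults["tr_dalpha"] = [False] * n
    mask_defaults["dmu2"] = [False] * n
    mask_defaults["a_chi"] = [not free_a_chi] * n
    mask = _normalize_fixed_mask(fixed_mask, n, mask_defaults)
    b = dict(_default_band_bounds(grid))
    b.update({
        "tr_dalpha": (-1e5, 1e5),
        "dmu2": (-1e3, 1e3),
        "a_chi": (-1e3, 1e3),
    })
    if bounds:
        b.update(bounds)

    keys = list(_BAND_FIELDS) + ["tr_dalpha", "dmu2", "a_chi"]
    template, fixed, lo, hi = [], [], [], []
    for i in range(n):
        start = {
            "area": init[i].area,
            "center": init[i].center,
            "width": init[i].width,
            "skewness": init[i].skewness,
            "tr_dalpha": init_molecular[i].tr_dalpha,
            "dmu2": init_molecular[i].dmu ** 2,
            "a_chi": 0.0,
        }
        for key in keys:
            template.append(start[key])
            fixed.append(mask[key][i])
            if not mask[key][i]:
                lo.append(b[key][0])
                hi.append(b[key][1])

    stride = len(keys)
    w_abs, w_stark = weights
    abs_scale = max(np.max(np.abs(abs_spec.values)), 1e-30)
    stark_scale = max(np.max(np.abs(stark_spec.values)), 1e-30)
    if point_weights == "uniform":
        pw_abs = np.full(grid.size, 1.0 / abs_scale)
        pw_stark = np.full(grid.size, 1.0 / stark_scale)
    elif point_weights == "proportional":
        pw_abs = 1.0 / np.maximum(np.abs(abs_spec.values), 0.05 * abs_scale)
        pw_stark = 1.0 / np.maximum(np.abs(stark_spec.values), 0.05 * stark_scale)
        # keep the two channels on comparable footing after reweighting
        pw_abs /= pw_abs.mean() * abs_scale
        pw_stark /= pw_stark.mean() * stark_scale
    else:
        raise ValueError(f"unknown point_weights mode {point_weights!r}")

    def split(x):
        vals = _unpack(x, template, fixed)
        bands, coefs = [], []
        for i in range(n):
            v = vals[stride * i : stride * (i + 1)]
            bands.append(SkewedGaussianBand(v[0], v[1], v[2], v[3]))
            # B, C linear in (TrdAlpha, dMu^2); sign of dmu2 passes through to C
            b_chi = v[4] * CM3_PER_A3 / (6.0 * HC_CGS)
            c_chi = v[5] * STATC_CM_PER_DEBYE**2 / (6.0 * HC_CGS**2)
            coefs.append(StarkBandCoefficients(v[6], b_chi, c_chi))
        return bands, coefs

    def resid(x):
        bands, coefs = split(x)
        r_abs = pw_abs * (absorption_model(bands, grid).values - abs_spec.values)
        r_stark = pw_stark * (
            stark_model(bands, coefs, field, grid).values - stark_spec.values
        )
        return np.concatenate([w_abs * r_abs, w_stark * r_stark])

    x0 = _pack(template, fixed)
    sol = least_squares(
        resid, x0, bounds=(np.asarray(lo), np.asarray(hi)), method="trf",
        x_scale="jac", xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=4000,
    )

    bands, coefs = split(sol.x)
    order = np.argsort([bb.center for bb in bands])
    bands = [bands[i] for i in order]
    coefs = [coefs[i] for i in order]
    molecular = [
        molecular_from_coefficients(c.b_chi, c.c_chi, at_magic_angle=True)
        for c in coefs
    ]
    abs_fit = absorption_model(bands, grid)
    stark_fit = stark_model(bands, coefs, field, grid)
    return StarkFitResult(
        bands=bands,
        coefficients=coefs,
        molecular=molecular,
        field=field,
        absorption_residual_norm=float(
            np.linalg.norm(abs_fit.values - abs_spec.values)
        ),
        stark_residual_norm=float(
            np.linalg.norm(stark_fit.values - stark_spec.values)
        ),
        converged=bool(sol.success),
        absorption_model=abs_fit,
        stark_model=stark_fit,
    )
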