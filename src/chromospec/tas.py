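"""Global analysis of broadband transient-absorption (TAS) matrices.

A pump-probe experiment delivers a matrix dA(t, lambda).  After two
pre-processing steps — subtraction of the mean pre-time-zero spectrum
(static scatter) and correction of the probe chirp (wavelength-dependent
time zero) — the matrix is fitted globally: every probe wavelength shares
one set of exponential time components convolved with a Gaussian
instrument response function (IRF).

Two equivalent parametrizations of the linear spectra are produced:

* EADS (evolution-associated difference spectra): species spectra under an
  unbranched, unidirectional sequential chain 1 -> 2 -> ... -> n;
* DADS (decay-associated difference spectra): amplitudes of independent
  parallel decays.

The two are related by an exact triangular change of basis, so they
reconstruct the identical model matrix.  The fit itself uses variable
projection: the nonlinear parameters (free lifetimes in log space, time
zero, IRF width) are optimized while the spectra are the conditionally
optimal linear coefficients at each step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erfc, erfcx

__all__ = [
    "TASDataset",
    "IRFModel",
    "KineticScheme",
    "GlobalFitResult",
    "convolved_exponential",
    "concentrations",
    "sequential_mixing_matrix",
    "dads_from_eads",
    "eads_from_dads",
    "prezero_subtract",
    "chirp_correct",
    "global_fit",
    "amplitude_fraction",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class DegenerateRatesError(ValueError):
    """Equal lifetimes make the sequential chain algebra singular."""


@dataclass
class TASDataset:
    """Delay x wavelength dA matrix with its axes.

    delays in ps (may be negative before time zero), wavelengths in nm,
    both strictly ascending.  Missing samples (e.g. pushed out of range by
    chirp correction) are NaN.
    """

    delays: np.ndarray
    wavelengths: np.ndarray
    deltaA: np.ndarray

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.deltaA = np.asarray(self.deltaA, dtype=float)
        for name, ax in (("delays", self.delays), ("wavelengths", self.wavelengths)):
            if ax.ndim != 1 or (ax.size >= 2 and not np.all(np.diff(ax) > 0)):
                raise ValueError(f"{name} axis must be 1-D and strictly ascending")
        if self.deltaA.shape != (self.delays.size, self.wavelengths.size):
            raise ValueError(
                f"deltaA shape {self.deltaA.shape} does not match axes "
                f"({self.delays.size}, {self.wavelengths.size})"
            )


@dataclass(frozen=True)
class IRFModel:
    """Gaussian instrument response: center t0 (ps), fwhm (ps), and an
    optional chirp polynomial t0(lambda) = t0 + sum_k c_k (lambda - lambda_ref)^k
    (k >= 1, cubic by default)."""

    t0: float = 0.0
    fwhm: float = 0.06
    chirp_coeffs: tuple[float, ...] = ()
    lambda_ref: float = 700.0

    def __post_init__(self) -> None:
        if not self.fwhm >= 0:
            raise ValueError("IRF fwhm must be >= 0")

    @property
    def sigma(self) -> float:
        return self.fwhm * _FWHM_TO_SIGMA

    def t0_at(self, wavelengths: np.ndarray) -> np.ndarray:
        lam = np.asarray(wavelengths, dtype=float) - self.lambda_ref
        shift = np.zeros_like(lam)
        for k, c in enumerate(self.chirp_coeffs, start=1):
            shift += c * lam**k
        if not np.all(np.isfinite(shift)):
            raise ValueError("chirp polynomial diverges over the spectral window")
        return self.t0 + shift


@dataclass(frozen=True)
class KineticScheme:
    """Sequential or parallel compartment model with lifetimes in ps.

    Lifetimes are strictly ascending; ``fixed`` marks components held at
    their value during fitting (e.g. a nanosecond component pinned to the
    fluorescence lifetime from TCSPC).
    """

    kind: Literal["sequential", "parallel"]
    lifetimes: tuple[float, ...]
    fixed: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("sequential", "parallel"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        taus = np.asarray(self.lifetimes, dtype=float)
        if taus.size == 0 or np.any(taus <= 0):
            raise ValueError("lifetimes must be positive")
        if np.any(np.diff(taus) <= 0):
            raise ValueError("lifetimes must be strictly ascending")
        if self.fixed and len(self.fixed) != taus.size:
            raise ValueError("fixed flags must match the number of lifetimes")
        if not self.fixed:
            object.__setattr__(self, "fixed", (False,) * taus.size)

    @property
    def rates(self) -> np.ndarray:
        return 1.0 / np.asarray(self.lifetimes, dtype=float)


def convolved_exponential(
    t: np.ndarray, rate: float, t0: float = 0.0, fwhm: float = 0.0
) -> np.ndarray:
    """Exponential decay convolved with a normalized Gaussian IRF.

    Analytic form (s = fwhm / (2 sqrt(2 ln 2))):

        c(t) = 1/2 exp(-k (t-t0) + k^2 s^2 / 2)
               * erfc(-((t-t0) - k s^2) / (s sqrt 2)),

    evaluated via the scaled complement erfcx for numerical stability at
    large k s.  fwhm = 0 degenerates to the step-function exponential.
    """
    if rate < 0 or fwhm < 0:
        raise ValueError("rate and fwhm must be non-negative")
    dt = np.atleast_1d(np.asarray(t, dtype=float)) - t0
    if fwhm == 0.0:
        return np.where(dt >= 0, np.exp(-rate * np.where(dt >= 0, dt, 0.0)), 0.0)
    s = fwhm * _FWHM_TO_SIGMA
    x = (rate * s * s - dt) / (s * np.sqrt(2.0))
    # 1/2 erfc(x) e^{k^2 s^2/2 - k dt} == 1/2 erfcx(x) e^{-dt^2/(2 s^2)};
    # the erfcx form is stable for x >= 0 (late decay of fast components),
    # the plain form for x < 0 where erfc(x) ~ 2 and the exponent is tame.
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 0.5 * erfcx(x[pos]) * np.exp(-dt[pos] ** 2 / (2.0 * s * s))
    neg = ~pos
    out[neg] = (
        0.5
        * erfc(x[neg])
        * np.exp(rate * (0.5 * rate * s * s - dt[neg]))
    )
    return out


def sequential_mixing_matrix(rates: np.ndarray) -> np.ndarray:
    """Upper-triangular B with c_seq = E @ B for the unbranched chain.

    Column l gives compartment l's amplitudes on the convolved exponentials
    E_j (Bateman coefficients): B[j, l] = prod_{m<l} k_m / prod_{m<=l, m!=j}
    (k_m - k_j), with B[0, 0] = 1 for the unit-injected first compartment.
    """
    k = np.asarray(rates, dtype=float)
    n = k.size
    if np.unique(k).size != n:
        raise DegenerateRatesError(
            "sequential chain requires distinct lifetimes; perturb the "
            "degenerate components"
        )
    B = np.zeros((n, n))
    for l in range(n):
        flux = np.prod(k[:l])  # product of the l transfer rates feeding l
        for j in range(l + 1):
            denom = np.prod([k[m] - k[j] for m in range(l + 1) if m != j])
            B[j, l] = flux / denom if l > 0 else 1.0
    return B


def concentrations(
    scheme: KineticScheme, irf: IRFModel, delays: np.ndarray
) -> np.ndarray:
    """Compartment populations on the delay grid (delays x components).

    Parallel: column j is the convolved exponential with rate k_j (equal
    unit excitation of every compartment).  Sequential: unit injection into
    compartment 1 and 100% transfer efficiency down the chain, expressed on
    the convolved-exponential basis through the Bateman coefficients.
    """
    t = np.asarray(delays, dtype=float)
    k = scheme.rates
    E = np.column_stack(
        [convolved_exponential(t, kj, irf.t0, irf.fwhm) for kj in k]
    )
    if scheme.kind == "parallel":
        return E
    return E @ sequential_mixing_matrix(k)


def dads_from_eads(eads: np.ndarray, scheme: KineticScheme) -> np.ndarray:
    """Map sequential-model spectra to the parallel-decay amplitudes.

    Defined by matrix equality of the reconstructions:
    C_seq @ EADS = E @ (B @ EADS) = C_par @ DADS, so DADS = B @ EADS.
    """
    if scheme.kind != "sequential":
        raise ValueError("EADS are defined for a sequential scheme")
    B = sequential_mixing_matrix(scheme.rates)
    return B @ np.asarray(eads, dtype=float)


def eads_from_dads(dads: np.ndarray, scheme: KineticScheme) -> np.ndarray:
    """Inverse of :func:`dads_from_eads` (triangular solve)."""
    if scheme.kind != "sequential":
        raise ValueError("EADS are defined for a sequential scheme")
    B = sequential_mixing_matrix(scheme.rates)
    return np.linalg.solve(B, np.asarray(dads, dtype=float))


def prezero_subtract(
    data: TASDataset, window: tuple[float, float], irf: IRFModel | None = None
) -> TASDataset:
    """Subtract the mean spectrum over a pre-time-zero delay window.

    Removes static scatter / baseline offsets.  The window must contain at
    least one delay safely before the IRF rise (t0 - 3 fwhm when an IRF is
    given).
    """
    lo, hi = window
    sel = (data.delays >= lo) & (data.delays <= hi)
    if irf is not None:
        sel &= data.delays < irf.t0 - 3.0 * irf.fwhm
    if not np.any(sel):
        raise ValueError("pre-zero window selects no usable delays")
    baseline = np.nanmean(data.deltaA[sel], axis=0)
    return replace(data, deltaA=data.deltaA - baseline[None, :])


def chirp_correct(data: TASDataset, irf: IRFModel) -> TASDataset:
    """Undo the wavelength dependence of time zero.

    Each wavelength's time trace is resampled at t + (t0(lambda) - t0), so
    that after correction every trace rises at the common t0.  Samples
    shifted outside the recorded delay span become NaN and are excluded
    from subsequent fits.
    """
    shifts = irf.t0_at(data.wavelengths) - irf.t0
    span = data.delays[-1] - data.delays[0]
    if np.any(np.abs(shifts) >= span):
        raise ValueError("chirp shift exceeds the delay span")
    out = np.empty_like(data.deltaA)
    t = data.delays
    for j, dt_j in enumerate(shifts):
        out[:, j] = np.interp(
            t + dt_j, t, data.deltaA[:, j], left=np.nan, right=np.nan
        )
    return replace(data, deltaA=out)


@dataclass
class GlobalFitResult:
    """Fitted scheme + IRF with both spectral representations.

    ``eads`` and ``dads`` are (components x wavelengths) and reconstruct
    the identical model matrix; for a parallel fit the EADS are taken equal
    to the DADS of the single-basis model.
    """

    scheme: KineticScheme
    irf: IRFModel
    eads: np.ndarray
    dads: np.ndarray
    residual: np.ndarray
    converged: bool
    rms: float = 0.0
    wavelengths: np.ndarray | None = None
    delays: np.ndarray | None = None

    def model_matrix(self, delays: np.ndarray) -> np.ndarray:
        return concentrations(self.scheme, self.irf, delays) @ (
            self.eads if self.scheme.kind == "sequential" else self.dads
        )


def global_fit(
    data: TASDataset,
    scheme_init: KineticScheme,
    irf_init: IRFModel,
    fit_irf: bool = True,
    max_nfev: int = 2000,
) -> GlobalFitResult:
    """Variable-projection global fit of a TAS matrix.

    Free lifetimes are optimized in log space (positivity by construction);
    fixed lifetimes are honored exactly.  At each step the species spectra
    are the conditionally optimal linear coefficients of the concentration
    matrix (ordinary least squares per wavelength, NaN-masked).  t0 and the
    IRF width are co-fitted unless ``fit_irf`` is False.  Reported
    lifetimes are sorted ascending, with the fixed flags following them.
    """
    n_comp = len(scheme_init.lifetimes)
    if data.delays.size < n_comp + 2:
        raise ValueError("need at least n_components + 2 delays")
    taus = np.asarray(scheme_init.lifetimes, dtype=float)
    fixed = np.asarray(scheme_init.fixed, dtype=bool)
    free_idx = np.nonzero(~fixed)[0]

    D = data.deltaA
    nan_mask = ~np.isfinite(D)
    has_nan = bool(np.any(nan_mask))
    Dz = np.where(nan_mask, 0.0, D)

    def build(x):
        taus_all = taus.copy()
        taus_all[free_idx] = np.exp(x[: free_idx.size])
        if fit_irf:
            t0, fwhm = x[free_idx.size], abs(x[free_idx.size + 1])
        else:
            t0, fwhm = irf_init.t0, irf_init.fwhm
        order = np.argsort(taus_all)
        scheme = KineticScheme(
            scheme_init.kind,
            tuple(taus_all[order]),
            tuple(fixed[order]),
        )
        irf = replace(irf_init, t0=t0, fwhm=fwhm)
        return scheme, irf

    def spectra_and_residual(scheme, irf):
        C = concentrations(scheme, irf, data.delays)
        if not has_nan:
            S, *_ = np.linalg.lstsq(C, D, rcond=None)
            R = D - C @ S
        else:
            nl = data.wavelengths.size
            S = np.empty((C.shape[1], nl))
            for j in range(nl):
                ok = ~nan_mask[:, j]
                S[:, j], *_ = np.linalg.lstsq(C[ok], Dz[ok, j], rcond=None)
            R = np.where(nan_mask, 0.0, D - C @ S)
        return C, S, R

    def resid(x):
        scheme, irf = build(x)
        _, _, R = spectra_and_residual(scheme, irf)
        return R.ravel()

    x0 = list(np.log(taus[free_idx]))
    if fit_irf:
        x0 += [irf_init.t0, irf_init.fwhm]
    if x0:
        sol = least_squares(
            resid, np.asarray(x0), method="trf", x_scale="jac",
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=max_nfev,
        )
        scheme, irf = build(sol.x)
        converged = bool(sol.success)
    else:  # everything fixed: pure linear problem
        scheme, irf = scheme_init, irf_init
        converged = True
    _, S, R = spectra_and_residual(scheme, irf)

    if scheme.kind == "sequential":
        eads = S
        dads = dads_from_eads(S, scheme)
    else:
        dads = S
        eads = S.copy()
    n_used = int(np.sum(~nan_mask))
    return GlobalFitResult(
        scheme=scheme,
        irf=irf,
        eads=eads,
        dads=dads,
        residual=np.where(nan_mask, np.nan, R),
        converged=converged,
        rms=float(np.sqrt(np.sum(R**2) / max(n_used, 1))),
        wavelengths=data.wavelengths.copy(),
        delays=data.delays.copy(),
    )


def amplitude_fraction(
    result: GlobalFitResult, component: int, band_window: tuple[float, float]
) -> float:
    """Percent of the total decay amplitude carried by one component.

    100 * integral |DADS_i| over the window / sum_j integral |DADS_j|,
    integrated over wavelength within ``band_window`` (nm).
    """
    if result.wavelengths is None:
        raise ValueError("fit result carries no wavelength axis")
    lam = np.asarray(result.wavelengths, dtype=float)
    lo, hi = band_window
    sel = (lam >= lo) & (lam <= hi)
    if not np.any(sel):
        raise ValueError("band window selects no wavelengths")
    x = lam[sel]
    integrals = np.array(
        [np.trapezoid(np.abs(row[sel]), x) for row in result.dads]
    )
    return float(100.0 * integrals[component] / integrals.sum())
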