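"""Synthetic datasets with the statistical structure the fitters assume.

Every input the pipeline consumes can be generated here: absorption +
electroabsorption spectrum pairs from a band-parameter table, broadband
transient-absorption matrices from a compartment scheme and species
spectra, and Poisson TCSPC histograms.  The presets encode the study
conditions of the zinc-porphyrin / four-helix-bundle complexes this
package was written around:

* ``2H2A`` — monomeric chromophore, four Qy-region bands (main band at
  669 nm, two vibronic satellites, a weak red impurity band);
* ``4E4K``/``4L4A`` — excitonically coupled dimers, five bands including
  the low/high exciton pair at 685/667 nm with strongly enhanced
  dipole-moment changes (exciton-CT mixing);
* ``monomer``/``dimer`` TAS presets — three components (1.77 ps, 130 ps,
  3.7 ns fixed) and four components (1.2, 14, 151 ps, 3.7 ns fixed)
  respectively, with ground-state bleach at 676/681 nm, a stimulated
  emission wing in the 715-760 nm region, and (dimer only) a broad
  photoinduced absorption rising beyond 710 nm with the 151 ps component;
* TCSPC preset — 3.7 ns mono-exponential decay through a 75 ps IRF with
  5000 counts in the peak channel.

Band widths/areas in the tables are Gaussian sigma in cm^-1 and integrated
intensity in absorbance x cm^-1; skewness is 0 throughout (the bands are
treated as symmetric).  Noise models: multiplicative Gaussian on spectra
(default 1%), additive Gaussian on TAS matrices (default 1% of the signal
maximum, i.e. SNR 100), Poisson on TCSPC counts.  The same seed always
reproduces bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .lineshapes import SkewedGaussianBand, Spectrum, absorption_model, default_grid
from .stark import (
    FieldConditions,
    MolecularStarkParams,
    StarkBandCoefficients,
    coefficients_from_molecular,
    stark_model,
)
from .tas import IRFModel, KineticScheme, TASDataset, concentrations
from .tcspc import DecayHistogram, reconvolution_model

__all__ = [
    "GeneratorSpec",
    "BandTableRow",
    "STARK_PRESETS",
    "TAS_PRESETS",
    "TCSPC_PRESET",
    "gen_stark_dataset",
    "gen_tas_dataset",
    "gen_tas_preset",
    "gen_tcspc",
    "default_delay_grid",
    "default_wavelength_grid",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Reproducibility + noise contract for one synthetic dataset.

    ``noise_level`` is the relative 1-sigma noise: multiplicative per-point
    for spectra, additive as a fraction of the signal maximum for TAS
    matrices (so SNR 100 is noise_level 0.01).  TCSPC noise is inherently
    Poisson and ignores this field.  noise_level 0 disables noise.
    """

    seed: int = 0
    noise_level: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_level < 0:
            raise ValueError("noise level must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class BandTableRow:
    """One row of a Stark band-parameter table.

    center_nm in nm; area and width (sigma) in the absorption model's
    working units (absorbance x cm^-1 and cm^-1); tr_dalpha in A^3 f^-2;
    dmu in D f^-1; gamma (skewness) and a_chi default to 0.
    """

    center_nm: float
    area: float
    width: float
    tr_dalpha: float
    dmu: float
    gamma: float = 0.0
    a_chi: float = 0.0

    def band(self) -> SkewedGaussianBand:
        return SkewedGaussianBand(
            area=self.area, center=1e7 / self.center_nm,
            width=self.width, skewness=self.gamma,
        )

    def molecular(self) -> MolecularStarkParams:
        return MolecularStarkParams(tr_dalpha=self.tr_dalpha, dmu=self.dmu)

    def coefficients(self) -> StarkBandCoefficients:
        b, c = coefficients_from_molecular(self.molecular())
        return StarkBandCoefficients(a_chi=self.a_chi, b_chi=b, c_chi=c)


# Fitted band tables of the three complexes (center nm, area, sigma cm^-1,
# Tr(dAlpha) A^3 f^-2, dMu D f^-1).
STARK_PRESETS: dict[str, tuple[BandTableRow, ...]] = {
    "2H2A": (
        BandTableRow(697.0, 25.0, 200.0, -57.5, 0.55),
        BandTableRow(669.0, 291.9, 149.9, 10.5, 0.64),
        BandTableRow(653.0, 98.4, 200.0, 14.3, 0.26),
        BandTableRow(635.0, 88.4, 300.0, 21.8, 1.22),
    ),
    "4E4K": (
        BandTableRow(708.0, 22.0, 363.2, 126.9, 1.04),
        BandTableRow(685.0, 32.0, 217.5, 117.7, 1.79),
        BandTableRow(667.0, 291.2, 231.2, 15.0, 1.17),
        BandTableRow(650.0, 54.9, 199.9, -9.4, 0.37),
        BandTableRow(636.0, 151.9, 350.0, -9.8, 1.1),
    ),
    "4L4A": (
        BandTableRow(708.0, 11.2, 382.1, 105.5, 0.99),
        BandTableRow(685.0, 25.7, 218.5, 94.1, 1.66),
        BandTableRow(667.0, 158.4, 231.2, 12.0, 1.18),
        BandTableRow(650.0, 28.8, 193.7, -9.7, 0.46),
        BandTableRow(636.0, 84.0, 350.0, -8.0, 1.09),
    ),
}


def gen_stark_dataset(
    band_table: Sequence[BandTableRow],
    field: FieldConditions | None = None,
    spec: GeneratorSpec = GeneratorSpec(),
    grid: np.ndarray | None = None,
) -> tuple[Spectrum, Spectrum]:
    """Absorption + Stark spectrum pair from a band-parameter table.

    The Stark channel is the Liptay derivative mixture with coefficients
    implied by each row's (Tr(dAlpha), dMu) at the given field (default
    2.2e5 V/cm, f = 1, magic angle).  Optional multiplicative Gaussian
    noise of ``spec.noise_level`` is applied independently per channel.
    """
    if len(band_table) == 0:
        raise ValueError("band table must contain at least one row")
    field = field or FieldConditions()
    nu = default_grid() if grid is None else np.asarray(grid, dtype=float)
    bands = [row.band() for row in band_table]
    coefs = [row.coefficients() for row in band_table]
    absorption = absorption_model(bands, nu)
    stark = stark_model(bands, coefs, field, nu)
    absorption.label = "synthetic absorption"
    stark.label = "synthetic stark"
    if spec.noise_level > 0:
        rng = spec.rng()
        absorption.values = absorption.values * (
            1.0 + spec.noise_level * rng.standard_normal(nu.size)
        )
        stark.values = stark.values * (
            1.0 + spec.noise_level * rng.standard_normal(nu.size)
        )
    return absorption, stark


# ---------------------------------------------------------------------------
# transient absorption


def default_wavelength_grid() -> np.ndarray:
    """Probe window 620-780 nm at 2 nm steps."""
    return np.arange(620.0, 780.0 + 1.0, 2.0)


def default_delay_grid() -> np.ndarray:
    """Pre-zero block, dense rise, then log-spaced out to 1 ns (ps)."""
    pre = np.arange(-1.0, -0.175, 0.1)
    rise = np.arange(-0.15, 1.0, 0.025)
    tail = np.geomspace(1.0, 1000.0, 60)
    return np.concatenate([pre, rise, tail])


def _gauss_nm(lam: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - center) / width) ** 2)


def _monomer_species(lam: np.ndarray) -> np.ndarray:
    """Parallel-basis (DADS) spectra of the monomer preset.

    Three spectrally similar species: ground-state bleach at 676 nm plus a
    stimulated-emission wing around 737 nm; the fastest component carries
    10% of the main-band amplitude and a relatively stronger SE wing.
    """
    gsb = -_gauss_nm(lam, 676.0, 9.0)
    se = -_gauss_nm(lam, 737.0, 18.0)
    d1 = 0.10 * gsb + 0.060 * se
    d2 = 0.45 * gsb + 0.140 * se
    d3 = 0.45 * gsb + 0.165 * se
    return 0.01 * np.vstack([d1, d2, d3])


def _dimer_species(lam: np.ndarray) -> np.ndarray:
    """Sequential-basis (EADS) spectra of the dimer preset.

    Main bleach red-shifted to 681 nm, evolving blueward; the third
    (151 ps) compartment carries a broad positive photoinduced absorption
    from ~712 nm to the red detection limit; the last compartment is the
    small monomer-like nanosecond fraction.
    """
    def eads(center, amp_gsb, amp_se, amp_pia=0.0):
        out = amp_gsb * -_gauss_nm(lam, center, 10.0)
        out += amp_se * -_gauss_nm(lam, 735.0, 20.0)
        if amp_pia:
            out += amp_pia * _gauss_nm(lam, 745.0, 28.0) * (lam > 700.0)
        return out

    e1 = eads(681.0, 1.00, 0.40)
    e2 = eads(682.0, 0.80, 0.30)
    e3 = eads(679.0, 0.55, 0.06, amp_pia=0.12)
    e4 = eads(677.0, 0.12, 0.045)
    return 0.01 * np.vstack([e1, e2, e3, e4])


TAS_PRESETS: dict[str, dict] = {
    "monomer": {
        "scheme": KineticScheme(
            "parallel", (1.77, 130.0, 3700.0), (False, False, True)
        ),
        "species": _monomer_species,
    },
    "dimer": {
        "scheme": KineticScheme(
            "sequential", (1.2, 14.0, 151.0, 3700.0), (False, False, False, True)
        ),
        "species": _dimer_species,
    },
}


def gen_tas_dataset(
    scheme: KineticScheme,
    species_spectra: np.ndarray,
    irf: IRFModel,
    spec: GeneratorSpec = GeneratorSpec(),
    delays: np.ndarray | None = None,
    wavelengths: np.ndarray | None = None,
) -> TASDataset:
    """TAS matrix = compartment concentrations x species spectra (+ chirp,
    + additive noise).

    ``species_spectra`` is (components x wavelengths) in the basis the
    scheme defines (EADS for sequential, DADS for parallel).  A chirp
    polynomial on the IRF displaces each wavelength's time zero during
    generation.  Additive Gaussian noise has sigma = noise_level x
    max |dA|.
    """
    t = default_delay_grid() if delays is None else np.asarray(delays, dtype=float)
    lam = (
        default_wavelength_grid()
        if wavelengths is None
        else np.asarray(wavelengths, dtype=float)
    )
    S = np.asarray(species_spectra, dtype=float)
    if S.shape != (len(scheme.lifetimes), lam.size):
        raise ValueError(
            f"species spectra shape {S.shape} does not match "
            f"({len(scheme.lifetimes)}, {lam.size})"
        )
    if irf.chirp_coeffs:
        t0s = irf.t0_at(lam)
        dA = np.empty((t.size, lam.size))
        for j in range(lam.size):
            irf_j = IRFModel(t0=float(t0s[j]), fwhm=irf.fwhm)
            dA[:, j] = concentrations(scheme, irf_j, t) @ S[:, j]
    else:
        dA = concentrations(scheme, irf, t) @ S
    if spec.noise_level > 0:
        sigma = spec.noise_level * np.max(np.abs(dA))
        dA = dA + sigma * spec.rng().standard_normal(dA.shape)
    return TASDataset(delays=t, wavelengths=lam, deltaA=dA)


def gen_tas_preset(
    name: str,
    irf: IRFModel | None = None,
    spec: GeneratorSpec = GeneratorSpec(noise_level=0.01),
) -> tuple[TASDataset, KineticScheme]:
    """Generate a named TAS preset; returns (dataset, generating scheme).

    Default IRF: 60 fs fwhm Gaussian at t0 = 0, no chirp; default noise is
    additive at SNR 100.
    """
    if name not in TAS_PRESETS:
        raise ValueError(f"unknown TAS preset {name!r} (choose from {sorted(TAS_PRESETS)})")
    preset = TAS_PRESETS[name]
    irf = irf or IRFModel(t0=0.0, fwhm=0.06)
    lam = default_wavelength_grid()
    S = preset["species"](lam)
    data = gen_tas_dataset(preset["scheme"], S, irf, spec=spec, wavelengths=lam)
    return data, preset["scheme"]


# ---------------------------------------------------------------------------
# TCSPC

TCSPC_PRESET = {
    "lifetimes_ns": (3.7,),
    "amplitudes": (1.0,),
    "irf_fwhm_ns": 0.075,
    "peak_counts": 5000,
    "window_ns": 25.0,
    "n_bins": 1024,
    "irf_center_ns": 2.0,
    "irf_peak_counts": 10000,
}


def gen_tcspc(
    lifetimes: Sequence[float] = TCSPC_PRESET["lifetimes_ns"],
    amplitudes: Sequence[float] = TCSPC_PRESET["amplitudes"],
    irf_fwhm: float = TCSPC_PRESET["irf_fwhm_ns"],
    peak_counts: float = TCSPC_PRESET["peak_counts"],
    spec: GeneratorSpec = GeneratorSpec(),
    window: float = TCSPC_PRESET["window_ns"],
    n_bins: int = TCSPC_PRESET["n_bins"],
    irf_center: float = TCSPC_PRESET["irf_center_ns"],
    irf_peak_counts: float = TCSPC_PRESET["irf_peak_counts"],
    poisson: bool = True,
) -> tuple[DecayHistogram, DecayHistogram]:
    """Poisson TCSPC decay + measured-IRF histogram pair.

    The decay expectation is the reconvolution of a Gaussian IRF (default
    75 ps fwhm, centered at 2 ns in a 25 ns / 1024-channel window) with the
    multiexponential, scaled so the peak channel expects ``peak_counts``
    (default 5000).  Both the decay and the returned IRF histogram are
    independent Poisson draws; ``poisson=False`` returns the expectations.
    """
    if peak_counts < 1:
        raise ValueError("peak counts must be >= 1")
    t = np.linspace(0.0, window, n_bins, endpoint=False)
    sigma = irf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    irf_shape = np.exp(-0.5 * ((t - irf_center) / sigma) ** 2)
    irf_clean = DecayHistogram(t, irf_shape / irf_shape.max() * irf_peak_counts, "irf")

    amps = np.asarray(amplitudes, dtype=float)
    expected = reconvolution_model(irf_clean, list(lifetimes), amps)
    expected = expected / expected.max() * peak_counts

    rng = spec.rng()
    if poisson:
        decay_counts = rng.poisson(expected).astype(float)
        irf_counts = rng.poisson(irf_clean.counts).astype(float)
    else:
        decay_counts = expected
        irf_counts = irf_clean.counts
    return (
        DecayHistogram(t, decay_counts, "synthetic decay"),
        DecayHistogram(t, irf_counts, "synthetic irf"),
    )
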