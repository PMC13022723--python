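# Methods

## Lineshapes and axis conventions

Every electronic transition is modelled as a skew-normal band
A(ν; A₀, ν₀, σ, γ) with area A₀ (absorbance·cm⁻¹), center ν₀ (cm⁻¹),
Gaussian width σ (cm⁻¹) and dimensionless skewness γ. The profile
integrates to A₀ for any γ and is non-negative for A₀ ≥ 0; at γ = 0 it is
a plain Gaussian with peak value A₀/(σ√(2π)). Widths and areas in the
preset band tables follow this convention (σ in cm⁻¹, A₀ in
absorbance·cm⁻¹).

All model evaluation happens on the wavenumber axis, because the Stark
expansion differentiates with respect to ν; nanometres are an I/O
convention mapped through the involution ν = 10⁷/λ. The internal grid is
uniform in ν at 5 cm⁻¹ over the fitted window (default 625–770 nm,
603 points), which resolves the narrowest ~150 cm⁻¹ bands with more than
30 points per σ.

The reduced derivatives ν·dᵏ/dνᵏ(A/ν) (k = 0, 1, 2) entering the Stark
model are computed **analytically** (chain rule through the Gaussian and
erf factors):

    D1 = A' − A/ν,      D2 = A'' − 2A'/ν + 2A/ν²,

so the optimizer sees smooth gradients. Central finite differences of A/ν
are retained as a test-only oracle (agreement ≤ 10⁻⁵ relative on
0.2 cm⁻¹ grids).

## Stark / Liptay analysis

The electroabsorption model is ΔA(ν) = (fF)²·Σ_bands [A_χ D0 + B_χ D1 +
C_χ D2]. Working units are CGS: ν in cm⁻¹, the applied field F converted
from V/cm to statvolt/cm (÷299.792458), B in cm²/erg, C in cm/erg. The
magic-angle relations B = Tr(Δα)/6hc and C = Δμ²/6h²c² convert to the
reported units with CODATA h, c, 1 Å³ = 10⁻²⁴ cm³ and
1 D = 10⁻¹⁸ statC·cm; the conversion pair is exercised by a round-trip
identity test at 10⁻¹⁰ relative. Because the local field factor f is
unknown, it defaults to 1 and all outputs are in f-scaled units
(Å³ f⁻², D f⁻¹), exactly as the fitted parameter tables report them.

`fit_simultaneous` shares one band set between the absorption and Stark
channels and parametrizes each band's Stark response directly by
(Tr(Δα), Δμ²) — algebraically identical to (B, C), which are linear in
these, but conditioned at magnitudes ~1–100 instead of ~10⁻⁸. Δμ² may go
negative during optimization; a negative value maps to C < 0 and is
reported as a non-physical band (Δμ = 0 plus a warning), never silently
clamped. A_χ is fixed at 0 at the magic angle (the configuration the
analysis supports) and can be freed for diagnostics. γ is fixed at 0 by
default: the preset tables do not constrain skewness, and the generators
declare γ = 0.

The joint objective concatenates the two channels' residuals, each
normalized by its channel's peak absolute value, with a user weight ratio
(default 1:1); with the Stark weight at zero the fit reduces exactly to
the absorption-only fit. The optimizer is a bounded trust-region
reflective least-squares solve (`scipy.optimize.least_squares`,
`x_scale="jac"`, tolerances 10⁻¹⁴), deterministic given the
initialization. Bands are reported sorted by ascending ν₀.

**Per-point weighting.** Uniform weighting within each channel is the
default. Under the generators' multiplicative noise model the noise
standard deviation is proportional to |signal|, and uniform-weight
nonlinear least squares then carries a second-order (noise²) bias on weak
bands that overlap strong ones — measured at ~8% on the 15 Å³ f⁻²
polarizability change of the dimers' 667 nm band at 1% noise, quartering
when the noise halves. `point_weights="proportional"` selects
inverse-variance weighting for that noise model (1/|data| with a floor at
5% of the channel peak, guarding the Stark zero crossings); it removes
the bias (ensemble-mean errors < 1%) and roughly halves the scatter, and
is what the ensemble-recovery tests use on noisy data.

## Transient-absorption global analysis

The kinetic basis function is the exponentially modified Gaussian
c(t) = ½·exp(−k(t−t₀) + k²s²/2)·erfc(−((t−t₀) − ks²)/s√2) with
s = fwhm/(2√(2 ln 2)), evaluated through `erfcx` for x ≥ 0 and the plain
product for x < 0 so neither tail overflows; fwhm = 0 degenerates to the
step exponential. Sequential-chain populations use the Bateman
coefficients b_jl (unit injection into compartment 1, 100% transfer down
the chain); equal lifetimes make that algebra singular and are rejected
rather than handled by the confluent limit. EADS and DADS are two bases
for the same model matrix, linked by the upper-triangular Bateman matrix
(DADS = B·EADS), so both representations reconstruct identically — an
invariant asserted to 10⁻¹⁰ on every fit.

`global_fit` uses variable projection: free lifetimes (in log space, so
positivity is structural), t₀ and the IRF width are the nonlinear
parameters; at each step the species spectra are the conditionally
optimal linear coefficients (per-wavelength least squares, NaN-masked).
Fixed lifetimes — in practice the 3.7 ns fluorescence component from
TCSPC, which the 1 ns delay window cannot determine — are honored
exactly. Lifetimes are reported ascending.

Pre-processing: `prezero_subtract` removes the mean spectrum over a
pre-time-zero window (static scatter); `chirp_correct` resamples each
wavelength's trace by the chirp polynomial (cubic in λ about a reference
wavelength by default) and marks samples shifted outside the recorded
span as missing, which the fit residual then excludes rather than
imputes.

## TCSPC reconvolution

The model is the discrete causal convolution of the normalized, temporally
shifted IRF histogram with Σ aᵢ·exp(−t/τᵢ), on the histogram's own bin
grid — the convention of standard TCSPC software, which a brute-force
direct-sum oracle reproduces to 10⁻⁶; the discrete model approaches the
continuous Gaussian⊗exponential only to first order in the bin width at
the IRF rise, which is expected and tested. Weights are
1/√max(counts, 1) (Gaussian approximation to Poisson noise, unit weight
on empty bins); the IRF shift is a free nuisance parameter. Reduced χ²
uses dof = bins − parameters, with the χ² < 1.200 acceptance rule. On
replicated synthetic data the estimator is unbiased to ≤1% and the
generating model's reduced χ² averages ≈1.

## Synthetic data

Generators are deterministic (`numpy.random.default_rng(seed)`; same seed
⇒ identical bytes) and declare their noise models: multiplicative
Gaussian on spectra (default 1%), additive Gaussian on TAS matrices with
σ = noise_level × max|ΔA| (default 1%, i.e. SNR 100), Poisson on TCSPC
counts.

* **Stark presets** are the fitted band tables of the three complexes
  (monomer `2H2A`; dimers `4E4K`, `4L4A`), with γ = 0 and A_χ = 0, under
  a 2.2×10⁵ V/cm field at the magic angle with f = 1.
* **TAS presets**: the monomer is generated in the parallel (DADS) basis —
  three spectrally similar species (bleach at 676 nm, stimulated-emission
  wing at 737 nm) with the fastest carrying 10% of the main-band
  amplitude; the dimer in the sequential (EADS) basis — four compartments
  with the main bleach red-shifted to ~681 nm and a broad positive
  photoinduced absorption beyond ~712 nm that rises and decays with the
  151 ps compartment. Species shapes are hand-built Gaussian mixtures
  that reproduce the qualitative spectral structure (band positions,
  signs, relative amplitudes), not quantum-chemically derived spectra;
  recovery tests therefore validate the kinetics and the fitting
  machinery, not the spectral shapes themselves. The delay grid spans
  −1 ps to 1 ns (dense linear rise, logarithmic tail, 115 points) over
  620–780 nm at 2 nm (81 points); the default IRF is 60 fs fwhm, within
  the 45–80 fs instrument range, with no chirp unless requested.
* **TCSPC preset**: 3.7 ns mono-exponential decay, 75 ps fwhm Gaussian
  IRF centered at 2 ns, 1024 channels over 25 ns, 5000 expected counts in
  the peak channel; the returned IRF histogram is an independent Poisson
  draw with 10⁴ peak counts. The 25 ns window keeps bin expectations
  ≳10 counts where Gaussian weighting of Poisson data is sound.

What passing the recovery tests shows — and does not: synthetic data obey
the fitted model family exactly (no coherent artifacts around time zero,
no baseline drift, no wavelength-correlated noise, no impurity emission),
so recovery demonstrates correctness and statistical calibration of the
estimators, not robustness to model misspecification in real
measurements.

## Numerical and design notes

* Simultaneous Stark fits of the five-band dimer tables are benign: with
  noiseless data the optimizer returns the generating parameters from
  initializations several percent off (centers +2 nm), because the
  absorption channel pins the band shapes and the Stark channel is linear
  in the per-band molecular parameters given those shapes.
* The monomer band table's summed spectrum peaks ~0.4 nm blue of the bare
  669 nm band center (overlap with the 653 nm vibronic satellite); tests
  compare against a dense-grid argmax rather than the bare center.
* Degenerate inputs: empty grids produce empty spectra; σ ≤ 0, unknown
  derivative orders, band/coefficient count mismatches, non-monotone
  axes, ragged matrices and transposed TAS layouts all raise early with
  the offending file/line where applicable.
* Sequential vs parallel is a modelling choice exposed to the user; the
  recovered lifetimes coincide (the two bases span the same exponential
  space), which is why lifetime-recovery checks are basis-independent.
* Problem sizes used by the recovery suite and `scripts/acceptance.py`
  (603-point spectra; 115×81 TAS matrices; 1024-channel histograms; 20
  noise replicates for the Stark ensemble) are the generators' defaults,
  chosen to mirror the instruments' native resolutions.

## Known limitations

* Only magic-angle Stark analysis: no angle-resolved (off-χ) Liptay
  terms, no higher-order Stark effects, and A_χ is treated as negligible.
* The sequential TAS model is unbranched and 100% efficient; branched or
  reversible target schemes and anisotropy decomposition are out of
  scope, as is coherent-artifact modelling.
* TCSPC fitting is Gaussian-weighted least squares, not Poisson maximum
  likelihood; at very low counts per bin the χ² calibration degrades.
* The preset species spectra are representative, not reconstructions of
  measured difference spectra.
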