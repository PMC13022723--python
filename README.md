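# chromospec

Spectroscopic inference for chromophore–protein complexes: a Python library
that extracts molecular photophysics from three complementary measurements
of pigment assemblies such as zinc-porphyrin–binding four-helix bundles,
where excitonic coupling between chromophore dimers mixes with
charge-transfer (CT) states.

1. **Stark (electroabsorption) spectroscopy — Liptay analysis.** Each
   electronic transition is a skewed Gaussian band in wavenumber space,

   A(ν) = A₀/(√(2π)σ) · exp[−(ν−ν₀)²/2σ²] · {1 + erf[γ(ν−ν₀)/√2σ]},

   and the field-induced change in absorbance is a weighted sum of its
   reduced derivatives,

   ΔA(ν) = (fF)² { A_χ A(ν) + B_χ ν d/dν(A/ν) + C_χ ν d²/dν²(A/ν) }.

   At the magic angle χ = arccos(1/√3) ≈ 54.7°, A_χ is negligible and
   B = Tr(Δα)/6hc, C = Δμ²/6h²c²: the derivative weights carry the trace
   of the polarizability change (Å³ f⁻²) and the dipole-moment change
   (D f⁻¹), with f the unknown local-field factor. Absorption and Stark
   spectra are fitted **simultaneously**, sharing one band set. A large Δμ
   flags CT character — the signature of exciton–CT mixing in coupled
   dimers.

2. **Broadband transient absorption — global analysis.** A ΔA(t, λ) matrix
   is pre-processed (pre-time-zero scatter subtraction, chirp correction)
   and fitted globally with exponential components convolved with a
   Gaussian IRF, via variable projection. Sequential (unbranched,
   unidirectional) and parallel compartment models give EADS and DADS,
   related by an exact triangular change of basis. The nanosecond component
   is fixed to the fluorescence lifetime from TCSPC.

3. **TCSPC — reconvolution fitting.** Poisson decay histograms are fitted
   as multiexponentials convolved with the measured IRF, accepted when the
   reduced χ² < 1.200.

Synthetic-data generators (`chromospec.synthetic`) produce every input the
fitters consume — band-table spectra, kinetic-scheme TAS matrices, Poisson
TCSPC histograms — with presets encoding the monomer (`2H2A`) and dimer
(`4E4K`, `4L4A`) band tables and the monomer (1.77 ps / 130 ps / 3.7 ns)
and dimer (1.2 / 14 / 151 ps / 3.7 ns) kinetic schemes.

## Worked example

```python
from chromospec.lineshapes import SkewedGaussianBand
from chromospec.stark import FieldConditions, fit_simultaneous
from chromospec.synthetic import STARK_PRESETS, gen_stark_dataset

rows = STARK_PRESETS["2H2A"]                    # four Qy-region bands
absorption, stark = gen_stark_dataset(rows)     # 2.2e5 V/cm, magic angle
init = [SkewedGaussianBand(r.area, 1e7 / (r.center_nm + 2.0), r.width)
        for r in rows]                          # start 2 nm off
result = fit_simultaneous(absorption, stark, FieldConditions(), init)
for band, mol in zip(result.bands, result.molecular):
    print(f"{1e7/band.center:6.1f} nm  Tr(da)={mol.tr_dalpha:7.1f}  "
          f"dmu={mol.dmu:5.2f}")
```

prints

```
 697.0 nm  Tr(da)=  -57.5  dmu= 0.55
 669.0 nm  Tr(da)=   10.5  dmu= 0.64
 653.0 nm  Tr(da)=   14.3  dmu= 0.26
 635.0 nm  Tr(da)=   21.8  dmu= 1.22
```

i.e. the fit walks back from the perturbed start to the generating band
table: the 669 nm main band of the monomeric complex has a small
dipole-moment change (0.64 D f⁻¹) and modest polarizability change — its
Stark response is first-derivative-like, with no CT admixture. The dimer
presets (`4E4K`, `4L4A`) recover Δμ ≈ 1.7–1.8 D f⁻¹ for the low-exciton
685 nm band, the three-fold enhancement that indicates exciton–CT mixing.

More narrative walk-throughs live in `examples/` (one per stage: Stark,
TAS, TCSPC). A thin CLI covers the same ground from the shell:
`chromospec simulate-stark|fit-stark|simulate-tas|fit-tas|simulate-tcspc|fit-tcspc`
(see `chromospec --help`; every run writes a `run_config.json` with the
exact options and seed).

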