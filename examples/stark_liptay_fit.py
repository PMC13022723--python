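"""Simultaneous Liptay fit of an absorption + Stark spectrum pair.

Generates the monomeric-complex preset (four Qy-region bands, magic-angle
field of 2.2e5 V/cm), fits both channels jointly and prints the per-band
molecular parameters.  Tr(dAlpha) is the trace of the polarizability change
(A^3 f^-2) and dMu the dipole-moment change (D f^-1); a large dMu signals
charge-transfer character of that transition.
"""

from chromospec.lineshapes import SkewedGaussianBand
from chromospec.stark import FieldConditions, fit_simultaneous
from chromospec.synthetic import GeneratorSpec, STARK_PRESETS, gen_stark_dataset

rows = STARK_PRESETS["2H2A"]
absorption, stark = gen_stark_dataset(
    rows, spec=GeneratorSpec(seed=0, noise_level=0.0)
)

# start the fit 2 nm off the true centers, Stark response at zero
init = [SkewedGaussianBand(r.area, 1e7 / (r.center_nm + 2.0), r.width) for r in rows]
result = fit_simultaneous(absorption, stark, FieldConditions(), init)

print("band    area     sigma    Tr(dAlpha)   dMu")
print("[nm]             [cm-1]   [A^3/f^2]    [D/f]")
for band, mol in zip(result.bands, result.molecular):
    print(
        f"{1e7 / band.center:6.1f} {band.area:8.1f} {band.width:8.1f} "
        f"{mol.tr_dalpha:10.1f} {mol.dmu:8.2f}"
    )
print(
    f"\nconverged: {result.converged}; residual norms "
    f"abs={result.absorption_residual_norm:.2e} "
    f"stark={result.stark_residual_norm:.2e}"
)
print(
    "The 669 nm main band shows a small dMu (~0.6 D/f): the monomer's "
    "Stark response is dominated by the polarizability change."
)
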