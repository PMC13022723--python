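"""Kinetic model, pre-processing and global analysis of TAS matrices."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad, solve_ivp

from chromospec.synthetic import (
    GeneratorSpec,
    TAS_PRESETS,
    default_wavelength_grid,
    gen_tas_dataset,
    gen_tas_preset,
)
from chromospec.tas import (
    DegenerateRatesError,
    IRFModel,
    KineticScheme,
    TASDataset,
    amplitude_fraction,
    chirp_correct,
    concentrations,
    convolved_exponential,
    dads_from_eads,
    eads_from_dads,
    global_fit,
    prezero_subtract,
    sequential_mixing_matrix,
)


def numeric_convolution(t, rate, t0, fwhm):
    """Quadrature oracle: normalized Gaussian x causal exponential."""
    s = fwhm / (2 * np.sqrt(2 * np.log(2)))

    def one(ti):
        val, _ = quad(
            lambda u: np.exp(-0.5 * ((u - t0) / s) ** 2)
            / (s * np.sqrt(2 * np.pi))
            * np.exp(-rate * (ti - u)),
            t0 - 10 * s,
            ti,
            epsabs=1e-13,
            epsrel=1e-13,
            limit=400,
        )
        return val

    return np.array([one(ti) for ti in t])


class TestConvolvedExponential:
    def test_delta_irf_limit(self):
        t = np.array([0.5, 1.0, 5.0])
        out = convolved_exponential(t, rate=2.0, t0=0.0, fwhm=0.0)
        np.testing.assert_allclose(out, np.exp(-2.0 * t), rtol=1e-14)

    def test_causality(self):
        t = np.array([-1.0, -0.7])
        out = convolved_exponential(t, rate=1.0, t0=0.0, fwhm=0.06)
        assert np.all(out < 1e-6)

    def test_against_quadrature(self):
        t = np.linspace(-0.3, 6.0, 25)
        got = convolved_exponential(t, rate=1 / 1.2, t0=0.05, fwhm=0.06)
        want = numeric_convolution(t, 1 / 1.2, 0.05, 0.06)
        assert np.max(np.abs(got - want)) < 1e-8

    @given(
        rate=st.floats(1e-3, 10.0),
        fwhm=st.floats(0.04, 0.1),
    )
    def test_quadrature_property(self, rate, fwhm):
        t = np.array([-0.1, 0.0, 0.1, 0.5, 2.0])
        got = convolved_exponential(t, rate, 0.0, fwhm)
        want = numeric_convolution(t, rate, 0.0, fwhm)
        assert np.max(np.abs(got - want)) < 1e-8

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            convolved_exponential(np.array([0.0]), rate=-1.0)


class TestConcentrations:
    irf = IRFModel(t0=0.1, fwhm=0.06)

    def test_single_component_bases_agree(self):
        t = np.linspace(-0.5, 10, 200)
        seq = concentrations(KineticScheme("sequential", (2.0,)), self.irf, t)
        par = concentrations(KineticScheme("parallel", (2.0,)), self.irf, t)
        direct = convolved_exponential(t, 0.5, self.irf.t0, self.irf.fwhm)
        np.testing.assert_allclose(seq[:, 0], direct, rtol=1e-14)
        np.testing.assert_allclose(par[:, 0], direct, rtol=1e-14)

    def test_sequential_matches_ode_integration(self):
        """Bateman-coefficient populations vs direct stiff integration of the
        chain pumped by the Gaussian IRF."""
        taus = (0.5, 5.0, 50.0)
        scheme = KineticScheme("sequential", taus)
        irf = self.irf
        k = 1.0 / np.asarray(taus)
        s = irf.sigma

        def pump(t):
            return np.exp(-0.5 * ((t - irf.t0) / s) ** 2) / (s * np.sqrt(2 * np.pi))

        def rhs(t, c):
            return [
                pump(t) - k[0] * c[0],
                k[0] * c[0] - k[1] * c[1],
                k[1] * c[1] - k[2] * c[2],
            ]

        t_eval = np.linspace(-0.4, 40.0, 120)
        sol = solve_ivp(
            rhs, (-1.0, 40.0), [0.0, 0.0, 0.0], t_eval=t_eval,
            method="DOP853", rtol=1e-11, atol=1e-13, max_step=0.05,
        )
        got = concentrations(scheme, irf, t_eval)
        assert np.max(np.abs(got - sol.y.T)) < 1e-6

    def test_unit_injection_at_narrow_irf(self):
        t = np.array([0.1001])
        scheme = KineticScheme("sequential", (1e4,))
        got = concentrations(scheme, IRFModel(t0=0.1, fwhm=1e-6), t)
        assert got[0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_rates_rejected(self):
        with pytest.raises(ValueError):
            KineticScheme("sequential", (1.0, 1.0, 2.0))
        with pytest.raises(DegenerateRatesError):
            sequential_mixing_matrix(np.array([1.0, 1.0]))


class TestEadsDads:
    scheme = KineticScheme("sequential", (1.0, 10.0, 100.0))

    def test_single_component_identity(self):
        one = KineticScheme("sequential", (5.0,))
        eads = np.array([[1.0, -2.0, 3.0]])
        np.testing.assert_array_equal(dads_from_eads(eads, one), eads)

    def test_round_trip_and_reconstruction(self):
        rng = np.random.default_rng(3)
        eads = rng.standard_normal((3, 17))
        dads = dads_from_eads(eads, self.scheme)
        back = eads_from_dads(dads, self.scheme)
        assert np.max(np.abs(back - eads)) < 1e-12
        t = np.linspace(-0.5, 300, 400)
        irf = IRFModel(0.0, 0.08)
        c_seq = concentrations(self.scheme, irf, t)
        c_par = concentrations(
            KineticScheme("parallel", self.scheme.lifetimes), irf, t
        )
        assert np.max(np.abs(c_seq @ eads - c_par @ dads)) < 1e-10

    def test_mixing_matrix_against_independent_expansion(self):
        """Expand each sequential population on the exponential basis by
        least squares against an ODE solution (no IRF) and compare with the
        analytic Bateman coefficients."""
        k = 1.0 / np.asarray(self.scheme.lifetimes)

        def rhs(t, c):
            return [
                -k[0] * c[0],
                k[0] * c[0] - k[1] * c[1],
                k[1] * c[1] - k[2] * c[2],
            ]

        t = np.linspace(0.0, 400.0, 4000)
        sol = solve_ivp(rhs, (0, 400.0), [1.0, 0.0, 0.0], t_eval=t,
                        method="LSODA", rtol=1e-11, atol=1e-13)
        basis = np.exp(-np.outer(t, k))
        coeffs, *_ = np.linalg.lstsq(basis, sol.y.T, rcond=None)
        B = sequential_mixing_matrix(k)
        assert np.max(np.abs(coeffs - B)) < 1e-5


class TestPreprocessing:
    def _dataset(self, noise=0.0, seed=0):
        data, _ = gen_tas_preset(
            "monomer", spec=GeneratorSpec(seed=seed, noise_level=noise)
        )
        return data

    def test_constant_offset_removed_exactly(self):
        data = self._dataset()
        offset = np.linspace(-1e-3, 2e-3, data.wavelengths.size)
        shifted = TASDataset(data.delays, data.wavelengths, data.deltaA + offset)
        out = prezero_subtract(shifted, (-1.0, -0.3))
        np.testing.assert_allclose(out.deltaA, data.deltaA, atol=1e-15)

    def test_prezero_rows_centered_after_subtraction(self):
        data = self._dataset(noise=0.01, seed=5)
        out = prezero_subtract(data, (-1.0, -0.3))
        pre = out.deltaA[out.delays <= -0.3]
        assert np.max(np.abs(pre.mean(axis=0))) < 1e-12

    def test_rms_reduction_matches_direct_computation(self):
        data = self._dataset(noise=0.01, seed=5)
        sel = data.delays <= -0.3
        out = prezero_subtract(data, (-1.0, -0.3))
        rms_before = np.sqrt(np.mean(data.deltaA[sel] ** 2))
        rms_after = np.sqrt(np.mean(out.deltaA[sel] ** 2))
        oracle = np.sqrt(
            np.mean((data.deltaA[sel] - data.deltaA[sel].mean(axis=0)) ** 2)
        )
        assert rms_after == pytest.approx(oracle, rel=1e-12)
        assert rms_after <= rms_before

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            prezero_subtract(self._dataset(), (-10.0, -5.0))

    def test_zero_chirp_is_identity(self):
        data = self._dataset()
        out = chirp_correct(data, IRFModel(t0=0.0, fwhm=0.06))
        np.testing.assert_allclose(out.deltaA, data.deltaA, atol=0)

    def test_known_chirp_recovered(self):
        """Data generated with a chirped IRF, then corrected: the fitted
        per-wavelength onset becomes constant within one delay step."""
        lam = default_wavelength_grid()
        scheme = KineticScheme("sequential", (1000.0,))
        irf = IRFModel(t0=0.0, fwhm=0.06, chirp_coeffs=(1.5e-3, 0.0, -2e-8),
                       lambda_ref=700.0)
        S = -np.ones((1, lam.size)) * 1e-3
        delays = np.arange(-1.0, 2.0, 0.02)
        data = gen_tas_dataset(scheme, S, irf, delays=delays, wavelengths=lam)

        def onsets(d):
            # half-rise time of |trace| per wavelength, linear interpolation
            out = []
            for j in range(d.wavelengths.size):
                y = np.abs(d.deltaA[:, j])
                y = np.where(np.isfinite(y), y, 0.0)
                half = 0.5 * y.max()
                i = int(np.argmax(y >= half))
                x0, x1 = d.delays[i - 1], d.delays[i]
                y0, y1 = y[i - 1], y[i]
                out.append(x0 + (half - y0) * (x1 - x0) / (y1 - y0))
            return np.asarray(out)

        assert np.ptp(onsets(data)) > 0.1  # chirp clearly present
        fixed = chirp_correct(data, irf)
        assert np.ptp(onsets(fixed)) <= 0.02 + 1e-9

    def test_opposite_chirp_round_trip(self):
        data = self._dataset()
        c = (2e-4, 0.0, 0.0)
        fwd = chirp_correct(data, IRFModel(0.0, 0.06, c))
        back = chirp_correct(fwd, IRFModel(0.0, 0.06, tuple(-x for x in c)))
        ok = np.isfinite(back.deltaA) & np.isfinite(data.deltaA)
        # interior samples return to the original within linear-interpolation
        # error: bounded by max|f''| h^2 with h the (<=16 fs) chirp shift,
        # i.e. a couple of percent of the signal at the sharp IRF rise
        scale = np.max(np.abs(data.deltaA))
        assert np.max(np.abs((back.deltaA - data.deltaA)[ok])) < 0.04 * scale


class TestGlobalFit:
    def test_noiseless_monomer_lifetimes_exact(self):
        data, truth = gen_tas_preset("monomer", spec=GeneratorSpec(noise_level=0.0))
        init = KineticScheme("parallel", (2.5, 90.0, 3700.0), (False, False, True))
        res = global_fit(data, init, IRFModel(0.005, 0.07))
        assert res.converged
        assert res.scheme.lifetimes[0] == pytest.approx(1.77, rel=1e-6)
        assert res.scheme.lifetimes[1] == pytest.approx(130.0, rel=1e-6)
        assert res.scheme.lifetimes[2] == 3700.0  # fixed

    def test_noisy_dimer_lifetimes_within_10pct(self):
        data, truth = gen_tas_preset(
            "dimer", spec=GeneratorSpec(seed=11, noise_level=0.01)
        )
        init = KineticScheme(
            "sequential", (0.9, 18.0, 120.0, 3700.0), (False, False, False, True)
        )
        res = global_fit(data, init, IRFModel(0.01, 0.08))
        for got, want in zip(res.scheme.lifetimes[:3], (1.2, 14.0, 151.0)):
            assert got == pytest.approx(want, rel=0.10)

    def test_self_consistent_residual_is_zero(self):
        data, scheme = gen_tas_preset("dimer", spec=GeneratorSpec(noise_level=0.0))
        res = global_fit(data, scheme, IRFModel(0.0, 0.06), fit_irf=False)
        assert np.nanmax(np.abs(res.residual)) < 1e-8

    def test_eads_dads_reconstruct_identically(self):
        data, _ = gen_tas_preset("dimer", spec=GeneratorSpec(seed=2, noise_level=0.01))
        init = KineticScheme(
            "sequential", (1.0, 12.0, 140.0, 3700.0), (False, False, False, True)
        )
        res = global_fit(data, init, IRFModel(0.0, 0.06))
        c_seq = concentrations(res.scheme, res.irf, data.delays)
        c_par = concentrations(
            KineticScheme("parallel", res.scheme.lifetimes), res.irf, data.delays
        )
        assert np.max(np.abs(c_seq @ res.eads - c_par @ res.dads)) < 1e-10

    def test_extra_component_never_fits_worse(self):
        data, _ = gen_tas_preset("monomer", spec=GeneratorSpec(seed=4, noise_level=0.01))
        irf = IRFModel(0.0, 0.06)
        res2 = global_fit(
            data, KineticScheme("parallel", (2.0, 200.0)), irf, fit_irf=False
        )
        taus2 = res2.scheme.lifetimes
        res3 = global_fit(
            data,
            KineticScheme("parallel", (taus2[0], taus2[1], 3700.0),
                          (False, False, True)),
            irf,
            fit_irf=False,
        )
        assert res3.rms <= res2.rms * (1 + 1e-9)

    def test_too_few_delays_rejected(self):
        data = TASDataset(
            np.array([0.0, 1.0, 2.0]), np.array([650.0, 660.0]), np.zeros((3, 2))
        )
        with pytest.raises(ValueError):
            global_fit(data, KineticScheme("parallel", (1.0, 10.0)), IRFModel())


class TestAmplitudeFraction:
    def test_single_component_is_100(self):
        data, _ = gen_tas_preset("monomer", spec=GeneratorSpec(noise_level=0.0))
        res = global_fit(
            data, KineticScheme("parallel", (100.0,)), IRFModel(0.0, 0.06),
            fit_irf=False,
        )
        assert amplitude_fraction(res, 0, (660.0, 690.0)) == pytest.approx(100.0)

    def test_fractions_sum_to_100(self):
        data, scheme = gen_tas_preset("dimer", spec=GeneratorSpec(seed=6, noise_level=0.01))
        res = global_fit(data, scheme, IRFModel(0.0, 0.06), fit_irf=False)
        total = sum(
            amplitude_fraction(res, i, (660.0, 700.0))
            for i in range(len(scheme.lifetimes))
        )
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_monomer_fast_component_carries_10pct(self):
        """The preset builds the fastest parallel species with 10% of the
        main-band amplitude; the fitted DADS should report it back."""
        data, scheme = gen_tas_preset("monomer", spec=GeneratorSpec(noise_level=0.0))
        res = global_fit(data, scheme, IRFModel(0.0, 0.06), fit_irf=False)
        frac = amplitude_fraction(res, 0, (660.0, 690.0))
        assert frac == pytest.approx(10.0, abs=0.5)

    def test_empty_window_rejected(self):
        data, scheme = gen_tas_preset("monomer", spec=GeneratorSpec(noise_level=0.0))
        res = global_fit(data, scheme, IRFModel(0.0, 0.06), fit_irf=False)
        with pytest.raises(ValueError):
            amplitude_fraction(res, 0, (100.0, 200.0))
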