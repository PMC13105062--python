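"""Torsional helical-phasing model: forward curve, limits, and fitting."""

import numpy as np
import pytest

from snaparray.phasing import (
    BOLTZMANN_ERG_PER_K,
    RISE_PER_BP_CM,
    PhasingParams,
    fit_phasing,
    helix_projection,
    log_predict_F,
    phase_of,
    predict_F,
    sigma_bp,
    sigma_tw,
)
from snaparray.simulate import simulate_phasing_series


class TestSigmaBp:
    def test_plugin_value(self):
        # direct evaluation of (h_r / 2 pi) sqrt(l k T / C_app) with
        # l = 3.4e-8 cm, T = 298 K, C_app = 2.4e-19 erg cm, h_r = 10.5,
        # checked against an independent hand calculation
        p = PhasingParams(h_r=10.5, C_app=2.4e-19, T=298.0)
        assert sigma_bp(p) == pytest.approx(0.1275830680884418, rel=1e-12)

    def test_linear_in_hr(self):
        p1 = PhasingParams(h_r=5.0)
        p2 = PhasingParams(h_r=10.0)
        assert sigma_bp(p2) == pytest.approx(2 * sigma_bp(p1))

    def test_rigid_limit(self):
        soft = sigma_bp(PhasingParams(C_app=1e-19))
        stiff = sigma_bp(PhasingParams(C_app=1e-16))
        assert stiff < soft
        assert sigma_bp(PhasingParams(C_app=1e-10)) == pytest.approx(0.0, abs=1e-3)

    def test_positive_modulus_required(self):
        with pytest.raises(ValueError):
            PhasingParams(C_app=-1.0)


class TestSigmaTw:
    def test_zero_at_zero_spacing(self):
        assert sigma_tw(0.0, PhasingParams()) == 0.0

    def test_sqrt_scaling(self):
        p = PhasingParams()
        assert sigma_tw(4.0, p) == pytest.approx(2 * sigma_bp(p))

    def test_monotone_and_negative_rejected(self):
        p = PhasingParams()
        s = np.arange(0, 40)
        vals = sigma_tw(s, p)
        assert (np.diff(vals) >= 0).all()
        with pytest.raises(ValueError):
            sigma_tw(-1.0, p)


@pytest.fixture(scope="module")
def narrow_params():
    """Parameters with sigma_TW << h_r so minima are sharp."""
    return PhasingParams.from_sigma_bp(h_r=5.46, sigma_bp_value=0.15,
                                       K_min=1.0, s_min=1.0)


class TestPredictF:
    def test_minimum_equals_k_min(self, narrow_params):
        assert predict_F(narrow_params.s_min, narrow_params) == pytest.approx(1.0, rel=1e-9)

    def test_later_minima_bounded_by_k_min(self, narrow_params):
        p = narrow_params
        # extra Gaussian tails only increase the sum, so F <= K_min there
        for n in range(1, 5):
            assert predict_F(p.s_min + n * p.h_r, p) <= p.K_min + 1e-12

    def test_against_arbitrary_precision_summation(self, narrow_params):
        """193-term sum cross-checked with sympy at 50 decimal digits."""
        import sympy

        p = narrow_params
        s = sympy.Rational(373, 100)
        sig2 = 2 * s * sympy.Float(sigma_bp(p), 50) ** 2
        total = sympy.Float(0, 50)
        for n in range(-p.N, p.N + 1):
            d = s - (sympy.Float(p.s_min, 50) + n * sympy.Float(p.h_r, 50))
            total += sympy.exp(-(d**2) / sig2)
        expected = float(1 / total)
        assert predict_F(3.73, p) == pytest.approx(expected, rel=1e-10)

    def test_underflow_returns_inf_sentinel(self):
        p = PhasingParams.from_sigma_bp(h_r=10.5, sigma_bp_value=1e-4,
                                        K_min=1.0, s_min=1.0)
        with pytest.warns(UserWarning, match="underflow"):
            assert np.isposinf(predict_F(6.0, p))

    def test_zero_spacing_limit(self):
        p = PhasingParams.from_sigma_bp(h_r=5.0, sigma_bp_value=0.1,
                                        K_min=2.0, s_min=0.0)
        assert predict_F(0.0, p) == pytest.approx(2.0)

    def test_stiffer_dna_raises_contrast(self):
        """Larger torsional modulus means less damping between minima."""
        s_mid = 1.0 + 5.46 / 2
        values = []
        for c_app in (1e-20, 1e-19, 1e-18):
            p = PhasingParams(h_r=5.46, K_min=1.0, s_min=1.0, C_app=c_app)
            values.append(log_predict_F(s_mid, p))
        assert values[0] < values[1] < values[2]

    def test_truncation_n96_is_converged(self, narrow_params):
        s = np.linspace(0.5, 40.0, 80)
        f96 = log_predict_F(s, narrow_params)
        p_big = PhasingParams(h_r=narrow_params.h_r, K_min=1.0, s_min=1.0,
                              C_app=narrow_params.C_app, N=10_000)
        f_big = log_predict_F(s, p_big)
        finite = np.isfinite(f96)
        np.testing.assert_allclose(f96[finite], f_big[finite], rtol=1e-12)

    def test_successive_minima_spaced_by_h_r(self, narrow_params):
        s = np.arange(0.5, 33.0, 0.01)
        f = log_predict_F(s, narrow_params)
        # local minima of the noise-free curve
        idx = np.nonzero((f[1:-1] < f[:-2]) & (f[1:-1] < f[2:]))[0] + 1
        gaps = np.diff(s[idx])
        assert len(gaps) >= 4
        np.testing.assert_allclose(gaps, narrow_params.h_r, atol=0.02)


class TestFit:
    def test_noise_free_self_consistency(self, narrow_params):
        df = simulate_phasing_series(narrow_params, range(0, 33), noise_frac=0.0,
                                     n_reps=1, rng=np.random.default_rng(0))
        init = PhasingParams(h_r=narrow_params.h_r * 1.1,
                             K_min=narrow_params.K_min * 1.1,
                             s_min=narrow_params.s_min * 0.9,
                             C_app=narrow_params.C_app * 1.1)
        fit = fit_phasing(df["spacing"], df["mean_intensity"], init=init, scale="log")
        assert fit.converged
        assert abs(fit.params.h_r - narrow_params.h_r) < 1e-3

    def test_noisy_recovery(self, narrow_params):
        rng = np.random.default_rng(11)
        errs = []
        for _ in range(5):
            df = simulate_phasing_series(narrow_params, range(0, 33),
                                         noise_frac=0.05, n_reps=3, rng=rng)
            fit = fit_phasing(df["spacing"], df["mean_intensity"], scale="log")
            errs.append(abs(fit.params.h_r - narrow_params.h_r))
        assert np.median(errs) < 0.1

    def test_constant_intensities_flagged(self):
        s = np.arange(1.0, 13.0)
        y = np.full_like(s, 5.0)
        fit = fit_phasing(s, y)
        assert not fit.converged
        assert "unidentifiable" in fit.message

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_phasing([1, 2, 3], [1.0, 2.0, 3.0])


class TestPhaseAndProjection:
    def test_phase_of(self, narrow_params):
        p = narrow_params
        assert phase_of(p.s_min, p) == 0.0
        assert phase_of(p.s_min + p.h_r / 2, p) == pytest.approx(0.5)
        assert phase_of(p.s_min + 3 * p.h_r, p) == pytest.approx(0.0, abs=1e-9)

    def test_helix_projection(self):
        assert helix_projection(10.5) == pytest.approx(0.0, abs=1e-12)
        assert helix_projection(5.25) == pytest.approx(np.pi)
        assert helix_projection(21.0) == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError):
            helix_projection(-1.0)
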