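"""Fractional-integral response: quadrature oracle, limits, prediction loop."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import gamma

from fdeeg import (
    FluxSeries,
    ModelConfig,
    StimulusPulse,
    detect_response,
    effective_diffusivity,
    frac_integral,
    fractional_response,
    gaussian_flux,
    growth_exponent,
    predict_signal,
    pulse_train_flux,
    sample_flux,
    simulate_fgn,
)
from fdeeg.exceptions import DomainError, ExtrapolationError

TABLE_PULSE = StimulusPulse(phi0=1.0, t_star=0.002, sigma=0.001)


def quad_oracle(pulse: StimulusPulse, H: float, t: float) -> float:
    """Adaptive quadrature of (1/Γ(H)) ∫0^t φ(ξ)(t−ξ)^{H−1} dξ with the
    endpoint singularity handled by an algebraic weight after the
    substitution u = t − ξ."""
    val, _ = quad(
        lambda u: gaussian_flux(t - u, pulse),
        0.0,
        t,
        weight="alg",
        wvar=(H - 1.0, 0.0),
        limit=200,
    )
    return val / gamma(H)


def dense_flux(pulse: StimulusPulse, duration: float, dt: float) -> FluxSeries:
    return sample_flux(pulse, duration, dt)


class TestGaussianFlux:
    def test_peak_and_width(self):
        p = StimulusPulse(phi0=2.0, t_star=0.01, sigma=0.003)
        assert gaussian_flux(p.t_star, p) == pytest.approx(2.0)
        assert gaussian_flux(p.t_star + p.sigma, p) == pytest.approx(2.0 / np.e)

    def test_reference_pulse_at_4ms(self):
        # printed exponent: no factor 2 in the denominator
        assert gaussian_flux(0.004, TABLE_PULSE) == pytest.approx(np.exp(-4.0))

    def test_conventional_exponent_flag(self):
        assert gaussian_flux(0.004, TABLE_PULSE, conventional=True) == pytest.approx(
            np.exp(-2.0)
        )

    def test_pulse_train_linearity(self):
        p = TABLE_PULSE
        t = 0.0015
        assert pulse_train_flux(t, [p]) == pytest.approx(gaussian_flux(t, p))
        assert pulse_train_flux(t, [p, p]) == pytest.approx(2 * gaussian_flux(t, p))

    def test_separated_pulses_independent_at_peaks(self):
        a = StimulusPulse(1.0, 0.002, 0.001)
        b = StimulusPulse(1.0, 0.050, 0.001)
        val = pulse_train_flux(a.t_star, [a, b])
        assert val == pytest.approx(a.phi0, abs=np.exp(-((0.048 / 0.001) ** 2)) + 1e-15)

    def test_empty_train_rejected(self):
        with pytest.raises(DomainError):
            pulse_train_flux(0.0, [])


class TestFracIntegral:
    @pytest.mark.parametrize("H", [0.3, 0.5, 0.8, 1.0])
    def test_constant_flux_closed_form(self, H):
        t_grid = np.linspace(0.0, 1.0, 257)
        flux = FluxSeries(t_grid, np.ones_like(t_grid))
        for t in (0.1, 0.5, 1.0):
            assert frac_integral(flux, H, t) == pytest.approx(
                t**H / gamma(H + 1.0), rel=1e-12
            )

    def test_zero_flux(self):
        t_grid = np.linspace(0.0, 1.0, 64)
        flux = FluxSeries(t_grid, np.zeros_like(t_grid))
        assert frac_integral(flux, 0.7, 0.8) == 0.0

    @pytest.mark.parametrize("H", [0.5, 0.6, 0.7, 0.8, 0.9, 1.0])
    @pytest.mark.parametrize("t", [0.01, 0.1, 0.5])
    def test_gaussian_pulse_matches_quadrature_oracle(self, H, t):
        flux = dense_flux(TABLE_PULSE, 0.5, 1e-5)
        ours = frac_integral(flux, H, t)
        ref = quad_oracle(TABLE_PULSE, H, t)
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_convergence_order_of_product_integration(self):
        H, t = 0.7, 0.1
        ref = quad_oracle(TABLE_PULSE, H, t)
        errs = []
        for dt in (4e-5, 2e-5):
            errs.append(abs(frac_integral(dense_flux(TABLE_PULSE, 0.2, dt), H, t) - ref))
        order = np.log2(errs[0] / errs[1])
        assert order >= 1.5

    def test_causality(self):
        """The value at t must not depend on flux after t."""
        t_grid = np.linspace(0.0, 1.0, 513)
        base = gaussian_flux(t_grid, StimulusPulse(1.0, 0.3, 0.05))
        # tamper strictly beyond the grid node bracketing t, since the
        # piecewise-linear reconstruction on the final sub-interval uses
        # the immediately following sample
        tampered = base.copy()
        tampered[t_grid > 0.61] += 5.0
        v1 = frac_integral(FluxSeries(t_grid, base), 0.7, 0.6)
        v2 = frac_integral(FluxSeries(t_grid, tampered), 0.7, 0.6)
        assert v1 == pytest.approx(v2, rel=1e-14)

    def test_domain_and_support_errors(self):
        t_grid = np.linspace(0.0, 1.0, 64)
        flux = FluxSeries(t_grid, np.ones_like(t_grid))
        with pytest.raises(DomainError):
            frac_integral(flux, 1.5, 0.5)
        with pytest.raises(ExtrapolationError):
            frac_integral(flux, 0.5, 2.0)


class TestFractionalResponse:
    def test_zero_flux_returns_initial_value(self):
        t_grid = np.linspace(0.0, 1.0, 64)
        flux = FluxSeries(t_grid, np.zeros_like(t_grid))
        assert fractional_response(flux, 0.7, 1e-4, 1e-3, V0=-3.2, t=0.9) == -3.2

    def test_constant_flux_half_closed_form(self):
        # H = 1/2: V = V0 + 2 φ0 sqrt(t) / (sqrt(π) sqrt(D_eff)); τ drops out
        phi0, d_eff, t = 2.5, 1.3e-4, 0.49
        t_grid = np.linspace(0.0, 1.0, 513)
        flux = FluxSeries(t_grid, np.full_like(t_grid, phi0))
        got = fractional_response(flux, 0.5, d_eff, tau=0.123, V0=1.0, t=t)
        want = 1.0 + 2.0 * phi0 * np.sqrt(t) / (np.sqrt(np.pi) * np.sqrt(d_eff))
        assert got == pytest.approx(want, rel=1e-12)

    def test_literal_variant_prefactor(self):
        t_grid = np.linspace(0.0, 1.0, 129)
        flux = FluxSeries(t_grid, np.ones_like(t_grid))
        h, d_eff, tau = 0.8, 2e-5, 1e-3
        derived = fractional_response(flux, h, d_eff, tau, 0.0, 0.5)
        literal = fractional_response(flux, h, d_eff, tau, 0.0, 0.5, variant="literal")
        assert literal == pytest.approx(derived / np.sqrt(d_eff), rel=1e-12)

    @pytest.mark.parametrize("a", [0.0, 0.5, 3.0])
    def test_linearity_in_the_flux(self, a):
        t_grid = np.linspace(0.0, 0.5, 257)
        base = gaussian_flux(t_grid, StimulusPulse(1.0, 0.1, 0.02))
        v0 = 2.0
        ref = fractional_response(FluxSeries(t_grid, base), 0.8, 1e-4, 1e-3, v0, 0.4)
        scaled = fractional_response(
            FluxSeries(t_grid, a * base), 0.8, 1e-4, 1e-3, v0, 0.4
        )
        assert scaled - v0 == pytest.approx(a * (ref - v0), abs=1e-12)

    def test_invalid_diffusivity(self):
        t_grid = np.linspace(0.0, 1.0, 64)
        flux = FluxSeries(t_grid, np.ones_like(t_grid))
        with pytest.raises(DomainError):
            fractional_response(flux, 0.7, 0.0, 1e-3, 0.0, 0.5)


class TestGrowthExponent:
    @pytest.mark.parametrize("H", [0.5, 0.8, 1.0])
    def test_power_law_growth(self, H):
        assert growth_exponent(H) == pytest.approx(H, abs=1e-6)


@pytest.fixture(scope="module")
def prestim():
    return simulate_fgn(256, 0.9, scale=2.0, seed=7)


class TestPredictSignal:

    def test_zero_amplitude_pulse_stays_flat(self, prestim):
        cfg = ModelConfig(
            pulses=(StimulusPulse(phi0=0.0),), V0=1.5, H_policy="prestim"
        )
        pred = predict_signal(prestim, cfg, 1.0)
        assert np.all(pred.series.values == 1.5)
        assert np.all((pred.H_trajectory.H_values >= 0) & (pred.H_trajectory.H_values <= 1))

    def test_fixed_persistent_h_reproduces_direct_evaluation(self, prestim):
        """Under a persistent fixed H the signed increments telescope, so
        the loop's peak equals a single direct model call at that time."""
        cfg = ModelConfig(H_policy="fixed", fixed_H=0.8, seed=1)
        pred = predict_signal(prestim, cfg, 1.0)
        assert len(pred.series) == 257  # V0 plus 256 steps
        assert pred.series.values[0] == cfg.V0
        k = int(np.argmax(pred.series.values))
        t_k = k * cfg.dt
        flux = sample_flux(cfg.pulses, 1.0, min(cfg.dt, cfg.pulses[0].sigma / 8))
        d_eff = effective_diffusivity(t_k, 0.8, cfg.params, reflect=False)
        direct = fractional_response(
            flux, 0.8, d_eff, cfg.params.tau, cfg.V0, t_k
        )
        assert pred.series.values[k] == pytest.approx(direct, abs=1e-9)

    def test_free_running_prediction_has_evoked_morphology(self, prestim):
        """A persistent fGn prestim plus the reference pulse yields a
        response the feature extractor detects: a positive deflection
        above the 5 μV band followed by a negative-going rebound."""
        cfg = ModelConfig(H_policy="trailing", seed=2)
        pred = predict_signal(prestim, cfg, 1.0)
        feats = detect_response(pred.series)
        assert feats.detected
        assert pred.series.value_at(feats.p_time_s) >= 5.0
        assert feats.n_time_s > feats.p_time_s
        assert feats.peak_to_peak_uV > 0

    def test_boundedness_and_finiteness(self, prestim):
        cfg = ModelConfig(H_policy="trailing", seed=3)
        pred = predict_signal(prestim, cfg, 1.0)
        assert np.all(np.isfinite(pred.series.values))
        assert np.all(pred.D_eff_trajectory >= 0)

    def test_deterministic_under_seed(self, prestim):
        cfg = ModelConfig(H_policy="trailing", seed=11)
        a = predict_signal(prestim, cfg, 0.25)
        b = predict_signal(prestim, cfg, 0.25)
        assert np.array_equal(a.series.values, b.series.values)

    def test_fixed_policy_requires_h(self):
        with pytest.raises(DomainError):
            ModelConfig(H_policy="fixed")
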