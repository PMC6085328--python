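"""Multi-exponential fitting: recovery, component naming, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flowflash import (AmbiguousComponentError, ExponentialComponent,
                       FitFailureError, FitResult, Trace, amplitude_change,
                       bootstrap_fit, component_amplitude,
                       fit_multiexponential, level_difference)


def make_trace(taus, amps, offset=0.0, sigma=0.0, seed=0,
               t=None, wavelength=445.0):
    if t is None:
        t = np.logspace(-6, -2, 400)
    y = np.full_like(t, offset)
    for a, tau in zip(amps, taus):
        y = y + a * np.exp(-t / tau)
    if sigma > 0:
        y = y + np.random.default_rng(seed).normal(0, sigma, t.shape)
    return Trace(wavelength=wavelength, times=t, values=y)


IDEAL_TAUS = (30e-6, 100e-6, 5e-3)
IDEAL_AMPS = (80.0, 10.0, 70.0)


class TestFitRecovery:
    def test_noise_free_single_exponential(self):
        trace = make_trace([5e-3], [1.0])
        fit = fit_multiexponential(trace, 1, seed=0)
        assert fit.converged
        assert fit.components[0].tau == pytest.approx(5e-3, rel=1e-3)
        assert fit.components[0].amplitude == pytest.approx(1.0, rel=1e-3)

    def test_noise_free_three_exponential(self):
        trace = make_trace(IDEAL_TAUS, IDEAL_AMPS)
        fit = fit_multiexponential(trace, 3, seed=0)
        for comp, tau, amp in zip(fit.components, IDEAL_TAUS, IDEAL_AMPS):
            assert comp.tau == pytest.approx(tau, rel=0.01)
            assert comp.amplitude == pytest.approx(amp, rel=0.01)

    def test_noisy_slowest_tau_over_seeds(self):
        # σ = 2% of the total amplitude; the mean recovered slow τ stays
        # within 10% of the generating 5 ms
        total = sum(IDEAL_AMPS)
        slow = [fit_multiexponential(
                    make_trace(IDEAL_TAUS, IDEAL_AMPS, sigma=0.02 * total,
                               seed=s),
                    3, seed=s).components[-1].tau
                for s in range(10)]
        assert np.mean(slow) == pytest.approx(5e-3, rel=0.10)

    def test_residual_sd_approaches_noise_sigma(self):
        sigma = 0.02 * sum(IDEAL_AMPS)
        fit = fit_multiexponential(
            make_trace(IDEAL_TAUS, IDEAL_AMPS, sigma=sigma, seed=11), 3,
            seed=11)
        assert fit.residual_sd == pytest.approx(sigma, rel=0.15)

    @settings(derandomize=True, max_examples=12, deadline=None)
    @given(log_tau=st.floats(-5.0, -2.5), a=st.floats(0.2, 5.0),
           offset=st.floats(-0.5, 0.5))
    def test_round_trip_within_model_class(self, log_tau, a, offset):
        tau = 10.0 ** log_tau
        trace = make_trace([tau], [a], offset=offset)
        fit = fit_multiexponential(trace, 1, seed=1, restarts=8)
        assert fit.components[0].tau == pytest.approx(tau, rel=0.01)
        assert fit.components[0].amplitude == pytest.approx(a, rel=0.01)
        assert fit.offset == pytest.approx(offset, abs=1e-3 * max(1.0, abs(a)))

    def test_seed_determinism_bit_exact(self):
        trace = make_trace(IDEAL_TAUS, IDEAL_AMPS, sigma=0.05, seed=4)
        f1 = fit_multiexponential(trace, 3, seed=99)
        f2 = fit_multiexponential(trace, 3, seed=99)
        assert f1.taus.tolist() == f2.taus.tolist()
        assert f1.amplitudes.tolist() == f2.amplitudes.tolist()
        assert f1.offset == f2.offset

    def test_constant_trace_fails(self):
        t = np.logspace(-6, -2, 100)
        trace = Trace(wavelength=445.0, times=t, values=np.ones_like(t))
        with pytest.raises(FitFailureError):
            fit_multiexponential(trace, 1, seed=0)

    def test_too_few_points_fails(self):
        t = np.logspace(-6, -2, 8)
        trace = Trace(wavelength=445.0, times=t, values=np.exp(-t / 1e-3))
        with pytest.raises(FitFailureError):
            fit_multiexponential(trace, 2, seed=0)

    def test_pre_flash_and_blanked_points_excluded(self):
        t = np.concatenate([[-1e-4, -1e-5], np.logspace(-6, -2, 200)])
        y = 1.0 * np.exp(-np.clip(t, 0, None) / 5e-3)
        y[0] = y[1] = 123.0          # pre-flash garbage
        y[5] = np.nan                # blanked artifact sample
        trace = Trace(wavelength=445.0, times=t, values=y)
        fit = fit_multiexponential(trace, 1, seed=0)
        assert fit.components[0].tau == pytest.approx(5e-3, rel=0.01)
        assert fit.n_points == 199


class TestComponentNaming:
    def fit(self):
        return FitResult(
            components=(ExponentialComponent(80.0, 30e-6),
                        ExponentialComponent(70.0, 5e-3)),
            offset=0.0, rss=0.0, residual_sd=0.0, n_points=100,
            converged=True)

    def test_unique_match_by_tau_window(self):
        assert component_amplitude(self.fit(), 5e-3) == 70.0
        assert component_amplitude(self.fit(), 30e-6) == 80.0

    def test_no_match_is_ambiguous(self):
        with pytest.raises(AmbiguousComponentError):
            component_amplitude(self.fit(), 1.0)

    def test_multiple_matches_are_ambiguous(self):
        with pytest.raises(AmbiguousComponentError):
            component_amplitude(self.fit(), 4e-4, tolerance_factor=20.0)


class TestAmplitudeChange:
    @pytest.mark.parametrize("ref, test, expected", [
        (70.0, 60.0, 100.0 / 7.0),
        (3.5, 3.5, 0.0),
        (100.0, 110.0, -10.0),
    ])
    def test_percent_decrease_convention(self, ref, test, expected):
        assert amplitude_change(ref, test) == pytest.approx(expected)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            amplitude_change(0.0, 1.0)


class TestHelpers:
    def test_level_difference_reads_phase_amplitude(self):
        # a clean 5-ms phase of amplitude 0.07 on a 0.01 baseline
        t = np.logspace(-6, -1, 500)
        trace = Trace(wavelength=445.0, times=t,
                      values=0.01 + 0.07 * np.exp(-t / 5e-3))
        drop = level_difference(trace, (1e-5, 1e-4), (5e-2, 1e-1))
        assert drop == pytest.approx(0.07, rel=0.02)

    def test_bootstrap_reports_spread(self):
        trace = make_trace([5e-3], [1.0], sigma=0.01, seed=2)
        fit = fit_multiexponential(trace, 1, seed=2)
        boot = bootstrap_fit(trace, fit, n_boot=20, seed=3, restarts=6)
        assert boot["n_successful"] > 10
        assert 0 < boot["tau_sd"][0] < 1e-3

    def test_fit_result_json_round_trip(self, tmp_path):
        trace = make_trace(IDEAL_TAUS, IDEAL_AMPS, sigma=0.02, seed=5)
        fit = fit_multiexponential(trace, 3, seed=5)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        back = FitResult.from_json(path)
        assert back.taus.tolist() == fit.taus.tolist()
        assert back.offset == fit.offset
        assert back.converged
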