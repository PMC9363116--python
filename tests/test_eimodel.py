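"""Rate model, analytic correlations, LIF network, GCaMP kernel."""

import numpy as np
import pytest
from dataclasses import replace

from pupdyn import (
    LIFParams,
    RateModelParams,
    analytic_rate_correlation,
    gcamp_convolve,
    lif_single_neuron_rate,
    model_pmth,
    simulate_lif,
    simulate_rate,
    sweep_JEI,
)
from pupdyn.eimodel import pulse_response_metrics


class TestGcampConvolve:
    def test_impulse_response_is_exponential(self):
        x = np.zeros(100)
        x[0] = 1.0
        y = gcamp_convolve(x, tau_s=2.0, fs=10.0)
        t = np.arange(100) / 10.0
        assert np.allclose(y, np.exp(-t / 2.0))

    def test_constant_steady_state(self):
        y = gcamp_convolve(np.ones(500), tau_s=2.0, fs=10.0)
        kernel_sum = np.exp(-np.arange(100) / 20.0).sum()
        assert y[-1] == pytest.approx(kernel_sum, rel=1e-3)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(200), rng.random(200)
        lhs = gcamp_convolve(2 * a + 3 * b)
        rhs = 2 * gcamp_convolve(a) + 3 * gcamp_convolve(b)
        assert np.allclose(lhs, rhs)


class TestSimulateRate:
    def test_pulse_relaxation_time_constant(self):
        """With J = 0 and no noise, the E rate relaxes exponentially with
        time constant tau_E after a pulse ends (closed-form check)."""
        p = RateModelParams(
            J_EE=0, J_EI=0, J_IE=0, J_II=0, noise_sigma=0.0,
            tau_E=0.5, pulse_amp=1.0, pulse_amp_I=0.0, pulse_dur_s=1.0,
            T_s=20.0, dt=0.002,
        )
        sim = simulate_rate(p, pulse_times=[5.0])
        i0 = int(round(6.5 / p.dt))  # after the pulse offset at t = 6 s
        i1 = i0 + int(round(p.tau_E / p.dt))
        baseline = p.I_ext_E
        ratio = (sim.rates[i1, 0] - baseline) / (sim.rates[i0, 0] - baseline)
        assert ratio == pytest.approx(np.exp(-1.0), rel=0.02)

    def test_weak_vs_strong_jei_undershoot(self):
        """Weak inhibition relaxes without undershoot; strong inhibition
        overshoots below baseline after the pulse."""
        pulses = [30.0, 60.0, 90.0]
        results = {}
        for jei in (0.0, 2.0):
            p = RateModelParams(J_EI=jei, noise_sigma=0.0, T_s=120.0)
            sim = simulate_rate(p, pulse_times=pulses)
            bins, curve, baseline = model_pmth(sim)
            peak, trough = pulse_response_metrics(curve, bins, baseline)
            results[jei] = (peak, trough)
        assert results[0.0][1] < 0.05 * results[0.0][0]  # no real undershoot
        assert results[2.0][1] > 0.5 * results[2.0][0]

    def test_seed_reproducibility(self):
        p = RateModelParams(T_s=10.0, seed=5)
        assert np.array_equal(simulate_rate(p).rates, simulate_rate(p).rates)

    def test_unstable_regime_raises(self):
        p = RateModelParams(J_EE=5.0, J_EI=0.0, noise_sigma=0.0, T_s=20.0)
        with pytest.raises((RuntimeError, ValueError)):
            simulate_rate(p, pulse_times=[1.0])


class TestAnalyticCorrelation:
    def test_decoupled_cross_correlation_zero(self):
        p = RateModelParams(J_EE=0, J_EI=0, J_IE=0, J_II=0)
        ana = analytic_rate_correlation(p)
        assert np.max(np.abs(ana["EI"])) < 1e-10
        assert ana["EE"][np.argmin(np.abs(ana["lags"]))] == pytest.approx(1.0)

    def test_decoupled_autocorrelation_is_filtered_ou(self):
        """Without coupling each population is an OU process; before GCaMP
        filtering its autocorrelation is exp(-|tau|/tau_eff).  The filtered
        curve must match the same closed form pushed through the kernel."""
        p = RateModelParams(J_EE=0, J_EI=0, J_IE=0, J_II=0, tau_E=0.5)
        ana = analytic_rate_correlation(p, gcamp_tau_s=1e-6)  # negligible kernel
        lags = ana["lags"]
        assert np.allclose(ana["EE"], np.exp(-np.abs(lags) / p.tau_E), atol=5e-3)

    def test_unstable_jacobian_rejected(self):
        p = RateModelParams(J_EE=5.0, J_EI=0.0)
        with pytest.raises(ValueError):
            analytic_rate_correlation(p)

    def test_jei_deepens_positive_lag_minimum(self):
        """The I->E correlogram minimum at positive lags deepens monotonically
        as inhibition strengthens."""
        mins = []
        for jei in (0.5, 1.0, 2.0):
            ana = analytic_rate_correlation(RateModelParams(J_EI=jei))
            pos = ana["lags"] > 0
            mins.append(ana["IE"][pos].min())
        assert mins[0] > mins[1] > mins[2]


class TestSimulateLIF:
    def test_subthreshold_no_spikes(self):
        p = LIFParams(N_E=10, N_I=0, C_EE=0, C_EI=0, C_IE=0, C_II=0,
                      ext_mean_E=0.5, ext_sigma=0.0, T_s=5.0)
        sim = simulate_lif(p)
        assert sim.active_frac.sum() == 0.0

    def test_single_neuron_closed_form_rate(self):
        """Constant suprathreshold current: simulated rate matches
        1/(tau_ref + tau_m ln((I - V_reset)/(I - V_th))) within 2%."""
        I = 1.5
        p = LIFParams(N_E=1, N_I=0, C_EE=0, C_EI=0, C_IE=0, C_II=0,
                      ext_mean_E=I, ext_sigma=0.0, dt=0.0001, T_s=20.0,
                      bin_s=0.001)
        sim = simulate_lif(p)
        measured = sim.active_frac[:, 0].sum() / p.T_s
        predicted = lif_single_neuron_rate(p, I)
        assert measured == pytest.approx(predicted, rel=0.02)

    def test_seed_reproducibility(self):
        p = LIFParams(N_E=50, N_I=10, C_EE=5, C_EI=2, C_IE=5, C_II=2, T_s=5.0, seed=9)
        s1, s2 = simulate_lif(p), simulate_lif(p)
        assert np.array_equal(s1.active_frac, s2.active_frac)

    def test_in_degree_exceeding_population_rejected(self):
        with pytest.raises(ValueError):
            LIFParams(N_I=10, C_EI=50)


class TestSweepJEI:
    def test_monotone_metrics_and_flip(self):
        table = sweep_JEI(RateModelParams(), [0.0, 0.5, 2.0], n_pulses=8,
                          pulse_interval_s=25.0)
        u = table["undershoot_depth"].to_numpy()
        c = table["corr_min_pos_lag"].to_numpy()
        assert u[0] <= u[1] <= u[2] and u[2] > 0.2
        assert c[0] >= c[1] >= c[2] and c[2] < -0.1
        # the response flips from peak-dominated to trough-dominated
        assert table["peak_response"][0] > table["undershoot_depth"][0]
        assert table["undershoot_depth"][2] > table["peak_response"][2]

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            sweep_JEI(RateModelParams(), [1.0])

    def test_model_pmth_periodic_average_equals_single(self):
        """Identical periodic responses average to a single response."""
        p = RateModelParams(J_EI=1.0, noise_sigma=0.0, T_s=200.0)
        pulses = [50.0, 90.0, 130.0, 170.0]
        sim = simulate_rate(p, pulse_times=pulses)
        bins, curve, _ = model_pmth(sim, window_s=20.0)
        stride = int(round(0.1 / p.dt))
        signal = gcamp_convolve(sim.rates[::stride, 0], 2.0, 10.0)
        o = int(round(90.0 * 10))
        single = signal[o - 100 : o + 101]
        assert np.allclose(curve, single, rtol=0, atol=1e-4)
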