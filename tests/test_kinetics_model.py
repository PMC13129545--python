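"""Mass-action model simulations and two-stage fitting.

The independent oracle is an explicit fixed-step RK4 integrator (0.01-s
steps, numba-compiled) over the same reaction network, written against the
reaction scheme rather than the package's adaptive-integrator path.
"""

import numpy as np
import pytest
from numba import njit

from caskinetics.errors import DomainError, FitError
from caskinetics.kinetics_model import (AssayMix, RateParameters,
                                        default_times_min, effective_kd,
                                        fit_stage1, fit_stage2, rates_from_dict,
                                        rates_to_dict, ratio_profile,
                                        simulate_model1, simulate_model2)


@njit(cache=False)
def _rk4_oracle(y0, kon_t, k2, kon_b, koff_b, dt, n_steps, save_every):
    """Fixed-step RK4 for [C, T, A, R, P, B, D]; rates in nM/s units."""
    n_save = n_steps // save_every + 1
    out = np.empty((n_save, 7))
    y = y0.copy()
    out[0] = y
    k = np.empty(7)
    ys = np.empty(7)
    acc = np.empty(7)
    saved = 1
    for step in range(1, n_steps + 1):
        for stage in range(4):
            if stage == 0:
                ys[:] = y
            elif stage == 1 or stage == 2:
                ys[:] = y + 0.5 * dt * k
            else:
                ys[:] = y + dt * k
            C, T, A, R, P, B, D = ys
            v_act = kon_t * C * T
            v_cl = k2 * A * R
            v_bg = kon_b * C * B - koff_b * D
            k[0] = -v_act - v_bg
            k[1] = -v_act
            k[2] = v_act
            k[3] = -v_cl
            k[4] = v_cl
            k[5] = -v_bg
            k[6] = v_bg
            if stage == 0:
                acc[:] = k
            elif stage == 3:
                acc[:] = acc + k
            else:
                acc[:] = acc + 2.0 * k
        y = y + (dt / 6.0) * acc
        if step % save_every == 0:
            out[saved] = y
            saved += 1
    return out


def rk4_signal(rates, mix, minutes, dt=0.01):
    save_every = int(round(60.0 / dt))
    n_steps = int(round(minutes[-1] * 60.0 / dt))
    out = _rk4_oracle(mix.initial_state(), rates.k_on_t * 1e-9, rates.k2 * 1e-9,
                      rates.k_on_b * 1e-9, rates.k_off_b, dt, n_steps, save_every)
    return out[np.asarray(minutes, dtype=int), 4]


class TestModel1:
    def test_initial_signal_is_zero(self, reference_rates, standard_mix):
        trace = simulate_model1(reference_rates, standard_mix)
        assert trace.signal[0] == 0.0

    def test_long_time_limit_exhausts_reporter(self, reference_rates, standard_mix):
        times = np.linspace(0, 6000.0, 200)  # 100 h
        trace = simulate_model1(reference_rates, standard_mix, times)
        assert trace.signal[-1] == pytest.approx(200.0, abs=0.2)

    def test_agrees_with_fixed_step_oracle(self, reference_rates, standard_mix):
        minutes = np.array([0.0, 10, 60, 180, 480, 960])
        trace = simulate_model1(reference_rates, standard_mix, default_times_min())
        oracle = rk4_signal(reference_rates, AssayMix(), minutes)
        ours = trace.signal[minutes.astype(int)]
        assert np.max(np.abs(ours - oracle)) < 0.1

    def test_rejects_negative_inputs(self):
        with pytest.raises(DomainError):
            RateParameters(k_on_t=-1.0, k2=1.0)
        with pytest.raises(DomainError):
            AssayMix(target_0=-0.1)


class TestModel2:
    def test_zero_background_reduces_to_model1(self, reference_rates, standard_mix):
        t1 = simulate_model1(reference_rates, standard_mix)
        t2 = simulate_model2(reference_rates, standard_mix)  # background_0 = 0
        assert np.max(np.abs(t1.signal - t2.signal)) < 1e-9

    def test_fast_unbinding_converges_to_model1(self, reference_rates, background_mix):
        weak = RateParameters(reference_rates.k_on_t, reference_rates.k2,
                              k_on_b=reference_rates.k_on_b, k_off_b=1e4)
        t1 = simulate_model1(reference_rates, AssayMix())
        t2 = simulate_model2(weak, background_mix)
        assert np.max(np.abs(t1.signal - t2.signal)) < 0.05

    def test_background_slows_half_time(self, reference_rates, standard_mix, background_mix):
        t1 = simulate_model1(reference_rates, standard_mix)
        t2 = simulate_model2(reference_rates, background_mix)

        def t05(trace):
            return trace.times[np.argmax(trace.signal > 0.5 * trace.signal.max())]

        assert t05(t2) > t05(t1)

    def test_agrees_with_fixed_step_oracle(self, reference_rates, background_mix):
        minutes = np.array([0.0, 10, 60, 180, 480, 960])
        trace = simulate_model2(reference_rates, background_mix, default_times_min())
        oracle = rk4_signal(reference_rates, background_mix, minutes)
        assert np.max(np.abs(trace.signal[minutes.astype(int)] - oracle)) < 0.1


class TestConservationAndMonotonicity:
    def test_conservation_laws(self, reference_rates, background_mix):
        trace = simulate_model2(reference_rates, background_mix,
                                rtol=1e-10, atol=1e-9, full_state=True)
        C, T, A, R, P, B, D = trace.full_state
        assert np.max(np.abs(R + P - 200.0)) < 1e-6
        assert np.max(np.abs(C + A + D - 60.0)) < 1e-6
        assert np.max(np.abs(T + A - 6.7)) < 1e-6
        assert np.max(np.abs(B + D - 200.0)) < 1e-6

    def test_signal_monotone_and_species_nonnegative(self, reference_rates, background_mix):
        trace = simulate_model2(reference_rates, background_mix, full_state=True)
        assert np.all(np.diff(trace.signal) >= -1e-9)
        assert trace.full_state.min() >= -1e-9

    def test_half_time_orderings_on_parameter_grid(self, reference_rates):
        """t0.5 rises with background concentration and k_ON,B, falls with k_OFF,B."""
        times = default_times_min()

        def t05(rates, background_0):
            tr = simulate_model2(rates, AssayMix(background_0=background_0), times)
            return tr.times[np.argmax(tr.signal > 0.5 * tr.signal.max())]

        r = reference_rates
        by_conc = [t05(r, b) for b in (0.0, 100.0, 200.0, 400.0)]
        assert all(a <= b for a, b in zip(by_conc, by_conc[1:]))
        by_kon = [t05(RateParameters(r.k_on_t, r.k2, kb, r.k_off_b), 200.0)
                  for kb in (1e5, 1.1e6, 1e7)]
        assert all(a <= b for a, b in zip(by_kon, by_kon[1:]))
        by_koff = [t05(RateParameters(r.k_on_t, r.k2, r.k_on_b, kf), 200.0)
                   for kf in (0.0026, 0.026, 0.26)]
        assert all(a >= b for a, b in zip(by_koff, by_koff[1:]))


class TestEffectiveKd:
    def test_reference_rates_give_24_nM(self, reference_rates):
        kd = effective_kd(reference_rates)
        assert kd * 1e9 == pytest.approx(23.6, abs=0.05)
        assert round(kd * 1e9) == 24

    def test_definition_limits(self):
        assert effective_kd(RateParameters(1e4, 1e4, k_on_b=1e6, k_off_b=0.0)) == 0.0
        assert effective_kd(RateParameters(1e4, 1e4, k_on_b=2.0, k_off_b=2.0)) == 1.0
        with pytest.raises(DomainError):
            effective_kd(RateParameters(1e4, 1e4, k_on_b=0.0, k_off_b=1.0))


class TestStage1Fit:
    def test_noiseless_recovery_below_one_percent(self, reference_rates, standard_mix):
        trace = simulate_model1(reference_rates, standard_mix)
        fit = fit_stage1(trace, standard_mix, seed=0)
        assert abs(fit.params.k_on_t - reference_rates.k_on_t) / reference_rates.k_on_t < 0.01
        assert abs(fit.params.k2 - reference_rates.k2) / reference_rates.k2 < 0.01

    def test_recovery_under_gaussian_noise(self, reference_rates, standard_mix, minute_grid):
        rng = np.random.default_rng(7)
        trace = simulate_model1(reference_rates, standard_mix, minute_grid)
        noisy = type(trace)(times=trace.times,
                            signal=trace.signal + rng.normal(0, 2.0, trace.signal.size))
        fit = fit_stage1(noisy, standard_mix, seed=0, early_stop_rms=0.0)
        assert abs(fit.params.k_on_t - reference_rates.k_on_t) / reference_rates.k_on_t < 0.05
        assert abs(fit.params.k2 - reference_rates.k2) / reference_rates.k2 < 0.05

    def test_flat_trace_raises_fit_error(self, standard_mix, minute_grid):
        class Flat:
            times = minute_grid
            signal = np.zeros_like(minute_grid)
        with pytest.raises(FitError):
            fit_stage1(Flat(), standard_mix)


class TestStage2Fit:
    def test_noiseless_recovery_below_one_percent(self, reference_rates, background_mix):
        trace = simulate_model2(reference_rates, background_mix)
        stage1 = RateParameters(reference_rates.k_on_t, reference_rates.k2)
        fit = fit_stage2(trace, stage1, background_mix, seed=0)
        assert abs(fit.params.k_on_b - reference_rates.k_on_b) / reference_rates.k_on_b < 0.01
        assert abs(fit.params.k_off_b - reference_rates.k_off_b) / reference_rates.k_off_b < 0.01

    def test_background_free_trace_pushes_kon_b_to_lower_bound(self, reference_rates,
                                                               standard_mix, background_mix):
        trace = simulate_model1(reference_rates, standard_mix)
        stage1 = RateParameters(reference_rates.k_on_t, reference_rates.k2)
        fit = fit_stage2(trace, stage1, background_mix, n_starts=4, seed=0)
        # no sequestration signature: fitted binding is negligible
        assert fit.params.k_on_b * 200e-9 < fit.params.k_off_b or fit.params.k_on_b < 1e3

    def test_ratio_profile_valley_is_shallow_near_truth(self, reference_rates, background_mix):
        """Along constant K_D,eff the residual rises slowly away from the
        generating k_ON,B — the documented identifiability structure."""
        trace = simulate_model2(reference_rates, background_mix)
        stage1 = RateParameters(reference_rates.k_on_t, reference_rates.k2)
        kd = effective_kd(reference_rates)
        grid = np.array([0.5, 1.0, 2.0]) * reference_rates.k_on_b
        rms = ratio_profile(trace, stage1, kd, grid, background_mix)
        assert rms[1] == pytest.approx(0.0, abs=1e-4)
        assert rms[0] > rms[1] and rms[2] > rms[1]
        assert max(rms) < 1.0  # the valley: off-scale factor 2 moves RMS < 1 nM


class TestParameterIO:
    def test_json_roundtrip(self, reference_rates):
        doc = rates_to_dict(reference_rates)
        assert doc["units"]["k_off_b"] == "s^-1"
        assert rates_from_dict(doc) == reference_rates
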