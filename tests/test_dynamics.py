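"""Forward simulators: closed forms, reductions, invariants, oracle checks."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from paindyn import (
    FirstOrderParams,
    PowerLawParams,
    RatingTrace,
    SecondOrderParams,
    SimState,
    StimulusTrace,
    TwoTauParams,
    predict_linear,
    predict_threshold_linear,
    ramp_forcing,
    simulate_first_order,
    simulate_power_law,
    simulate_second_order,
    simulate_two_tau,
)
from paindyn.stimuli import supra_threshold_intervals


def test_ramp_forcing_threshold_behavior():
    assert ramp_forcing(45.0, 45.0) == 0.0
    assert ramp_forcing(40.0, 45.0) == 0.0
    assert ramp_forcing(47.0, 45.0) == 2.0


class TestFirstOrder:
    def test_step_response_asymptote_and_closed_form(self, step_stimulus):
        # constant drive 2 °C above threshold: P(t) = A tau dT (1 - e^{-t/tau})
        p = FirstOrderParams(A=1.0, tau=5.0, T0=45.0)
        out = simulate_first_order(p, step_stimulus)
        analytic = 10.0 * (1.0 - np.exp(-out.t / 5.0))
        assert np.abs(out.P - analytic).max() < 1e-6
        assert out.P[int(5.0 / 0.1)] == pytest.approx(10.0 * (1 - np.exp(-1)), abs=1e-9)
        assert out.P[-1] == pytest.approx(10.0, abs=1e-3)

    def test_pure_decay_below_threshold(self):
        t = 0.1 * np.arange(200)
        stim = StimulusTrace(t, np.full(200, 44.0))
        p = FirstOrderParams(A=1.0, tau=5.0, T0=45.0)
        out = simulate_first_order(p, stim, P0=8.0)
        np.testing.assert_allclose(out.P, 8.0 * np.exp(-t / 5.0), atol=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            FirstOrderParams(A=1.0, tau=0.0, T0=45.0)
        with pytest.raises(ValueError):
            FirstOrderParams(A=1.0, tau=np.inf, T0=45.0)


class TestPowerLaw:
    def test_delta_one_reduces_exactly_to_first_order(self, step_stimulus, complex_stim):
        fo = FirstOrderParams(A=1.2, tau=5.0, T0=45.0)
        pl = PowerLawParams(A=1.2, tau=5.0, T0=45.0, delta=1.0)
        for stim in (step_stimulus, complex_stim):
            a = simulate_first_order(fo, stim)
            b = simulate_power_law(pl, stim)
            assert np.abs(a.P - b.P).max() <= 1e-12

    def test_delta_zero_gives_constant_drive_steady_state(self, step_stimulus):
        p = PowerLawParams(A=1.0, tau=5.0, T0=45.0, delta=0.0)
        out = simulate_power_law(p, step_stimulus)
        assert out.P[-1] == pytest.approx(5.0, abs=1e-3)  # A·tau

    def test_delta_two_steady_state(self):
        t = 0.1 * np.arange(600)
        stim = StimulusTrace(t, np.full(600, 48.0))  # T0 + 3
        p = PowerLawParams(A=1.0, tau=5.0, T0=45.0, delta=2.0)
        out = simulate_power_law(p, stim)
        assert out.P[-1] == pytest.approx(45.0, rel=1e-3)  # A·tau·9

    def test_negative_delta_safe_at_threshold(self):
        t = 0.1 * np.arange(100)
        stim = StimulusTrace(t, np.full(100, 45.0))  # exactly T0
        p = PowerLawParams(A=1.0, tau=5.0, T0=45.0, delta=-0.5)
        out = simulate_power_law(p, stim)
        assert np.all(out.P == 0.0)


class TestTwoTau:
    def test_degenerate_reduction_to_first_order(self, complex_stim):
        two = TwoTauParams(A_fast=1.2, tau_fast=5.0, A_slow=0.0, tau_slow=30.0, T0=45.0)
        fo = FirstOrderParams(A=1.2, tau=5.0, T0=45.0)
        a = simulate_two_tau(two, complex_stim)
        b = simulate_first_order(fo, complex_stim)
        np.testing.assert_allclose(a.P, b.P, atol=1e-12)

    def test_equal_time_constants_rejected(self):
        with pytest.raises(ValueError):
            TwoTauParams(A_fast=1.0, tau_fast=5.0, A_slow=1.0, tau_slow=5.0, T0=45.0)

    def test_step_steady_state_superposes(self):
        t = 0.1 * np.arange(2000)  # 200 s: lets the slow pool settle
        stim = StimulusTrace(t, np.full(2000, 47.0))
        two = TwoTauParams(A_fast=1.0, tau_fast=2.0, A_slow=0.5, tau_slow=20.0, T0=45.0)
        out = simulate_two_tau(two, stim)
        expect = (1.0 * 2.0 + 0.5 * 20.0) * 2.0
        assert out.P[-1] == pytest.approx(expect, rel=0.01)


class TestSecondOrder:
    def test_silent_without_forcing_or_state(self, default_second):
        t = 0.1 * np.arange(300)
        stim = StimulusTrace(t, np.full(300, 35.0))
        out = simulate_second_order(default_second, stim)
        assert np.all(out.P == 0.0)

    def test_fine_step_oracle_on_complex_stimulus(self, default_second, complex_stim):
        coarse = simulate_second_order(default_second, complex_stim, max_step=0.05)
        fine = simulate_second_order(default_second, complex_stim, max_step=0.0005)
        assert np.abs(coarse.P - fine.P).max() < 0.1

    def test_fall_faster_than_rise(self, default_second):
        from paindyn.stimuli import ProtocolSpec, offset_rate_series
        tr = offset_rate_series([8.0], ProtocolSpec())[0]
        out = simulate_second_order(default_second, tr)
        pk = out.P.max()
        ipk = int(out.P.argmax())
        i10 = np.argmax(out.P >= 0.1 * pk)
        i90 = np.argmax(out.P >= 0.9 * pk)
        j90 = ipk + np.argmax(out.P[ipk:] <= 0.9 * pk)
        j10 = ipk + np.argmax(out.P[ipk:] <= 0.1 * pk)
        rise = out.t[i90] - out.t[i10]
        fall = out.t[j10] - out.t[j90]
        assert fall < rise

    def test_nonuniform_grid_rejected(self, default_second):
        with pytest.raises(Exception):
            simulate_second_order(default_second,
                                  StimulusTrace(np.array([0, 1, 2.5]), np.full(3, 40.0)))

    @given(
        k1=st.floats(0.0, 3.0),
        gamma=st.floats(0.0, 3.0),
        k2=st.floats(0.0, 0.5),
        Tc=st.floats(-2.0, 5.0),
        P0=st.floats(0.0, 50.0),
    )
    def test_non_negativity_holds_for_admissible_params(self, complex_stim,
                                                        k1, gamma, k2, Tc, P0):
        params = SecondOrderParams(k1=k1, gamma=gamma, k2=k2, T0=45.0, Tc=Tc)
        out = simulate_second_order(params, complex_stim, init=SimState(P=P0))
        assert np.all(out.P >= 0.0)
        assert np.all(np.isfinite(out.P))


class TestSubThresholdSilence:
    """If T stays below threshold and the state starts at zero, every model is silent."""

    def test_all_models_silent(self, complex_stim):
        sub = StimulusTrace(complex_stim.t, np.minimum(complex_stim.T, 44.0))
        T0 = 45.0
        outs = [
            simulate_first_order(FirstOrderParams(1.0, 5.0, T0), sub),
            simulate_power_law(PowerLawParams(1.0, 5.0, T0, 2.0), sub),
            simulate_two_tau(TwoTauParams(1.0, 2.0, 1.0, 20.0, T0), sub),
            simulate_second_order(SecondOrderParams(0.4, 0.8, 0.08, T0, 0.5), sub),
            predict_threshold_linear(sub, T0),
        ]
        for out in outs:
            assert np.all(out.P == 0.0)


class TestNullPredictors:
    def test_linear_follows_temperature(self, complex_stim):
        out = predict_linear(complex_stim)
        np.testing.assert_array_equal(out.P, complex_stim.T)

    def test_threshold_linear_low_threshold_equals_shifted_linear(self, complex_stim):
        out = predict_threshold_linear(complex_stim, 30.0)
        np.testing.assert_allclose(out.P, complex_stim.T - 30.0)

    def test_threshold_above_max_is_all_zero(self, complex_stim):
        out = predict_threshold_linear(complex_stim, 60.0)
        assert np.all(out.P == 0.0)

    def test_threshold_46_active_only_during_pulses(self, complex_stim):
        out = predict_threshold_linear(complex_stim, 46.0)
        active = RatingTrace(out.t, out.P)
        intervals = supra_threshold_intervals(complex_stim, 46.0 + 1e-9)
        mask = np.zeros(len(out.P), dtype=bool)
        for a, b in intervals:
            mask |= (out.t >= a) & (out.t <= b)
        assert np.all(out.P[~mask] == 0.0)
        assert len(intervals) == 3


class TestMonotonicity:
    def test_first_order_plateau_rating_increases_with_temperature(self):
        p = FirstOrderParams(A=1.0, tau=5.0, T0=45.0)
        finals = []
        for temp in (45.5, 46.5, 47.5, 49.0):
            t = 0.1 * np.arange(600)
            out = simulate_first_order(p, StimulusTrace(t, np.full(600, temp)))
            finals.append(out.P[-1])
        assert np.all(np.diff(finals) > 0)
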