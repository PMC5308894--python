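"""Submembrane-Ca2+ shift state: kinetics, interpolation, calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cav3sim import CaShiftState, EffectiveGating, cav33_model, effective_params, update_shift
from cav3sim.ca_dynamics import DEFAULT_K_OFF, DEFAULT_K_ON
from cav3sim.fitting import half_time
from cav3sim.protocols import VoltageProtocol, peak_amplitude, simulate, step
from cav3sim.synthetic import DEFAULT_ATTENUATION_ALPHA, SyntheticConfig, make_train_dataset


class TestShiftKinetics:
    def test_bapta_clamps_shift_at_zero(self):
        state = CaShiftState(s=0.4, buffer="bapta")
        out = update_shift(state, inward_ca_current=-500.0, dt=100.0)
        assert out.s == 0.0

    def test_zero_ca_clamps_shift_at_zero(self):
        state = CaShiftState(s=0.4, ca_carried=False)
        assert update_shift(state, -500.0, 100.0).s == 0.0

    def test_outward_current_carries_no_flux(self):
        state = CaShiftState(s=0.0)
        assert update_shift(state, +500.0, 1000.0).s == pytest.approx(0.0, abs=1e-9)

    def test_zero_flux_decay_half_time(self):
        state = CaShiftState(s=1.0, k_off=DEFAULT_K_OFF)
        t_half = math.log(2.0) / DEFAULT_K_OFF
        assert update_shift(state, 0.0, t_half).s == pytest.approx(0.5, rel=1e-9)

    def test_constant_flux_monotone_approach_to_fixed_point(self):
        k_on, k_off, f = 1e-4, DEFAULT_K_OFF, 2.0
        s_ss = k_on * f / (k_on * f + k_off)
        state = CaShiftState(s=0.0, k_on=k_on, k_off=k_off, flux_norm=1.0)
        prev = 0.0
        for _ in range(50):
            state = update_shift(state, -f, 1000.0)
            assert prev <= state.s <= s_ss + 1e-12
            prev = state.s
        assert state.s == pytest.approx(s_ss, rel=1e-3)

    def test_larger_cumulative_charge_larger_steady_state(self):
        finals = []
        for f in (0.5, 1.0, 2.0, 4.0):
            state = CaShiftState(k_on=1e-4, flux_norm=1.0)
            for _ in range(200):
                state = update_shift(state, -f, 1000.0)
            finals.append(state.s)
        assert np.all(np.diff(finals) > 0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0.0, max_value=1e4),  # |flux| (pA)
                st.floats(min_value=0.0, max_value=1e5),  # dt (ms)
            ),
            min_size=1,
            max_size=40,
        ),
        st.floats(min_value=0.0, max_value=1.0),
    )
    def test_shift_bounded_on_random_trains(self, events, s0):
        state = CaShiftState(s=s0, k_on=1e-3, flux_norm=10.0)
        for f, dt in events:
            state = update_shift(state, -f, dt)
            assert 0.0 <= state.s <= 1.0


class TestEffectiveGating:
    def test_endpoints_match_printed_sets(self, rest, shifted, v_grid):
        e0 = EffectiveGating(0.0, rest, shifted)
        e1 = EffectiveGating(1.0, rest, shifted)
        for fn in ("m_inf", "h_inf", "tau_m", "tau_h"):
            np.testing.assert_allclose(getattr(e0, fn)(v_grid), getattr(rest, fn)(v_grid))
            np.testing.assert_allclose(getattr(e1, fn)(v_grid), getattr(shifted, fn)(v_grid))

    def test_midpoint_blends_function_values(self, rest, shifted):
        e = effective_params(CaShiftState(s=0.5), rest, shifted)
        assert e.h_inf(-70.0) == pytest.approx((0.39626 + 0.09797) / 2.0, rel=1e-3)

    def test_blend_is_valuewise_not_coefficientwise(self, rest, shifted):
        e = EffectiveGating(0.5, rest, shifted)
        v = -75.0
        assert e.tau_h(v) == pytest.approx(
            0.5 * rest.tau_h(v) + 0.5 * shifted.tau_h(v), rel=1e-12
        )


class TestTrainAndCalibration:
    def test_no_ca_train_flat_after_settling(self, clean_config):
        cfg = clean_config.model_copy(update={"ca_carried": False})
        _, df = make_train_dataset(cfg, n_sweeps=40)
        amps = df["amp"].to_numpy()
        # the sweep-1 -> 2 drop is short-term inactivation; afterwards flat
        assert np.abs(amps[-1] / amps[1] - 1.0) < 0.01
        assert df["s"].max() == 0.0

    def test_bapta_train_flat_after_settling(self, clean_config):
        cfg = clean_config.model_copy(update={"buffer": "bapta"})
        _, df = make_train_dataset(cfg, n_sweeps=40)
        amps = df["amp"].to_numpy()
        assert np.abs(amps[-1] / amps[1] - 1.0) < 0.01

    def test_calibration_reproduces_default_rates(self, calibrated_rates):
        k_on, k_off = calibrated_rates
        assert k_off == pytest.approx(math.log(2.0) / 20_000.0, rel=1e-9)
        assert k_on == pytest.approx(DEFAULT_K_ON, rel=0.05)

    def test_calibrated_onset_half_time(self, calibrated_rates, model):
        k_on, k_off = calibrated_rates
        proto = VoltageProtocol(-100.0, [step(450.0, -30.0)], sweep_repeats=90,
                                inter_sweep_interval=550.0, sample_dt=0.2)
        shift = CaShiftState(k_on=k_on, k_off=k_off)
        trs = simulate(proto, model, shift=shift, normalize_flux=True)
        amps = np.array(
            [peak_amplitude(tr)[0] * (1 - DEFAULT_ATTENUATION_ALPHA * tr.meta["s_start"])
             for tr in trs]
        )
        t = np.arange(len(amps)) * 1000.0
        onset = half_time(t[1:], amps[1:])
        assert onset == pytest.approx(18_000.0, rel=0.10)

    def test_recovery_half_time_from_k_off(self, calibrated_rates):
        # amplitude recovery at zero flux tracks s decay: half-time ~ ln2/k_off
        _, k_off = calibrated_rates
        assert math.log(2.0) / k_off == pytest.approx(20_000.0, rel=0.10)

    def test_doubling_k_on_speeds_onset(self, calibrated_rates, model):
        k_on, k_off = calibrated_rates

        def onset(k):
            proto = VoltageProtocol(-100.0, [step(450.0, -30.0)], sweep_repeats=60,
                                    inter_sweep_interval=550.0, sample_dt=0.2)
            trs = simulate(proto, model, shift=CaShiftState(k_on=k, k_off=k_off),
                           normalize_flux=True)
            amps = np.array([peak_amplitude(tr)[0] for tr in trs])
            return half_time(np.arange(1, len(amps)) * 1000.0, amps[1:])

        assert onset(2.0 * k_on) < onset(k_on)
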