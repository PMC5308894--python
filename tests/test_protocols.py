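"""Protocol integration: exact gate stepping, trace metrics, convergence."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cav3sim import (
    CAV33_REST,
    CaShiftState,
    Trace,
    VoltageProtocol,
    cav33_model,
    charge_integral,
    gate_step,
    peak_amplitude,
    simulate,
    step,
)
from cav3sim.fitting import MonoExpDecay
from cav3sim.gating import GateState
from cav3sim.protocols import MAX_TOTAL_DURATION_MS, ramp


class TestGateStep:
    def test_zero_dt_is_identity(self, rest):
        st = GateState(0.3, 0.6)
        assert gate_step(st, -30.0, 0.0, rest) == st

    def test_long_dt_reaches_steady_state(self, rest):
        st = gate_step(GateState(0.0, 1.0), -30.0, 1e7, rest)
        target = rest.steady_state(-30.0)
        assert st.m == pytest.approx(target.m, abs=1e-12)
        assert st.h == pytest.approx(target.h, abs=1e-12)

    def test_semigroup_composition(self, rest):
        # n sub-steps at constant voltage == one step over the total interval
        st_once = gate_step(GateState(0.01, 0.95), -45.0, 120.0, rest)
        st_comp = GateState(0.01, 0.95)
        for _ in range(16):
            st_comp = gate_step(st_comp, -45.0, 7.5, rest)
        assert st_comp.m == pytest.approx(st_once.m, abs=1e-12)
        assert st_comp.h == pytest.approx(st_once.h, abs=1e-12)

    def test_matches_adaptive_ode_oracle(self, rest):
        """Exponential-Euler trajectory vs a high-accuracy generic ODE solve."""
        v = -30.0
        y0 = rest.steady_state(-100.0)

        def rhs(t, y):
            m, h = y
            return [
                (rest.m_inf(v) - m) / rest.tau_m(v),
                (rest.h_inf(v) - h) / rest.tau_h(v),
            ]

        ts = np.linspace(0.0, 450.0, 91)[1:]
        sol = solve_ivp(rhs, (0.0, 450.0), list(y0), rtol=1e-10, atol=1e-14,
                        dense_output=True)
        ref = sol.sol(ts)
        st = GateState(*y0)
        t_prev = 0.0
        for k, t in enumerate(ts):
            st = gate_step(st, v, t - t_prev, rest)
            t_prev = t
            assert st.m == pytest.approx(ref[0, k], rel=1e-6)
            assert st.h == pytest.approx(ref[1, k], rel=1e-6)


class TestSimulate:
    def test_constant_protocol_gives_flat_trace(self, model):
        proto = VoltageProtocol(-100.0, [step(200.0, -100.0)], sample_dt=0.1)
        tr = simulate(proto, model)[0]
        assert np.ptp(tr.i) < 1e-9 * max(1.0, np.abs(tr.i).max())

    def test_test_pulse_decay_follows_tau_h(self, model, rest):
        proto = VoltageProtocol(-100.0, [step(450.0, -30.0)], sample_dt=0.05)
        tr = simulate(proto, model)[0]
        amp, t_peak = peak_amplitude(tr)
        mask = (tr.t >= t_peak) & (tr.t <= 470.0)
        fit = MonoExpDecay(tr.t[mask], tr.i[mask]).fit()
        assert fit.converged
        assert fit.tau == pytest.approx(rest.tau_h(-30.0), rel=0.1)

    def test_peak_converged_in_dt(self, model):
        amps = []
        for dt in (0.1, 0.05):
            proto = VoltageProtocol(-100.0, [step(450.0, -30.0)], sample_dt=dt)
            amps.append(peak_amplitude(simulate(proto, model)[0])[0])
        assert abs(amps[1] - amps[0]) / amps[1] < 1e-3

    def test_shifted_kinetics_reduce_peak_at_full_availability(self, model):
        # at holding -100 both states are fully available; the residual
        # amplitude difference is purely kinetic
        proto = VoltageProtocol(-100.0, [step(450.0, -30.0)], sample_dt=0.05)
        a_rest = peak_amplitude(simulate(proto, cav33_model("rest"))[0])[0]
        a_shift = peak_amplitude(simulate(proto, cav33_model("shifted"))[0])[0]
        assert 0.84 < a_shift / a_rest < 0.90

    def test_gates_bounded_on_mixed_protocol(self, model):
        proto = VoltageProtocol(
            -90.0,
            [step(50.0, -30.0), ramp(100.0, -30.0, 20.0), step(50.0, -120.0)],
            sample_dt=0.05,
        )
        shift = CaShiftState(s=0.3)
        tr = simulate(proto, model, shift=shift, normalize_flux=True)[0]
        # reconstruct bound check from recorded s and current: s must stay
        # within [0,1]; current must be finite everywhere
        assert np.all(np.isfinite(tr.i))
        assert np.all((tr.s >= 0.0) & (tr.s <= 1.0))

    def test_bapta_shift_equals_no_shift(self, model):
        proto = VoltageProtocol(-100.0, [step(450.0, -30.0)],
                                sweep_repeats=3, inter_sweep_interval=530.0,
                                sample_dt=0.1)
        plain = simulate(proto, model)
        bapta = simulate(proto, model, shift=CaShiftState(buffer="bapta"),
                         normalize_flux=True)
        for a, b in zip(plain, bapta):
            np.testing.assert_allclose(a.i, b.i, rtol=0, atol=1e-12)

    def test_duration_cap_rejected(self, model):
        with pytest.raises(ValueError):
            VoltageProtocol(-100.0, [step(MAX_TOTAL_DURATION_MS + 1, -30.0)])


class TestTraceMetrics:
    def _flat_trace(self, value=0.0, n=1000, dt=0.1):
        t = np.arange(1, n + 1) * dt
        meta = {"segments": [("pre", 0.0, 20.0), ("step0", 20.0, t[-1])]}
        return Trace(t, np.full(n, -100.0), np.full(n, value), meta)

    def test_pure_baseline_has_zero_amplitude(self):
        tr = self._flat_trace(value=-3.0)
        amp, _ = peak_amplitude(tr)
        assert amp == pytest.approx(0.0, abs=1e-12)

    def test_amplitude_scales_with_trace(self, model):
        proto = VoltageProtocol(-100.0, [step(100.0, -30.0)], sample_dt=0.1)
        tr = simulate(proto, model)[0]
        scaled = Trace(tr.t, tr.v_cmd, 2.5 * tr.i, tr.meta)
        a1, _ = peak_amplitude(tr)
        a2, _ = peak_amplitude(scaled)
        assert a2 / a1 == pytest.approx(2.5, rel=1e-9)

    def test_rectangular_pulse_charge(self):
        tr = self._flat_trace(n=3000)
        tr.i[(tr.t > 100.0) & (tr.t <= 200.0)] = -10.0
        q = charge_integral(tr, window=(100.0, 200.0), baseline_window=(5.0, 20.0))
        assert q == pytest.approx(1000.0, rel=2e-3)

    def test_charge_additive_over_disjoint_windows(self, model):
        proto = VoltageProtocol(-100.0, [step(200.0, -30.0)], sample_dt=0.1)
        tr = simulate(proto, model)[0]
        base = (10.0, 20.0)
        total = charge_integral(tr, window=(20.0, 220.0), baseline_window=base)
        left = charge_integral(tr, window=(20.0, 120.0), baseline_window=base)
        right = charge_integral(tr, window=(120.0, 220.0), baseline_window=base)
        assert left + right == pytest.approx(total, rel=5e-3)

    def test_empty_window_raises(self):
        tr = self._flat_trace()
        with pytest.raises(ValueError):
            peak_amplitude(tr, window=(1e4, 2e4))

    def test_csv_roundtrip(self, model, tmp_path):
        proto = VoltageProtocol(-100.0, [step(50.0, -30.0)], sample_dt=0.1)
        tr = simulate(proto, model)[0]
        path = tmp_path / "trace.csv"
        tr.to_csv(path)
        back = Trace.from_csv(path)
        np.testing.assert_allclose(back.i, tr.i, rtol=1e-12)
        assert back.meta["holding_v"] == -100.0
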