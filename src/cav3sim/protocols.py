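"""Voltage-clamp command waveforms, gating-ODE integration and trace metrics.

The integrator uses the exact exponential relaxation of each HH gate over
every sample interval (exponential Euler), which is exact for constant-
voltage segments; ramps and arbitrary waveforms are treated as piecewise
constant at the sample resolution.  When the submembrane-Ca2+ shift state
is engaged, the effective gating curves are re-blended every sub-step from
the channel's own instantaneous Ca2+ flux.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ca_dynamics import CaShiftState, EffectiveGating, _advance_s
from .channel import ChannelModel
from .gating import GateState, GatingParams

__all__ = [
    "ProtocolSegment",
    "VoltageProtocol",
    "Trace",
    "step",
    "ramp",
    "waveform",
    "gate_step",
    "simulate",
    "standard_flux_norm",
    "peak_amplitude",
    "charge_integral",
]

#: Guard against accidentally unbounded protocols (ms of simulated time).
MAX_TOTAL_DURATION_MS = 4_000_000.0


@dataclass(frozen=True)
class ProtocolSegment:
    """One piece of a command waveform: a step, a linear ramp, or samples."""

    kind: str  # "step" | "ramp" | "waveform"
    duration: float  # ms
    v_start: float = 0.0
    v_end: float = 0.0
    samples: Optional[Tuple[np.ndarray, np.ndarray]] = None  # (t, v), t from 0

    def __post_init__(self) -> None:
        if self.kind not in ("step", "ramp", "waveform"):
            raise ValueError("segment kind must be 'step', 'ramp' or 'waveform'")
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
        if self.kind == "waveform":
            if self.samples is None:
                raise ValueError("waveform segment requires samples")
            t, v = self.samples
            if len(t) != len(v) or len(t) < 2:
                raise ValueError("waveform samples must be two equal-length series")
            if np.any(np.diff(t) <= 0):
                raise ValueError("waveform sample times must be strictly increasing")

    def voltages(self, dt: float) -> np.ndarray:
        """Command voltage at the end of each dt sub-interval."""
        n = max(1, int(round(self.duration / dt)))
        t = (np.arange(n) + 1.0) * dt
        if self.kind == "step":
            return np.full(n, self.v_start)
        if self.kind == "ramp":
            return self.v_start + (self.v_end - self.v_start) * t / self.duration
        ts, vs = self.samples
        return np.interp(t, ts, vs, left=vs[0], right=vs[-1])


def step(duration: float, v: float) -> ProtocolSegment:
    return ProtocolSegment("step", duration, v_start=v, v_end=v)


def ramp(duration: float, v_start: float, v_end: float) -> ProtocolSegment:
    return ProtocolSegment("ramp", duration, v_start=v_start, v_end=v_end)


def waveform(t: Sequence[float], v: Sequence[float]) -> ProtocolSegment:
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    return ProtocolSegment("waveform", float(t[-1] - t[0]), samples=(t - t[0], v))


@dataclass(frozen=True)
class VoltageProtocol:
    """A multi-sweep voltage-clamp protocol.

    ``pre_ms`` milliseconds at the holding potential are recorded at the
    start of every sweep so trace metrics have a baseline window.  The
    inter-sweep interval is integrated analytically at the holding
    potential (not sampled), keeping slow trains cheap.
    """

    holding_v: float
    segments: Tuple[ProtocolSegment, ...]
    sweep_repeats: int = 1
    inter_sweep_interval: float = 0.0
    sample_dt: float = 0.05
    pre_ms: float = 20.0
    equilibration: str = "analytic"

    def __init__(self, holding_v, segments, sweep_repeats=1, inter_sweep_interval=0.0,
                 sample_dt=0.05, pre_ms=20.0, equilibration="analytic"):
        object.__setattr__(self, "holding_v", float(holding_v))
        object.__setattr__(self, "segments", tuple(segments))
        object.__setattr__(self, "sweep_repeats", int(sweep_repeats))
        object.__setattr__(self, "inter_sweep_interval", float(inter_sweep_interval))
        object.__setattr__(self, "sample_dt", float(sample_dt))
        object.__setattr__(self, "pre_ms", float(pre_ms))
        object.__setattr__(self, "equilibration", equilibration)
        if self.sample_dt <= 0:
            raise ValueError("sample_dt must be positive")
        if self.sweep_repeats < 1:
            raise ValueError("sweep_repeats must be >= 1")
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        total = self.sweep_repeats * (
            self.pre_ms + sum(s.duration for s in self.segments) + self.inter_sweep_interval
        )
        if total > MAX_TOTAL_DURATION_MS:
            raise ValueError(
                f"protocol duration {total:.0f} ms exceeds the cap {MAX_TOTAL_DURATION_MS:.0f} ms"
            )

    @property
    def sweep_duration(self) -> float:
        return self.pre_ms + sum(s.duration for s in self.segments)

    def segment_windows(self) -> List[Tuple[str, float, float]]:
        """(label, t_start, t_end) per recorded segment, pre segment first."""
        out = [("pre", 0.0, self.pre_ms)]
        t = self.pre_ms
        for i, seg in enumerate(self.segments):
            out.append((f"{seg.kind}{i}", t, t + seg.duration))
            t += seg.duration
        return out


@dataclass
class Trace:
    """A simulated (or synthetic noisy) sweep: time, command voltage, current."""

    t: np.ndarray
    v_cmd: np.ndarray
    i: np.ndarray
    meta: dict = field(default_factory=dict)
    s: Optional[np.ndarray] = None  # Ca2+-shift state per sample, when engaged

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.v_cmd) == len(self.i)):
            raise ValueError("t, v_cmd and i must have equal length")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_ms": self.t, "v_mV": self.v_cmd, "i_pA": self.i})
        if self.s is not None:
            df["shift_s"] = self.s
        return df

    def to_csv(self, path) -> None:
        """Write the trace as CSV plus a JSON metadata sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        path.with_suffix(".json").write_text(json.dumps(self.meta, indent=1, default=str))

    @classmethod
    def from_csv(cls, path) -> "Trace":
        path = Path(path)
        df = pd.read_csv(path)
        meta = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        s = df["shift_s"].to_numpy() if "shift_s" in df else None
        return cls(df["time_ms"].to_numpy(), df["v_mV"].to_numpy(), df["i_pA"].to_numpy(), meta, s)

    def plot(self, ax=None):  # pragma: no cover - convenience only
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.t, self.i, lw=0.8)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("current (pA)")
        return ax


def gate_step(state: GateState, v: float, dt: float, params: GatingParams) -> GateState:
    """Exact relaxation of both gates over dt at constant voltage."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if dt == 0:
        return state
    m_inf = float(params.m_inf(v))
    h_inf = float(params.h_inf(v))
    em = math.exp(-dt / float(params.tau_m(v)))
    eh = math.exp(-dt / float(params.tau_h(v)))
    return GateState(m_inf + (state.m - m_inf) * em, h_inf + (state.h - h_inf) * eh)


def _simulate_segment_fixed(
    v_seq: np.ndarray, is_const: bool, m0: float, h0: float, dt: float,
    params: GatingParams, model: ChannelModel,
):
    """Integrate a segment with fixed gating parameters (no shift).

    Constant-voltage segments use the closed-form relaxation, vectorized.
    """
    if is_const:
        v = float(v_seq[0])
        m_inf = float(params.m_inf(v))
        h_inf = float(params.h_inf(v))
        tm = float(params.tau_m(v))
        th = float(params.tau_h(v))
        tt = (np.arange(len(v_seq)) + 1.0) * dt
        m = m_inf + (m0 - m_inf) * np.exp(-tt / tm)
        h = h_inf + (h0 - h_inf) * np.exp(-tt / th)
        i = model.current(v, m, h)
        return np.asarray(i, dtype=float), float(m[-1]), float(h[-1])
    # varying voltage: precompute curves, loop the affine recurrence
    minf = np.asarray(params.m_inf(v_seq), dtype=float)
    hinf = np.asarray(params.h_inf(v_seq), dtype=float)
    em = np.exp(-dt / np.asarray(params.tau_m(v_seq), dtype=float))
    eh = np.exp(-dt / np.asarray(params.tau_h(v_seq), dtype=float))
    n = len(v_seq)
    m_arr = np.empty(n)
    h_arr = np.empty(n)
    m, h = m0, h0
    for k in range(n):
        m = minf[k] + (m - minf[k]) * em[k]
        h = hinf[k] + (h - hinf[k]) * eh[k]
        m_arr[k] = m
        h_arr[k] = h
    i = model.current(v_seq, m_arr, h_arr)
    return np.asarray(i, dtype=float), m, h


def _simulate_segment_shift(
    v_seq: np.ndarray, is_const: bool, m0: float, h0: float, s0: float, dt: float,
    rest: GatingParams, shifted: GatingParams, model: ChannelModel, shift: CaShiftState,
):
    """Integrate a segment with the Ca2+-shift state coupled per sub-step."""
    n = len(v_seq)
    if is_const:
        v = float(v_seq[0])
        mr = float(rest.m_inf(v)); ms = float(shifted.m_inf(v))
        hr = float(rest.h_inf(v)); hs = float(shifted.h_inf(v))
        tmr = float(rest.tau_m(v)); tms = float(shifted.tau_m(v))
        thr = float(rest.tau_h(v)); ths = float(shifted.tau_h(v))
        mr_a = ms_a = hr_a = hs_a = None
    else:
        mr_a = np.asarray(rest.m_inf(v_seq)); ms_a = np.asarray(shifted.m_inf(v_seq))
        hr_a = np.asarray(rest.h_inf(v_seq)); hs_a = np.asarray(shifted.h_inf(v_seq))
        tmr_a = np.asarray(rest.tau_m(v_seq)); tms_a = np.asarray(shifted.tau_m(v_seq))
        thr_a = np.asarray(rest.tau_h(v_seq)); ths_a = np.asarray(shifted.tau_h(v_seq))
        drive_a = np.asarray(model.driving(v_seq), dtype=float)
    k_on, k_off = shift.k_on, shift.k_off
    active = shift.active
    fn = shift.flux_norm
    g = model.g_max
    p = model.exponent_p
    exp = math.exp
    i_arr = np.empty(n)
    s_arr = np.empty(n)
    m, h, s = m0, h0, s0
    if is_const:
        drive = float(model.driving(float(v_seq[0])))
    for k in range(n):
        if is_const:
            minf = mr + s * (ms - mr)
            hinf = hr + s * (hs - hr)
            tm = tmr + s * (tms - tmr)
            th = thr + s * (ths - thr)
            d = drive
        else:
            minf = mr_a[k] + s * (ms_a[k] - mr_a[k])
            hinf = hr_a[k] + s * (hs_a[k] - hr_a[k])
            tm = tmr_a[k] + s * (tms_a[k] - tmr_a[k])
            th = thr_a[k] + s * (ths_a[k] - thr_a[k])
            d = drive_a[k]
        m = minf + (m - minf) * exp(-dt / tm)
        h = hinf + (h - hinf) * exp(-dt / th)
        i = g * (m ** p) * h * d
        if active:
            f = -i / fn if i < 0.0 else 0.0
            s = _advance_s(s, f, k_on, k_off, dt)
        else:
            s = 0.0
        i_arr[k] = i
        s_arr[k] = s
    return i_arr, s_arr, m, h, s


def _holding_interval(m, h, s, v_hold, duration, model, shift, rest, shifted, n_chunks=8):
    """Analytic relaxation at holding between sweeps, with slow s decay.

    Only the phasic pulse flux drives the shift state; the standing
    (window) current at holding is neglected as a drive, so between sweeps
    s simply decays with k_off while the gates relax in a few chunks to
    follow the slowly changing effective curves.
    """
    if shift is None:
        st = gate_step(GateState(m, h), v_hold, duration, rest)
        return st.m, st.h, s
    dt_c = duration / n_chunks
    for _ in range(n_chunks):
        eff = EffectiveGating(s, rest, shifted)
        st = gate_step(GateState(m, h), v_hold, dt_c, eff)
        m, h = st.m, st.h
        s = 0.0 if not shift.active else _advance_s(s, 0.0, shift.k_on, shift.k_off, dt_c)
    return m, h, s


def standard_flux_norm(model: ChannelModel, sample_dt: float = 0.05) -> float:
    """Reference current amplitude for normalized Ca2+ flux.

    The resting-state peak of the standard paradigm (450 ms pulse to
    -30 mV from holding -100 mV) for this cell/model; all shift dynamics
    express their drive relative to it.
    """
    ref_proto = VoltageProtocol(-100.0, [step(450.0, -30.0)], sample_dt=sample_dt)
    ref_trace = simulate(ref_proto, model, shift=None)[0]
    ref_amp, _ = peak_amplitude(ref_trace)
    if ref_amp <= 0:
        raise ValueError("reference sweep has no inward current; cannot normalize flux")
    return ref_amp


def simulate(
    protocol: VoltageProtocol,
    model: ChannelModel,
    shift: Optional[CaShiftState] = None,
    normalize_flux: bool = False,
) -> List[Trace]:
    """Run a protocol through the channel model; one Trace per sweep.

    When ``shift`` is given the model must carry both endpoint parameter
    sets (``model.gating`` as resting, ``model.gating_shifted``); the shift
    state is threaded through sweeps and the inter-sweep intervals.  With
    ``normalize_flux`` the shift's ``flux_norm`` is set to the cell's
    standard reference amplitude -- the resting-state peak of a 450 ms
    pulse to -30 mV from holding -100 mV -- decoupling the feedback gain
    from the arbitrary conductance scale while preserving how Ca2+ entry
    scales with holding potential and waveform across paradigms.
    """
    dt = protocol.sample_dt
    rest = model.gating
    shifted = model.gating_shifted
    if shift is not None and shifted is None:
        raise ValueError("shift dynamics require model.gating_shifted")

    if shift is not None and normalize_flux:
        ref_amp = standard_flux_norm(model, sample_dt=dt)
        shift = CaShiftState(
            s=shift.s, k_on=shift.k_on, k_off=shift.k_off,
            buffer=shift.buffer, ca_carried=shift.ca_carried, flux_norm=ref_amp,
        )

    s = shift.s if shift is not None else 0.0
    eff0 = EffectiveGating(s, rest, shifted) if shift is not None else rest
    st = eff0.steady_state(protocol.holding_v)
    m, h = st.m, st.h

    windows = protocol.segment_windows()
    traces: List[Trace] = []
    for sweep in range(protocol.sweep_repeats):
        t_parts, v_parts, i_parts, s_parts = [], [], [], []
        t_off = 0.0
        s_start = s
        segs = [step(protocol.pre_ms, protocol.holding_v)] + list(protocol.segments)
        for seg in segs:
            v_seq = seg.voltages(dt)
            is_const = seg.kind == "step"
            if shift is None:
                i_seq, m, h = _simulate_segment_fixed(v_seq, is_const, m, h, dt, rest, model)
                s_seq = None
            else:
                i_seq, s_seq, m, h, s = _simulate_segment_shift(
                    v_seq, is_const, m, h, s, dt, rest, shifted, model, shift
                )
            n = len(v_seq)
            t_parts.append(t_off + (np.arange(n) + 1.0) * dt)
            v_parts.append(np.asarray(v_seq, dtype=float))
            i_parts.append(i_seq)
            if s_seq is not None:
                s_parts.append(s_seq)
            t_off += seg.duration
        meta = {
            "sweep": sweep,
            "holding_v": protocol.holding_v,
            "sample_dt": dt,
            "segments": windows,
            "s_start": s_start,
            "s_end": s,
        }
        traces.append(
            Trace(
                np.concatenate(t_parts),
                np.concatenate(v_parts),
                np.concatenate(i_parts),
                meta,
                np.concatenate(s_parts) if s_parts else None,
            )
        )
        if protocol.inter_sweep_interval > 0 and sweep < protocol.sweep_repeats - 1:
            m, h, s = _holding_interval(
                m, h, s, protocol.holding_v, protocol.inter_sweep_interval,
                model, shift, rest, shifted,
            )
    return traces


def _default_windows(trace: Trace):
    segs = trace.meta.get("segments")
    if not segs:
        raise ValueError("trace carries no segment metadata; pass windows explicitly")
    pre = next(w for w in segs if w[0] == "pre")
    test = segs[-1]
    baseline = (max(pre[1], pre[2] - 10.0), pre[2])
    window = (test[1], min(test[2] + 1.0, float(trace.t[-1])))
    return window, baseline


def peak_amplitude(
    trace: Trace,
    window: Optional[Tuple[float, float]] = None,
    baseline_window: Optional[Tuple[float, float]] = None,
) -> Tuple[float, float]:
    """Peak inward amplitude (positive pA) and its time within a window.

    The baseline is the mean current over ``baseline_window`` (default: the
    final 10 ms at holding before the first command segment); the peak is
    the extremal inward (negative-going) deflection after baseline
    subtraction, searched over ``window`` (default: the last command
    segment plus 1 ms).
    """
    if window is None or baseline_window is None:
        dflt_window, dflt_base = _default_windows(trace)
        window = window or dflt_window
        baseline_window = baseline_window or dflt_base
    bmask = (trace.t >= baseline_window[0]) & (trace.t <= baseline_window[1])
    wmask = (trace.t >= window[0]) & (trace.t <= window[1])
    if not np.any(wmask):
        raise ValueError("peak window contains no samples")
    if not np.any(bmask):
        raise ValueError("baseline window contains no samples")
    baseline = float(np.mean(trace.i[bmask]))
    d = trace.i[wmask] - baseline
    k = int(np.argmin(d))
    amp = max(0.0, -float(d[k]))
    return amp, float(trace.t[wmask][k])


def charge_integral(
    trace: Trace,
    window: Optional[Tuple[float, float]] = None,
    baseline_window: Optional[Tuple[float, float]] = None,
) -> float:
    """Trapezoidal integral of |baseline-subtracted current| (pA*ms)."""
    if window is None or baseline_window is None:
        dflt_window, dflt_base = _default_windows(trace)
        window = window or dflt_window
        baseline_window = baseline_window or dflt_base
    bmask = (trace.t >= baseline_window[0]) & (trace.t <= baseline_window[1])
    wmask = (trace.t >= window[0]) & (trace.t <= window[1])
    if not np.any(wmask):
        raise ValueError("integration window contains no samples")
    baseline = float(np.mean(trace.i[bmask])) if np.any(bmask) else 0.0
    d = np.abs(trace.i[wmask] - baseline)
    return float(np.trapezoid(d, trace.t[wmask]))
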