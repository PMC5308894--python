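"""Curve fitting and kinetic measurements for voltage-clamp analyses.

Model objects are built from data and expose ``fit()`` returning a results
object with estimates, standard errors, residual diagnostics and a
``summary()`` table:

* :class:`Boltzmann` -- steady-state inactivation/activation curves,
  ``I/Imax = A / (1 + exp(+-(Vm - V0.5)/k))``.
* :class:`MonoExpDecay` -- single-exponential inactivation decay or
  recovery, ``|I|(t) = A exp(-t/tau) + C``.  A single exponential is exact
  for an HH h-gate at constant voltage, making the estimator
  self-consistent with the channel model.

Fits are deterministic: initialization follows fixed, documented
heuristics and no randomness is involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from lmfit import Parameters, minimize

__all__ = [
    "Boltzmann",
    "BoltzmannResults",
    "MonoExpDecay",
    "ExpResults",
    "half_time",
    "recovery_ratio",
]


def _summary(title: str, rows, diagnostics) -> str:
    lines = [title, "=" * len(title)]
    for name, value, stderr in rows:
        se = f" +/- {stderr:.4g}" if stderr is not None and np.isfinite(stderr) else ""
        lines.append(f"{name:>12s}: {value:.6g}{se}")
    lines.append("-" * len(title))
    for k, v in diagnostics.items():
        lines.append(f"{k:>12s}: {v}")
    return "\n".join(lines)


@dataclass
class BoltzmannResults:
    """Fitted Boltzmann parameters with residual diagnostics."""

    v_half: float
    slope: float
    amplitude: float
    v_half_stderr: Optional[float]
    slope_stderr: Optional[float]
    rss: float
    converged: bool
    direction: str
    nfev: int = 0

    def predict(self, v) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        sign = 1.0 if self.direction == "inactivation" else -1.0
        return self.amplitude / (1.0 + np.exp(sign * (v - self.v_half) / self.slope))

    def summary(self) -> str:
        return _summary(
            f"Boltzmann fit ({self.direction})",
            [
                ("V0.5 (mV)", self.v_half, self.v_half_stderr),
                ("slope (mV)", self.slope, self.slope_stderr),
                ("amplitude", self.amplitude, None),
            ],
            {"rss": f"{self.rss:.3g}", "converged": self.converged, "nfev": self.nfev},
        )


class Boltzmann:
    """Boltzmann sigmoid model of normalized current vs membrane potential.

    ``direction="inactivation"`` fits a decreasing sigmoid
    ``A/(1+exp((Vm - V0.5)/k))``; ``"activation"`` the increasing mirror.
    Requires at least 5 points spanning the transition.
    """

    def __init__(self, v, y, direction: str = "inactivation"):
        self.v = np.asarray(v, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if direction not in ("inactivation", "activation"):
            raise ValueError("direction must be 'inactivation' or 'activation'")
        if len(self.v) != len(self.y):
            raise ValueError("v and y must have equal length")
        if len(self.v) < 5:
            raise ValueError("need at least 5 points to fit a Boltzmann")
        self.direction = direction

    def _residual(self, params, sign):
        vh = params["v_half"].value
        k = params["slope"].value
        a = params["amplitude"].value
        return a / (1.0 + np.exp(sign * (self.v - vh) / k)) - self.y

    def fit(self, v_half0: Optional[float] = None, slope0: float = 5.0) -> BoltzmannResults:
        sign = 1.0 if self.direction == "inactivation" else -1.0
        span = float(np.max(self.y) - np.min(self.y))
        amp0 = float(np.max(self.y)) if np.max(self.y) > 0 else 1.0
        if v_half0 is None:
            # voltage where y is nearest half of its span
            target = float(np.min(self.y)) + span / 2.0
            v_half0 = float(self.v[np.argmin(np.abs(self.y - target))])
        degenerate = span < 0.05 * max(amp0, 1e-12)
        params = Parameters()
        params.add("v_half", value=v_half0)
        params.add("slope", value=slope0, min=1e-6)
        params.add("amplitude", value=amp0)
        out = minimize(self._residual, params, args=(sign,), method="leastsq")
        rss = float(np.sum(out.residual**2))
        slope = float(out.params["slope"].value)
        converged = bool(out.success) and slope > 0 and not degenerate
        return BoltzmannResults(
            v_half=float(out.params["v_half"].value),
            slope=slope,
            amplitude=float(out.params["amplitude"].value),
            v_half_stderr=out.params["v_half"].stderr,
            slope_stderr=out.params["slope"].stderr,
            rss=rss,
            converged=converged,
            direction=self.direction,
            nfev=int(out.nfev),
        )


@dataclass
class ExpResults:
    """Fitted single-exponential parameters."""

    amplitude: float
    tau: float
    offset: float
    tau_stderr: Optional[float]
    rss: float
    converged: bool
    nfev: int = 0

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.amplitude * np.exp(-(t - t[0]) / self.tau) + self.offset

    def summary(self) -> str:
        return _summary(
            "Monoexponential fit",
            [
                ("amplitude", self.amplitude, None),
                ("tau (ms)", self.tau, self.tau_stderr),
                ("offset", self.offset, None),
            ],
            {"rss": f"{self.rss:.3g}", "converged": self.converged, "nfev": self.nfev},
        )


class MonoExpDecay:
    """Single-exponential decay of current magnitude from the peak.

    Built from a trace segment starting at the current peak; fits
    ``|I|(t) = A exp(-t/tau) + C``.  Time is referenced to the first
    sample.  Initialization: C = mean of the final 10% of samples,
    A = first sample minus C, tau = time for the magnitude to fall to
    1/e of A above C (fallback: one third of the segment).
    """

    def __init__(self, t, y):
        self.t = np.asarray(t, dtype=float)
        self.y = np.abs(np.asarray(y, dtype=float))
        if len(self.t) != len(self.y):
            raise ValueError("t and y must have equal length")
        if len(self.t) < 5:
            raise ValueError("need at least 5 points to fit an exponential")

    def _residual(self, params):
        a = params["amplitude"].value
        tau = params["tau"].value
        c = params["offset"].value
        return a * np.exp(-(self.t - self.t[0]) / tau) + c - self.y

    def fit(self) -> ExpResults:
        n_tail = max(1, len(self.y) // 10)
        c0 = float(np.mean(self.y[-n_tail:]))
        a0 = float(self.y[0] - c0)
        if a0 <= 0:
            a0 = max(float(np.max(self.y) - c0), 1e-12)
        target = c0 + a0 / np.e
        below = np.nonzero(self.y <= target)[0]
        tau0 = float(self.t[below[0]] - self.t[0]) if len(below) else float(
            (self.t[-1] - self.t[0]) / 3.0
        )
        tau0 = max(tau0, (self.t[1] - self.t[0]))
        params = Parameters()
        params.add("amplitude", value=a0)
        params.add("tau", value=tau0, min=1e-9)
        params.add("offset", value=c0)
        out = minimize(self._residual, params, method="leastsq")
        tau = float(out.params["tau"].value)
        return ExpResults(
            amplitude=float(out.params["amplitude"].value),
            tau=tau,
            offset=float(out.params["offset"].value),
            tau_stderr=out.params["tau"].stderr,
            rss=float(np.sum(out.residual**2)),
            converged=bool(out.success) and tau > 0,
            nfev=int(out.nfev),
        )


def half_time(t, y) -> float:
    """Linear-interpolated time at which y crosses its half-change point.

    The midpoint is halfway between the initial value ``y[0]`` and the
    asymptotic value ``y[-1]``; ``y`` must be approximately monotone.
    Raises ``ValueError`` when the series never crosses the midpoint.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) != len(y) or len(t) < 2:
        raise ValueError("need two equal-length series of at least 2 points")
    mid = 0.5 * (y[0] + y[-1])
    d = y - mid
    sign0 = np.sign(d[0]) if d[0] != 0 else np.sign(y[0] - y[-1])
    crossing = np.nonzero(sign0 * d <= 0)[0]
    crossing = crossing[crossing > 0]
    if len(crossing) == 0 or sign0 == 0:
        raise ValueError("series never crosses its half-change midpoint")
    k = int(crossing[0])
    y0, y1 = y[k - 1], y[k]
    if y1 == y0:
        return float(t[k])
    frac = (mid - y0) / (y1 - y0)
    return float(t[k - 1] + frac * (t[k] - t[k - 1]))


def recovery_ratio(p1_amp: float, p2_amp: float) -> float:
    """Paired-pulse recovery P2/P1; requires a positive first-pulse amplitude."""
    if p1_amp <= 0:
        raise ValueError("P1 amplitude must be positive")
    return p2_amp / p1_amp
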