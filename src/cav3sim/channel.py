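"""Whole-cell Cav3.3 current assembly: I = g_max * m^p * h * D(v).

The driving-force term D(v) is either the Goldman-Hodgkin-Katz (GHK)
constant-field flux for Ca2+ under asymmetric concentrations (default,
2 mM outside / 100 nM free inside) or a simple ohmic term (v - e_rev) for
testing.  All headline analyses in this package are amplitude *ratios*,
which are insensitive to the choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from .gating import CAV33_REST, CAV33_SHIFTED, GateState, GatingParams

__all__ = ["ChannelModel", "ghk_driving", "cav33_model"]

_Z_CA = 2.0
_F = 96485.332  # C/mol
_R = 8.314462  # J/(mol K)

ArrayLike = Union[float, np.ndarray]


def ghk_driving(
    v: ArrayLike, ca_out_mm: float = 2.0, ca_in_mm: float = 1e-4, temperature_c: float = 24.0
) -> ArrayLike:
    """GHK constant-field driving term for Ca2+ (arbitrary flux units x mM).

    Returns ``u * (ca_in - ca_out * exp(-u)) / (1 - exp(-u))`` with
    ``u = zFV/RT``.  Negative (inward) for physiological gradients at
    potentials below the Ca2+ reversal; the removable singularity at
    v = 0 is evaluated by its analytic limit ``ca_in - ca_out``.
    """
    v = np.asarray(v, dtype=float)
    rt = _R * (temperature_c + 273.15)
    u = _Z_CA * _F * (v * 1e-3) / rt
    small = np.abs(u) < 1e-9
    u_safe = np.where(small, 1.0, u)
    # 1 - exp(-u) computed as -expm1(-u) for stability near 0
    frac = u_safe / (-np.expm1(-u_safe))
    frac = np.where(small, 1.0, frac)
    out = frac * (ca_in_mm - ca_out_mm * np.exp(-np.where(small, 0.0, u)))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ChannelModel:
    """Full Cav3.3 channel description.

    Parameters
    ----------
    gating : GatingParams
        The active gating parameter set (resting by default).
    gating_shifted : GatingParams, optional
        The fully Ca2+-shifted endpoint set; required when the channel is
        simulated with the submembrane-Ca2+ feedback engaged.
    exponent_p : int
        Power on the activation gate (m^p * h); 2 by default, following
        the thalamic T-current convention.
    g_max : float
        Maximal conductance/permeability scale (arbitrary units, > 0).
        Inward current is negative by sign convention of the driving term.
    driving_force_mode : {"ghk", "ohmic"}
    ca_out, ca_in_nm : float
        External Ca2+ (mM) and internal free Ca2+ (nM) for the GHK term.
    e_rev : float
        Reversal potential (mV), ohmic mode only.
    temperature : float
        Recording temperature in Celsius, informational: the time-constant
        curves are taken as already valid at 24 C and ``q10_factor``
        defaults to 1 (no rescaling).
    """

    gating: GatingParams = field(default=CAV33_REST)
    gating_shifted: Optional[GatingParams] = None
    exponent_p: int = 2
    g_max: float = 1.0
    driving_force_mode: str = "ghk"
    ca_out: float = 2.0
    ca_in_nm: float = 100.0
    e_rev: float = 40.0
    temperature: float = 24.0
    q10_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.exponent_p < 1:
            raise ValueError("activation exponent must be >= 1")
        if self.g_max <= 0:
            raise ValueError("g_max must be positive")
        if self.ca_out <= 0 or self.ca_in_nm <= 0:
            raise ValueError("Ca2+ concentrations must be positive")
        if self.driving_force_mode not in ("ghk", "ohmic"):
            raise ValueError("driving_force_mode must be 'ghk' or 'ohmic'")

    def driving(self, v: ArrayLike) -> ArrayLike:
        if self.driving_force_mode == "ghk":
            return ghk_driving(v, self.ca_out, self.ca_in_nm * 1e-6, self.temperature)
        v = np.asarray(v, dtype=float)
        out = v - self.e_rev
        return float(out) if out.ndim == 0 else out

    def current(self, v: ArrayLike, m: ArrayLike, h: ArrayLike) -> ArrayLike:
        """Membrane current in pA-equivalent units, inward negative."""
        out = self.g_max * np.asarray(m) ** self.exponent_p * np.asarray(h) * self.driving(v)
        out = np.asarray(out)
        return float(out) if out.ndim == 0 else out

    def current_at(self, v: float, state: GateState) -> float:
        return float(self.current(v, state.m, state.h))

    def with_gating(self, gating: GatingParams) -> "ChannelModel":
        return replace(self, gating=gating)


def cav33_model(state: str = "rest", **kwargs) -> ChannelModel:
    """Convenience constructor for the two printed Cav3.3 states.

    ``state`` is ``"rest"`` or ``"shifted"``; both endpoint sets are always
    attached so the model can also be driven by the Ca2+-shift dynamics.
    """
    if state == "rest":
        gating = CAV33_REST
    elif state == "shifted":
        gating = CAV33_SHIFTED
    else:
        raise ValueError("state must be 'rest' or 'shifted'")
    return ChannelModel(gating=gating, gating_shifted=CAV33_SHIFTED, **kwargs)
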