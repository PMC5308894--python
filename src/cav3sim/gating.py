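"""Hodgkin-Huxley gating description of the Cav3.3 T-type calcium channel.

The channel is described by an activation gate ``m`` and an inactivation
gate ``h``, each with a voltage-dependent steady state (Boltzmann sigmoid)
and a voltage-dependent relaxation time constant of the bell-shaped form

    tau(v) = A + B / (exp((v + V1)/k1) + exp(-(v + V2)/k2))

Two parameter sets ship with the package as read-only JSON fixtures:

* ``cav3.3_rest`` -- gating measured at rest (low-frequency stimulation),
* ``cav3.3_shifted`` -- gating after 40 s of 1 Hz stimulation, i.e. the
  fully Ca2+-shifted state with a ~9 mV hyperpolarized inactivation curve
  and roughly 2.4-fold faster inactivation.

Units package-wide: membrane potential in mV, time in ms, current in pA
(inward negative).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import NamedTuple, Union

import numpy as np

__all__ = [
    "TauCoeffs",
    "GatingParams",
    "GateState",
    "load_params",
    "CAV33_REST",
    "CAV33_SHIFTED",
]

ArrayLike = Union[float, np.ndarray]


class GateState(NamedTuple):
    """Instantaneous occupancy of the activation (m) and inactivation (h) gates."""

    m: float
    h: float


@dataclass(frozen=True)
class TauCoeffs:
    """Coefficients of the double-exponential time-constant curve.

    ``tau(v) = offset + scale / (exp((v + v1)/k1) + exp(-(v + v2)/k2))``

    ``offset`` and ``scale`` are in ms; ``v1``/``v2`` in mV set the centers
    of the rising and falling limbs, ``k1``/``k2`` (mV, positive) their
    steepness.
    """

    offset: float
    scale: float
    v1: float
    k1: float
    v2: float
    k2: float

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("tau steepness factors k1, k2 must be positive")
        if self.offset < 0 or self.scale <= 0:
            raise ValueError("tau requires offset >= 0 and scale > 0")

    def tau(self, v: ArrayLike) -> ArrayLike:
        v = np.asarray(v, dtype=float)
        with np.errstate(over="ignore"):  # saturates harmlessly at extremes
            den = np.exp((v + self.v1) / self.k1) + np.exp(-(v + self.v2) / self.k2)
        out = self.offset + self.scale / den
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GatingParams:
    """Steady-state and kinetic parameters for one channel state.

    ``v_half_act``/``v_half_inact`` are the physical midpoint potentials of
    the activation and inactivation curves (e.g. -52.6 mV / -72.4 mV for
    the resting set), ``k_act``/``k_inact`` the Boltzmann slope factors
    (positive, mV).
    """

    v_half_act: float
    k_act: float
    v_half_inact: float
    k_inact: float
    tau_m_coeffs: TauCoeffs
    tau_h_coeffs: TauCoeffs
    name: str = ""

    def __post_init__(self) -> None:
        if self.k_act <= 0 or self.k_inact <= 0:
            raise ValueError("Boltzmann slope factors must be positive")

    # -- steady-state curves -------------------------------------------------

    def m_inf(self, v: ArrayLike) -> ArrayLike:
        """Steady-state activation, increasing sigmoid in (0, 1)."""
        v = np.asarray(v, dtype=float)
        with np.errstate(over="ignore"):
            out = 1.0 / (1.0 + np.exp(-(v - self.v_half_act) / self.k_act))
        return float(out) if out.ndim == 0 else out

    def h_inf(self, v: ArrayLike) -> ArrayLike:
        """Steady-state availability (inactivation curve), decreasing sigmoid."""
        v = np.asarray(v, dtype=float)
        with np.errstate(over="ignore"):
            out = 1.0 / (1.0 + np.exp((v - self.v_half_inact) / self.k_inact))
        return float(out) if out.ndim == 0 else out

    # -- time constants ------------------------------------------------------

    def tau_m(self, v: ArrayLike) -> ArrayLike:
        """Activation time constant (ms), strictly positive."""
        return self.tau_m_coeffs.tau(v)

    def tau_h(self, v: ArrayLike) -> ArrayLike:
        """Inactivation time constant (ms), strictly positive."""
        return self.tau_h_coeffs.tau(v)

    def steady_state(self, v: float) -> GateState:
        """Equilibrium gate occupancies at a constant potential."""
        return GateState(float(self.m_inf(v)), float(self.h_inf(v)))

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GatingParams":
        d = dict(d)
        d.pop("version", None)
        d.pop("description", None)
        return cls(
            v_half_act=d["v_half_act"],
            k_act=d["k_act"],
            v_half_inact=d["v_half_inact"],
            k_inact=d["k_inact"],
            tau_m_coeffs=TauCoeffs(**d["tau_m_coeffs"]),
            tau_h_coeffs=TauCoeffs(**d["tau_h_coeffs"]),
            name=d.get("name", ""),
        )


def load_params(name_or_path: Union[str, Path]) -> GatingParams:
    """Load a gating parameter set.

    ``name_or_path`` is either the name of a packaged fixture
    (``"cav3.3_rest"`` or ``"cav3.3_shifted"``) or a path to a JSON file
    with the same schema.
    """
    p = Path(str(name_or_path))
    if p.suffix == ".json" and p.exists():
        data = json.loads(p.read_text())
    else:
        ref = resources.files("cav3sim.params").joinpath(f"{name_or_path}.json")
        try:
            data = json.loads(ref.read_text())
        except FileNotFoundError as exc:  # pragma: no cover - message path
            raise FileNotFoundError(
                f"unknown parameter set {name_or_path!r}; "
                "expected 'cav3.3_rest', 'cav3.3_shifted' or a JSON path"
            ) from exc
    return GatingParams.from_dict(data)


CAV33_REST = load_params("cav3.3_rest")
CAV33_SHIFTED = load_params("cav3.3_shifted")
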