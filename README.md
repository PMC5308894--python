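# cav3sim

Hodgkin–Huxley simulation and analysis of activity-dependent availability
of the Cav3.3 T-type calcium channel.

## The scientific problem

Cav3 (T-type) calcium channels open near the resting membrane potential,
and Cav3.3 in particular passes enough Ca²⁺ during sustained activity to
regulate itself: cumulative Ca²⁺ entry at the inner mouth of the channel
produces a hyperpolarizing shift of the steady-state inactivation curve,
and with it a use-dependent loss of channel availability.  The effect is
local (blocked by intracellular BAPTA but not EGTA), requires Ca²⁺-carried
current, builds with a half-time of ~18 s during 1 Hz stimulation and
reverses with a half-time of ~20 s.

This package is for electrophysiologists and modellers who want to
simulate, fit and reason about that feedback.  It provides:

- **`cav3sim.gating` / `cav3sim.channel`** — the channel in two printed
  states.  Gating follows the HH form `I = g·m^p·h·D(V)` (default `p = 2`,
  GHK constant-field driving term, 2 mM Ca²⁺ out / 100 nM in, 24 °C) with

  `m∞(V) = 1/(1+exp(−(V−V_a)/k_a))`, `h∞(V) = 1/(1+exp((V−V_h)/k_h))`,
  `τ(V) = A + B/(exp((V+V₁)/k₁)+exp(−(V+V₂)/k₂))`

  Resting state: `V_a = −52.6 mV, k_a = 4.7 mV, V_h = −72.4 mV,
  k_h = 5.7 mV`; fully Ca²⁺-shifted state: `V_a = −55.9, k_a = 5.6,
  V_h = −81.1, k_h = 5.0`, with ~2.4-fold faster inactivation.
- **`cav3sim.protocols`** — voltage-clamp protocols (steps, ramps,
  arbitrary waveforms, multi-sweep trains) integrated by exact exponential
  relaxation of the gates; peak-amplitude and charge-integral metrics.
- **`cav3sim.ca_dynamics`** — a scalar shift state `s ∈ [0,1]` with
  first-order kinetics `ds/dt = k_on·f·(1−s) − k_off·s` (f = normalized
  Ca²⁺ flux) that interpolates the gating *function values* between the
  two states; EGTA / BAPTA / 0-Ca²⁺ regimes; calibration to the 18 s /
  20 s half-times.
- **`cav3sim.fitting`** — Boltzmann (`I/I_max = 1/(1+exp((V−V_0.5)/k))`)
  and monoexponential model objects with statsmodels-style
  `fit() → results.summary()`.
- **`cav3sim.synthetic`** — noisy multi-sweep synthetic recordings for the
  SSI, train, holding-switch-recovery and thalamic-burst AP-clamp
  paradigms, with lognormal cell-to-cell amplitude variability and 2 kHz
  filtered noise.
- **`cav3sim.pipeline` / `cav3sim` CLI** — reproducible figure-level runs.

## Worked example

Predict how much of the peak current survives full Ca²⁺-shifting at a
physiological holding potential:

```python
from cav3sim.pipeline import run_shift_prediction

res = run_shift_prediction(holding_v=-70.0)
print(f"peak (rest)    {res['peak_rest']:.3f}")
print(f"peak (shifted) {res['peak_shifted']:.3f}")
print(f"decrease       {res['percent_decrease']:.1f} %")
```

prints

```
peak (rest)    1.358
peak (shifted) 0.289
decrease       78.7 %
```

At −70 mV the resting channel retains ~40% availability (`h∞ = 0.396`)
but the shifted channel only ~10% (`h∞ = 0.098`); that 4-fold availability
ratio, slightly compounded by the faster shifted kinetics, removes ~75–80%
of the peak current.  The same computation from −110 mV, where both states
are fully available, loses only ~13% (pure kinetics).  Fitting a Boltzmann
to a full simulated steady-state-inactivation protocol recovers the
midpoints the gating equations encode:

```python
from cav3sim.pipeline import RunConfig, run_ssi_shift
from cav3sim.synthetic import SyntheticConfig

cfg = RunConfig(experiment="ssi_shift",
                synthetic=SyntheticConfig(n_cells=1, noise_sd=0.0,
                                          g_max_cv=0.0, v_half_jitter_sd=0.0))
fit = run_ssi_shift(cfg)
print(round(fit["v_half_stim1"], 1), round(fit["v_half_stim40"], 1))
# -72.4 -81.1
```

The CLI wraps the same analyses:

```bash
cav3sim reproduce ssi_shift --out results/ --seed 1
cav3sim generate --paradigm train --seed 1 --out results/train/
```

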