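# Methods

## Channel model

The Cav3.3 current is described by the Hodgkin–Huxley formalism

    I(V, t) = g_max · m(t)^p · h(t) · D(V),

with an activation gate `m` and an inactivation gate `h` relaxing toward
voltage-dependent steady states `m∞(V)`, `h∞(V)` (Boltzmann sigmoids) with
time constants `τ_m(V)`, `τ_h(V)` of the double-exponential bell form
`A + B/(exp((V+V₁)/k₁) + exp(−(V+V₂)/k₂))`.  Two complete parameter sets
ship as read-only JSON fixtures:

| | `cav3.3_rest` | `cav3.3_shifted` |
|---|---|---|
| activation V₀.₅ / k (mV) | −52.6 / 4.7 | −55.9 / 5.6 |
| inactivation V₀.₅ / k (mV) | −72.4 / 5.7 | −81.1 / 5.0 |
| τ_h at −30 mV (ms) | ≈ 65.4 | ≈ 27.0 |

The shifted set represents the channel after ~40 s of 1 Hz stimulation
under EGTA dialysis, i.e. with the submembrane-Ca²⁺ feedback fully
engaged.  Assumptions and conventions:

- **Gating exponent `p = 2`** by default, the convention of the classical
  thalamic T-current models this parameterization descends from; the
  exponent is configurable.  The headline −70 mV inhibition prediction is
  78.7% at `p = 2` and 81.8% at `p = 1`, so the choice matters at the
  few-percentage-point level; `p = 2` is the package default everywhere.
- **Driving force**: GHK constant-field flux for Ca²⁺ with 2 mM external
  and 100 nM internal free Ca²⁺ at 24 °C (the removable singularity at
  V = 0 is evaluated analytically); an ohmic `(V − E_rev)` mode exists for
  testing.  All headline quantities are amplitude ratios and move by
  < 0.2 percentage points between the two modes.
- **Temperature**: the τ curves are taken as already valid at 24 °C; no
  Q10 rescaling is applied (`q10_factor = 1` is an explicit hook).
- **Units**: mV, ms, pA throughout; inward current negative, amplitudes
  reported as positive magnitudes.

## Protocol integration

Gates are advanced by the exact exponential relaxation
`x' = x∞ + (x − x∞)·e^(−dt/τ)` per sample interval (default
`dt = 0.05 ms`), which is exact on constant-voltage segments and treats
ramps/waveforms as piecewise constant per sub-step; halving `dt` changes
the standard test-pulse peak by < 0.1%, and the trajectory matches an
adaptive high-order ODE solve to ≤ 1e−6 relative error.  Each sweep
records 20 ms at holding before the first command segment; the baseline
for peak and charge measurements is the mean current over the final 10 ms
of that window (no capacitive or leak artifacts are modelled, so any
nonzero baseline is window current), and peaks are searched over the test
segment plus 1 ms to exclude tail currents.  Inter-sweep intervals are
relaxed analytically at holding rather than sampled, keeping 0.033 Hz
trains cheap.

## Submembrane-Ca²⁺ feedback

A single shift state `s ∈ [0, 1]` interpolates every gating curve between
the resting (`s = 0`) and shifted (`s = 1`) sets *by function value* at
each voltage — guaranteeing both printed endpoint behaviours exactly and
keeping intermediate curves monotone.  The state follows first-order
kinetics driven by the channel's own phasic Ca²⁺ flux,

    ds/dt = k_on · f(t) · (1 − s) − k_off · s,    f = |I_Ca| / I_ref,

integrated exactly over each sub-step at constant flux.  `I_ref` is the
cell's resting-state peak for the standard paradigm (450 ms pulse to
−30 mV from −100 mV), which decouples the feedback gain from the
arbitrary conductance scale while preserving how Ca²⁺ entry varies with
holding potential and waveform.  The standing window current at holding
is neglected as a drive (sub-pA scale under EGTA buffering); without this
choice sustained window flux at depolarized holdings would dominate the
cumulative entry and invert the holding-potential dependence.  Intracellular
BAPTA and Ca²⁺-free (Na⁺-carried) conditions clamp `s = 0`.

**Calibration.** `k_off = ln 2 / 20 s` follows from the recovery
half-time; `k_on` is found by bisection so the peak-amplitude time course
of the 1 Hz standard train halves its slow decline at 18 s (measured from
sweep 2 onward — the sweep-1→2 drop of ~7% is ordinary short-term
inactivation, since a 450 ms pulse leaves only ~550 ms of recovery against
τ_h(−100) ≈ 210 ms).  Calibrated default: `k_on = 2.806e−5 /ms` per unit
normalized flux.

**Structural limitation (important).** With first-order kinetics the
onset rate `k_on·f + k_off` can never be slower than `k_off`, so onset
and recovery half-times of 18 s and 20 s force `k_on·f ≈ 0.1·k_off` and
cap the steady-state shift of the 1 Hz train near `s ≈ 0.1`.  The
calibrated dynamics therefore reproduce the printed *time courses* and
every availability-driven prediction, but underpredict the *magnitude* of
the dynamic train inhibition (~9% simulated at −100 mV) and the
EGTA-vs-BAPTA separation of the AP-clamp charge decline.  A mechanism
with cooperativity or an intermediate Ca²⁺ pool would be needed to
produce both slow half-times and near-complete shifting; the experimental
literature leaves that mechanism unresolved, and this package does not
invent one.

## Curve fitting

Boltzmann fits use `I/I_max = A/(1 + exp(±(V_m − V_0.5)/k))` with
deterministic initialization (`V_0.5` = voltage nearest the half-span of
the data, `k = 5 mV`, `A = max(y)`); inactivation decays are fitted with a
single exponential `|I|(t) = A·e^(−t/τ) + C` from the peak to the pulse
end (exact for an HH h-gate at constant voltage, hence self-consistent).
Degenerate inputs (span < 5% of amplitude) are flagged unconverged, never
silently returned.  SSI curves are normalized to the most hyperpolarized
conditioning sweep.  Half-times are linear interpolations of the crossing
of the midpoint between initial and asymptotic values.

## Synthetic recordings

The generator emulates whole-cell recordings of transfected cells:

- amplitude scale `g_max_mean = 150` (arbitrary conductance units) puts
  the standard test-pulse peak near 500 pA, typical of whole-cell Cav3.3;
- lognormal cell-to-cell conductance variability (CV 0.3) and Gaussian
  jitter of both V₀.₅ values (sd 1.5 mV) produce figure-like scatter
  (both values are package choices, not measured quantities);
- additive white current noise (sd 5 pA) low-pass filtered at 2 kHz to
  match the recording bandwidth;
- an optional direct amplitude attenuation `1 − α·s` (default α = 0.42,
  fixed at the `s = 1` endpoint so a fully shifted channel at −100 mV
  loses ~50% of its peak, the value fast 1 Hz trains display) used only
  for trace emulation, never for the model predictions;
- the thalamic-burst AP-clamp command is synthesized parametrically (13
  spikes with decelerating intervals on a −100 → −60 mV envelope,
  τ = 120 ms, followed by a depolarized after-potential), since no
  recorded waveform is published.  With it, the Ca²⁺-independent
  spike-current facilitation (4th/1st spike ratio > 1) and the
  within-burst decay (13th/1st < 1) emerge from gate kinetics alone; the
  magnitude of both depends strongly on the waveform details and is
  treated as qualitative.

Not emulated: series resistance, capacitive transients, leak, space-clamp
error, spatial Ca²⁺ diffusion (EGTA/BAPTA length-scale physics is
abstracted to a binary regime), and receptor pharmacology (Ca²⁺-permeable
receptor activation is representable only as an imposed shift/bolus).
Passing tests on synthetic data therefore demonstrate the internal
consistency of model, protocols and estimators — not fidelity to any
particular recorded cell.

## Problem sizes and numerics

Default analyses run at `dt = 0.05 ms`; multi-sweep paradigm tests and
calibration use `dt = 0.1–0.2 ms`, where the standard peak differs from
the converged value by < 0.1%.  SSI protocols use 19 conditioning steps
(−130…−40 mV, 5 mV) of 5 s; trains use 40–90 sweeps; the AP-clamp runs 40
one-second repeats.  Calibration brackets `k_on` in [1e−6, 5e−2] /ms by
bisection on the log scale and reports non-convergence rather than
extrapolating.  All generators are pure functions of (config, seed);
fits are deterministic with fixed heuristic initialization.
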