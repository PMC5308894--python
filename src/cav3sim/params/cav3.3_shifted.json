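{
  "name": "cav3.3_shifted",
  "version": 1,
  "description": "Cav3.3 gating after 40 s of 1 Hz stimulation (fully Ca2+-shifted state), 24 C whole-cell convention",
  "v_half_act": -55.9,
  "k_act": 5.6,
  "v_half_inact": -81.1,
  "k_inact": 5.0,
  "tau_m_coeffs": {"offset": 1.141, "scale": 0.9592, "v1": 14.95, "k1": 13.97, "v2": 81.53, "k2": 5.0},
  "tau_h_coeffs": {"offset": 26.55, "scale": 0.66, "v1": 32.42, "k1": 6.4, "v2": 225.0, "k2": 22.21}
}
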