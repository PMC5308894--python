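{
  "name": "cav3.3_rest",
  "version": 1,
  "description": "Cav3.3 gating at rest (low-frequency stimulation), 24 C whole-cell convention",
  "v_half_act": -52.6,
  "k_act": 4.7,
  "v_half_inact": -72.4,
  "k_inact": 5.7,
  "tau_m_coeffs": {"offset": 1.377, "scale": 1.512, "v1": 12.52, "k1": 14.38, "v2": 81.59, "k2": 5.0},
  "tau_h_coeffs": {"offset": 65.34, "scale": 1.0, "v1": 41.04, "k1": 4.01, "v2": 333.1, "k2": 46.86}
}
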