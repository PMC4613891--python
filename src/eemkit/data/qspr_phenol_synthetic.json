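{
  "name": "phenol-pka-synthetic",
  "descriptor_names": ["q_HO", "q_O", "q_C"],
  "coefficients": [-18.0, 9.0, -4.0],
  "intercept": 16.5,
  "provenance": "Synthetic phenol-type pKa model for workflow tests and examples: coefficients are plausible in sign and magnitude (more positive phenolic H => more acidic => lower pKa) but are NOT fitted to any experimental data and must not be used for prediction."
}
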