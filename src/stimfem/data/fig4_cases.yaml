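# Multipolar (2x2 grid) matrix: net-zero (+1,-1,+1,-1) mA and net-nonzero
# (+1,+1,+1,+1) mA with current returned to the grounded outer boundary.
# Representative patterns; the superposition-equivalence property being
# tested is pattern-independent.
- {case_id: "z1", figure: fig4, source_model: pcs, substrate_scheme: silicone,
   superposition_mode: simultaneous, current_pattern: [1.0, -1.0, 1.0, -1.0],
   gold_standard: true}
- {case_id: "z2", figure: fig4, source_model: pcs, substrate_scheme: silicone,
   superposition_mode: superposition_A_floating,
   current_pattern: [1.0, -1.0, 1.0, -1.0], expected_zero_error: true}
- {case_id: "z3", figure: fig4, source_model: fp, substrate_scheme: silicone,
   superposition_mode: simultaneous, current_pattern: [1.0, -1.0, 1.0, -1.0],
   expected_zero_error: true}
- {case_id: "z4", figure: fig4, source_model: fp, substrate_scheme: silicone,
   superposition_mode: superposition_A_floating,
   current_pattern: [1.0, -1.0, 1.0, -1.0], expected_zero_error: true}
- {case_id: "z5", figure: fig4, source_model: pcs,
   substrate_scheme: platinum_insulated_with_seams,
   superposition_mode: simultaneous, current_pattern: [1.0, -1.0, 1.0, -1.0],
   expected_zero_error: true}
- {case_id: "n1", figure: fig4, source_model: pcs, substrate_scheme: silicone,
   superposition_mode: simultaneous, current_pattern: [1.0, 1.0, 1.0, 1.0],
   gold_standard: true}
- {case_id: "n2", figure: fig4, source_model: pcs, substrate_scheme: silicone,
   superposition_mode: superposition_A_floating,
   current_pattern: [1.0, 1.0, 1.0, 1.0], expected_zero_error: true}
- {case_id: "n3", figure: fig4, source_model: fp, substrate_scheme: silicone,
   superposition_mode: superposition_A_floating,
   current_pattern: [1.0, 1.0, 1.0, 1.0], expected_zero_error: true}
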