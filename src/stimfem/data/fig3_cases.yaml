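# Bipolar comparison matrix: +1 mA / -1 mA, flush thin-platinum contacts.
# Superposition A floats the inactive contact during each unit solve
# (condition of continuity); Superposition B grounds it.
- {case_id: "1",  source_model: pcs, substrate_scheme: silicone,
   superposition_mode: simultaneous, current_pattern: [1.0, -1.0], gold_standard: true}
- {case_id: "2",  source_model: pcs, substrate_scheme: silicone,
   superposition_mode: superposition_A_floating, current_pattern: [1.0, -1.0],
   expected_zero_error: true}
- {case_id: "3",  source_model: pcs, substrate_scheme: silicone,
   superposition_mode: superposition_B_grounded, current_pattern: [1.0, -1.0]}
- {case_id: "4",  source_model: pcs, substrate_scheme: platinum_insulated_with_seams,
   superposition_mode: simultaneous, current_pattern: [1.0, -1.0], expected_zero_error: true}
- {case_id: "5",  source_model: pcs, substrate_scheme: platinum_insulated_with_seams,
   superposition_mode: superposition_A_floating, current_pattern: [1.0, -1.0],
   expected_zero_error: true}
- {case_id: "6",  source_model: bcs, substrate_scheme: silicone,
   superposition_mode: simultaneous, current_pattern: [1.0, -1.0], expected_zero_error: true}
- {case_id: "7",  source_model: bcs, substrate_scheme: silicone,
   superposition_mode: superposition_A_floating, current_pattern: [1.0, -1.0],
   expected_zero_error: true}
- {case_id: "8",  source_model: bcs, substrate_scheme: silicone,
   superposition_mode: superposition_B_grounded, current_pattern: [1.0, -1.0]}
- {case_id: "9",  source_model: bcs, substrate_scheme: platinum_insulated_with_seams,
   superposition_mode: simultaneous, current_pattern: [1.0, -1.0], expected_zero_error: true}
- {case_id: "10", source_model: bcs, substrate_scheme: platinum_insulated_with_seams,
   superposition_mode: superposition_A_floating, current_pattern: [1.0, -1.0],
   expected_zero_error: true}
- {case_id: "11", source_model: fp, substrate_scheme: silicone,
   superposition_mode: simultaneous, current_pattern: [1.0, -1.0], expected_zero_error: true}
- {case_id: "12", source_model: fp, substrate_scheme: silicone,
   superposition_mode: superposition_A_floating, current_pattern: [1.0, -1.0],
   expected_zero_error: true}
- {case_id: "13", source_model: fp, substrate_scheme: silicone,
   superposition_mode: superposition_B_grounded, current_pattern: [1.0, -1.0]}
- {case_id: "14", source_model: fp, substrate_scheme: platinum_insulated_with_seams,
   superposition_mode: simultaneous, current_pattern: [1.0, -1.0], expected_zero_error: true}
- {case_id: "15", source_model: fp, substrate_scheme: platinum_insulated_with_seams,
   superposition_mode: superposition_A_floating, current_pattern: [1.0, -1.0],
   expected_zero_error: true}
- {case_id: "16", source_model: ep, substrate_scheme: silicone,
   superposition_mode: simultaneous, current_pattern: [1.0, -1.0]}
- {case_id: "17", source_model: ep, substrate_scheme: silicone,
   superposition_mode: superposition_A_floating, current_pattern: [1.0, -1.0],
   expected_zero_error: true}
- {case_id: "18", source_model: ep, substrate_scheme: silicone,
   superposition_mode: superposition_B_grounded, current_pattern: [1.0, -1.0]}
- {case_id: "19", source_model: ep, substrate_scheme: platinum_insulated_with_seams,
   superposition_mode: simultaneous, current_pattern: [1.0, -1.0],
   known_solver_artifact: true}
- {case_id: "20", source_model: ep, substrate_scheme: platinum_insulated_with_seams,
   superposition_mode: superposition_A_floating, current_pattern: [1.0, -1.0],
   known_solver_artifact: true}
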