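# Monopolar comparison matrix: one active contact at 1 mA, one inactive.
# Substrate-scheme sweep (cases 1-4) repeats per source model (5-8 bcs,
# 9-12 fp, 13-16 ep).  Cases whose exact composition could not be pinned
# down from the narrative are marked provenance: inferred and carry no
# acceptance weight.  known_solver_artifact flags configurations where the
# commercial solver grounded the inactive contact spuriously; this
# implementation deliberately does not reproduce that behaviour.
- {case_id: "1",  source_model: pcs, substrate_scheme: silicone, gold_standard: true}
- {case_id: "2",  source_model: pcs, substrate_scheme: silicone_insulated, expected_zero_error: true}
- {case_id: "3",  source_model: pcs, substrate_scheme: medium_insulated}
- {case_id: "4",  source_model: pcs, substrate_scheme: platinum_insulated_with_seams, expected_zero_error: true}
- {case_id: "5",  source_model: bcs, substrate_scheme: silicone, expected_zero_error: true}
- {case_id: "6",  source_model: bcs, substrate_scheme: silicone_insulated, expected_zero_error: true}
- {case_id: "7",  source_model: bcs, substrate_scheme: medium_insulated}
- {case_id: "8",  source_model: bcs, substrate_scheme: platinum_insulated_with_seams, expected_zero_error: true}
- {case_id: "9",  source_model: fp, substrate_scheme: silicone, expected_zero_error: true}
- {case_id: "10", source_model: fp, substrate_scheme: silicone_insulated, expected_zero_error: true}
- {case_id: "11", source_model: fp, substrate_scheme: medium_insulated}
- {case_id: "12", source_model: fp, substrate_scheme: platinum_insulated_with_seams, expected_zero_error: true}
- {case_id: "13", source_model: ep, substrate_scheme: silicone, expected_zero_error: true}
- {case_id: "14", source_model: ep, substrate_scheme: silicone_insulated, expected_zero_error: true}
- {case_id: "15", source_model: ep, substrate_scheme: medium_insulated}
- {case_id: "16", source_model: ep, substrate_scheme: platinum_insulated_with_seams,
   known_solver_artifact: true}
- {case_id: "17", source_model: pcs, substrate_scheme: silicone, contact_profile: raised_half}
- {case_id: "18", source_model: bcs, substrate_scheme: silicone, contact_profile: raised_half,
   provenance: inferred}
- {case_id: "19", source_model: fp, substrate_scheme: silicone, contact_profile: raised_half,
   provenance: inferred}
- {case_id: "20", source_model: bcs, substrate_scheme: silicone,
   contact_model: thin_substrate_conductivity, provenance: inferred}
- {case_id: "21", source_model: fp, substrate_scheme: silicone,
   contact_model: thin_substrate_conductivity, provenance: inferred}
- {case_id: "22", source_model: ep, substrate_scheme: silicone,
   contact_model: thin_substrate_conductivity, provenance: inferred}
- {case_id: "23", source_model: bcs, substrate_scheme: silicone,
   contact_model: no_thin_domain, provenance: inferred}
- {case_id: "24", source_model: bcs, substrate_scheme: platinum_insulated_with_seams,
   contact_model: no_thin_domain}
- {case_id: "25", source_model: fp, substrate_scheme: silicone,
   contact_model: no_thin_domain, provenance: inferred}
- {case_id: "26", source_model: fp, substrate_scheme: platinum_insulated_with_seams,
   contact_model: no_thin_domain}
- {case_id: "27", source_model: ep, substrate_scheme: silicone,
   contact_model: no_thin_domain, provenance: inferred}
- {case_id: "28", source_model: ep, substrate_scheme: platinum_insulated_with_seams,
   contact_model: no_thin_domain, known_solver_artifact: true}
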