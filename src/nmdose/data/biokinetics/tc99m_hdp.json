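{
  "name": "Tc99m-HDP/MDP bone scan",
  "nuclide": "Tc99m",
  "comment": "Representative first-order bone-agent kinetics: fast blood clearance (T1/2 ~40 min) split between skeletal uptake (trapped), the renal/urinary path and exchangeable soft tissue. Transfer coefficients are editable configuration, not measured constants; see docs/methods.md.",
  "injection_compartment": "Blood",
  "excretion_sink": "Urine",
  "compartments": ["Blood", "Bone", "Kidneys", "Soft tissue"],
  "transfer_per_min": {
    "Blood->Bone": 0.0078,
    "Blood->Kidneys": 0.0061,
    "Blood->Soft tissue": 0.0034,
    "Soft tissue->Blood": 0.0023,
    "Kidneys->Urine": 0.0347
  },
  "region_map": {
    "Blood": "Remainder",
    "Bone": "Bone",
    "Kidneys": "Kidneys",
    "Soft tissue": "Remainder"
  }
}
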