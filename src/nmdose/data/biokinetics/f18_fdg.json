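{
  "name": "F18-FDG",
  "nuclide": "F18",
  "comment": "Representative FDG kinetics: rapid plasma clearance with metabolic trapping in brain, myocardium and other organs, and renal excretion of non-metabolised tracer. Transfer coefficients are editable configuration; see docs/methods.md.",
  "injection_compartment": "Blood",
  "excretion_sink": "Urine",
  "compartments": ["Blood", "Brain", "Heart", "Liver", "Lungs", "Pancreas", "Spleen", "Kidneys", "Other tissue"],
  "transfer_per_min": {
    "Blood->Brain": 0.00416,
    "Blood->Heart": 0.00208,
    "Blood->Liver": 0.00277,
    "Blood->Lungs": 0.00162,
    "Blood->Pancreas": 0.00037,
    "Blood->Spleen": 0.00055,
    "Blood->Kidneys": 0.00554,
    "Blood->Other tissue": 0.02911,
    "Other tissue->Blood": 0.0012,
    "Kidneys->Urine": 0.0462
  },
  "region_map": {
    "Blood": "Blood",
    "Brain": "Brain",
    "Heart": "Heart",
    "Liver": "Liver",
    "Lungs": "Lungs",
    "Pancreas": "Pancreas",
    "Spleen": "Spleen",
    "Kidneys": "Kidneys",
    "Other tissue": "Remainder"
  }
}
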