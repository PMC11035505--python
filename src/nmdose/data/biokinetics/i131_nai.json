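{
  "name": "Na131I iodide",
  "nuclide": "I131",
  "comment": "Representative systemic iodide kinetics: blood iodide partitions between thyroid uptake, renal excretion, salivary/gastric secretion feeding the gut chain, liver and exchangeable tissue. The colon chain is terminated at the recto-sigmoid segment (faecal clearance is slow on the study horizon). Transfer coefficients are editable configuration; see docs/methods.md.",
  "injection_compartment": "Blood",
  "excretion_sink": "Urine",
  "compartments": ["Blood", "Thyroid", "Kidneys", "Salivary glands", "Stomach wall", "Liver", "Other tissue", "Small intestine", "Right colon", "Left colon", "Recto-sigmoid colon"],
  "transfer_per_min": {
    "Blood->Thyroid": 0.000578,
    "Blood->Kidneys": 0.001155,
    "Blood->Salivary glands": 0.000139,
    "Blood->Stomach wall": 0.000162,
    "Blood->Liver": 0.000116,
    "Blood->Other tissue": 0.000162,
    "Other tissue->Blood": 0.0020,
    "Liver->Blood": 0.0058,
    "Salivary glands->Small intestine": 0.0116,
    "Stomach wall->Small intestine": 0.0116,
    "Small intestine->Blood": 0.0039,
    "Small intestine->Right colon": 0.0040,
    "Right colon->Left colon": 0.00105,
    "Left colon->Recto-sigmoid colon": 0.00105,
    "Kidneys->Urine": 0.0347
  },
  "region_map": {
    "Blood": "Blood",
    "Thyroid": "Thyroid",
    "Kidneys": "Kidneys",
    "Salivary glands": "Salivary glands",
    "Stomach wall": "Stomach wall",
    "Liver": "Liver",
    "Other tissue": "Remainder",
    "Small intestine": "Small intestine content",
    "Right colon": "Right colon content",
    "Left colon": "Left colon content",
    "Recto-sigmoid colon": "Recto-sigmoid colon content"
  }
}
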