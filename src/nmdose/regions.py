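"""Canonical source-region labels.

Every biokinetic compartment maps onto one of these anatomical source
regions; the phantom generator labels the same set so that time-activity
curves and per-region dose-rate factors can be joined by name.
"""

TABLE1_REGIONS = (
    "Urinary bladder content",
    "Kidneys",
    "Bone",
    "Remainder",
    "Liver",
    "Blood",
    "Brain",
    "Heart",
    "Lungs",
    "Pancreas",
    "Spleen",
    "Salivary glands",
    "Stomach wall",
    "Thyroid",
    "Small intestine content",
    "Right colon content",
    "Left colon content",
    "Recto-sigmoid colon content",
)

BLADDER = "Urinary bladder content"
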