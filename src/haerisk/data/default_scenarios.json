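[
  {
    "label": "Black x Midwest",
    "evidence": {"Race": "Black", "Region": "Midwest"}
  },
  {
    "label": "Black x South",
    "evidence": {"Race": "Black", "Region": "South"}
  },
  {
    "label": "Black x Midwest x >=65",
    "evidence": {"Race": "Black", "Region": "Midwest", "Age": "≥65"}
  },
  {
    "label": "Hispanic x Medicare/Medicaid",
    "evidence": {"Race": "Hispanic", "Payer": {"Medicare": 1.0, "Medicaid": 1.0}}
  }
]
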