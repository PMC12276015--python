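{
  "nodes": [
    {"name": "Age", "categories": ["≤17", "18-39", "40-64", "≥65"], "role": "predictor"},
    {"name": "Race", "categories": ["White", "Black", "Hispanic", "Other"], "role": "predictor"},
    {"name": "Income", "categories": ["Q1", "Q2", "Q3", "Q4"], "role": "predictor"},
    {"name": "Payer", "categories": ["Medicare", "Medicaid", "Private", "Other"], "role": "predictor"},
    {"name": "Region", "categories": ["Northeast", "Midwest", "South", "West"], "role": "predictor"},
    {"name": "Hypertension", "categories": ["no", "yes"], "role": "predictor"},
    {"name": "Autoimmune", "categories": ["no", "yes"], "role": "predictor"},
    {"name": "Diabetes", "categories": ["no", "yes"], "role": "predictor"},
    {"name": "Severity", "categories": ["minor", "moderate", "major", "extreme"], "role": "predictor"},
    {"name": "MortalityRisk", "categories": ["low", "high"], "role": "outcome"}
  ],
  "edges": [
    ["Age", "Hypertension"],
    ["Age", "Autoimmune"],
    ["Age", "Diabetes"],
    ["Age", "MortalityRisk"],
    ["Race", "MortalityRisk"],
    ["Income", "MortalityRisk"],
    ["Payer", "MortalityRisk"],
    ["Region", "MortalityRisk"],
    ["Hypertension", "Severity"],
    ["Autoimmune", "Severity"],
    ["Diabetes", "Severity"],
    ["Severity", "MortalityRisk"]
  ]
}
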