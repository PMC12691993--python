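{
  "id": "canonic_full",
  "description": "Canonic glucose catabolism: full glycolysis (10 reactions), pyruvate dehydrogenase (one step) x2, citric acid cycle (8 reactions) x2; GTP booked as ATP. Complete oxidation of one glucose to six CO2.",
  "steps": [
    {"reaction": "HK", "multiplicity": 1},
    {"reaction": "GPI", "multiplicity": 1},
    {"reaction": "PFK", "multiplicity": 1},
    {"reaction": "ALDO", "multiplicity": 1},
    {"reaction": "TPI", "multiplicity": 1},
    {"reaction": "GAPDH", "multiplicity": 2},
    {"reaction": "PGK", "multiplicity": 2},
    {"reaction": "PGM", "multiplicity": 2},
    {"reaction": "ENO", "multiplicity": 2},
    {"reaction": "PK", "multiplicity": 2},
    {"reaction": "PDH", "multiplicity": 2},
    {"reaction": "CS", "multiplicity": 2},
    {"reaction": "ACO", "multiplicity": 2},
    {"reaction": "IDH3", "multiplicity": 2},
    {"reaction": "OGDH", "multiplicity": 2},
    {"reaction": "SUCLG", "multiplicity": 2},
    {"reaction": "SDH", "multiplicity": 2},
    {"reaction": "FH", "multiplicity": 2},
    {"reaction": "MDH2", "multiplicity": 2}
  ]
}
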