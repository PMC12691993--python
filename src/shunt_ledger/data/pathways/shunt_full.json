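{
  "id": "shunt_full",
  "description": "Partial glycolysis (first 7 of 10 reactions, to 3-phosphoglycerate) coupled to the serine-folate shunt: serinogenesis x2, mitochondrial folate cycling of 4 one-carbon units (2 serine-derived, 2 glycine-derived), glycine cleavage x2, glutamate recycled by NADH-dependent glutamate dehydrogenase. Complete oxidation of one glucose to six CO2.",
  "steps": [
    {"reaction": "HK", "multiplicity": 1},
    {"reaction": "GPI", "multiplicity": 1},
    {"reaction": "PFK", "multiplicity": 1},
    {"reaction": "ALDO", "multiplicity": 1},
    {"reaction": "TPI", "multiplicity": 1},
    {"reaction": "GAPDH", "multiplicity": 2},
    {"reaction": "PGK", "multiplicity": 2},
    {"reaction": "PHGDH", "multiplicity": 2},
    {"reaction": "PSAT1", "multiplicity": 2},
    {"reaction": "PSPH", "multiplicity": 2},
    {"reaction": "SFXN1", "multiplicity": 2},
    {"reaction": "SHMT2", "multiplicity": 2},
    {"reaction": "GCS", "multiplicity": 2},
    {"reaction": "GDH", "multiplicity": 2},
    {"reaction": "MTHFD2_DH", "multiplicity": 4},
    {"reaction": "MTHFD2_CH", "multiplicity": 4},
    {"reaction": "ALDH1L2", "multiplicity": 4}
  ]
}
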