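{
  "id": "ppp_full",
  "description": "Complete glucose oxidation through the pentose phosphate pathway: hexokinase, oxidative PPP x6, non-oxidative sugar rearrangement, and four gluconeogenic recycling steps returning glyceraldehyde-3-phosphate and fructose-6-phosphate to glucose-6-phosphate.",
  "steps": [
    {"reaction": "HK", "multiplicity": 1},
    {"reaction": "G6PD", "multiplicity": 6},
    {"reaction": "PGLS", "multiplicity": 6},
    {"reaction": "PGD", "multiplicity": 6},
    {"reaction": "RPI", "multiplicity": 2},
    {"reaction": "RPE", "multiplicity": 4},
    {"reaction": "TKT1", "multiplicity": 2},
    {"reaction": "TALDO", "multiplicity": 2},
    {"reaction": "TKT2", "multiplicity": 2},
    {"reaction": "TPI_GN", "multiplicity": 1},
    {"reaction": "ALDO_GN", "multiplicity": 1},
    {"reaction": "FBP1", "multiplicity": 1},
    {"reaction": "GPI_GN", "multiplicity": 5}
  ]
}
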