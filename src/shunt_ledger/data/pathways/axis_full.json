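{
  "id": "axis_full",
  "description": "NADPH-FADH2 axis: complete glucose oxidation through the pentose phosphate pathway whose 12 NADPH are destined for 1:1 disposal as respirable FADH2 through fatty acid cycling. The cycling cost is carried by the ATP-equivalence scenario (NADPH at -3/2 ATP); the ledger itself reports the 12 NADPH and the -1 substrate-level ATP.",
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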