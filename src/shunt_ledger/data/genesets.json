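{
  "format": "shunt-ledger-genesets",
  "version": 1,
  "genesets": [
    {"name": "shunt_serinogenesis", "purpose": "shunt_serinogenesis",
     "genes": ["PHGDH", "PSAT1", "PSPH", "SFXN1"]},
    {"name": "shunt_mito_folate", "purpose": "shunt_mito_folate",
     "genes": ["SHMT2", "MTHFD2", "MTHFD1L", "ALDH1L2"]},
    {"name": "shunt_cyto_folate", "purpose": "shunt_cyto_folate",
     "genes": ["MTHFD1", "ALDH1L1"]},
    {"name": "glycine_cleavage", "purpose": "glycine_cleavage",
     "genes": ["GLDC", "AMT", "GCSH", "DLD"]},
    {"name": "nadph_export", "purpose": "nadph_export",
     "genes": ["IDH1", "IDH2"]},
    {"name": "serine_anabolic", "purpose": "serine_anabolic",
     "genes": ["SRR", "SPTLC1", "SPTLC2", "CBS"]},
    {"name": "mito_translation", "purpose": "mito_translation",
     "genes": ["MTFMT"]},
    {"name": "purine_synthesis", "purpose": "purine_synthesis",
     "genes": ["PPAT", "GART", "ATIC"]},
    {"name": "purine_salvage", "purpose": "purine_salvage",
     "genes": ["APRT", "HPRT1"]},
    {"name": "pyrimidine_dna", "purpose": "pyrimidine_dna",
     "genes": ["TYMS", "DHFR", "CAD", "RRM2"]},
    {"name": "methionine_cycle", "purpose": "methionine_cycle",
     "genes": ["MTHFR", "MTR", "MAT2A", "CBS"]},
    {"name": "antioxidant_cyto", "purpose": "antioxidant_cyto",
     "genes": ["GSR", "TXNRD1", "GPX1", "SOD1", "CAT", "TXN"]},
    {"name": "antioxidant_mito", "purpose": "antioxidant_mito",
     "genes": ["GPX4", "SOD2", "TXNRD2", "TXN2"]}
  ]
}
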