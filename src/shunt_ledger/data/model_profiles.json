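{
  "format": "shunt-ledger-model-profiles",
  "version": 1,
  "profiles": [
    {"model_id": "model1", "label": "MPP-treated LUHMES neurons (RNA-seq)",
     "padj_threshold": 1e-06, "low_expr_threshold": 1.0},
    {"model_id": "model2", "label": "Methionine-restricted rat liver (exon microarray)",
     "padj_threshold": 0.05, "low_expr_threshold": 0.0},
    {"model_id": "model3", "label": "NDUFS2 R228Q patient fibroblasts (RNA-seq)",
     "padj_threshold": 1e-06, "low_expr_threshold": 5.0}
  ]
}
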