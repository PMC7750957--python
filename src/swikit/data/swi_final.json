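{
  "name": "swi_final",
  "provenance": "Final Solubility-Weighted Index residue weights, derived by AUC-maximizing refinement of Smith et al. (2003) normalized B-factors on the PSI:Biology solubility dataset (Bhandari, Gardner & Lim 2020, Bioinformatics 36:4691-4698; values as published in the SoDoPE implementation).",
  "values": {
    "A": 0.8356471476582918,
    "C": 0.5208088354857734,
    "D": 0.9079044671339564,
    "E": 0.9876987431418378,
    "F": 0.5849790194237692,
    "G": 0.7997168496420723,
    "H": 0.8947913996466419,
    "I": 0.6784124413866582,
    "K": 0.9267104557513497,
    "L": 0.6554221515081433,
    "M": 0.6296623675420369,
    "N": 0.8597433107431216,
    "P": 0.8235328714705341,
    "Q": 0.789434648348208,
    "R": 0.7712466317693457,
    "S": 0.7440908318492778,
    "T": 0.8096922697856334,
    "V": 0.7357011981778542,
    "W": 0.6374678690957594,
    "Y": 0.6112801822947587
  }
}
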