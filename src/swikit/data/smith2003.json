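{
  "name": "smith2003",
  "provenance": "Normalized B-factors (flexibility parameters) of Smith, Radivojac, Obradovic, Dunker & Zhu (2003) Protein Sci 12:1060-1072; used as the initial weights for SWI training.",
  "values": {
    "A": 0.717,
    "C": 0.668,
    "D": 0.921,
    "E": 0.963,
    "F": 0.599,
    "G": 0.843,
    "H": 0.754,
    "I": 0.632,
    "K": 0.912,
    "L": 0.681,
    "M": 0.685,
    "N": 0.851,
    "P": 0.85,
    "Q": 0.849,
    "R": 0.814,
    "S": 0.84,
    "T": 0.758,
    "V": 0.619,
    "W": 0.626,
    "Y": 0.615
  }
}
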