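{
  "name": "bhaskaran1988",
  "provenance": "Average flexibility indices of Bhaskaran & Ponnuswamy (1988) Int J Pept Protein Res 32:241-255 (AAindex BHAR880101); a B-factor-derived per-residue flexibility propensity scale.",
  "values": {
    "A": 0.357,
    "C": 0.346,
    "D": 0.511,
    "E": 0.497,
    "F": 0.314,
    "G": 0.544,
    "H": 0.323,
    "I": 0.462,
    "K": 0.466,
    "L": 0.365,
    "M": 0.295,
    "N": 0.463,
    "P": 0.509,
    "Q": 0.493,
    "R": 0.529,
    "S": 0.507,
    "T": 0.444,
    "V": 0.386,
    "W": 0.305,
    "Y": 0.42
  }
}
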