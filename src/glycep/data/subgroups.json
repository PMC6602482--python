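{
  "schema_version": 1,
  "description": "Default consolidation of the 20 standard amino acids into 13 functional subgroups used for triangle pattern typing. Replaceable via config; the reserved catch-all group 'UNK' receives unknown residues ('X').",
  "groups": {
    "AG": ["A", "G"],
    "VLI": ["V", "L", "I"],
    "F": ["F"],
    "Y": ["Y"],
    "W": ["W"],
    "C": ["C"],
    "M": ["M"],
    "P": ["P"],
    "ST": ["S", "T"],
    "NQ": ["N", "Q"],
    "DE": ["D", "E"],
    "KR": ["K", "R"],
    "H": ["H"]
  },
  "unknown_group": "UNK"
}
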