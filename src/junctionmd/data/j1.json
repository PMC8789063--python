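{
  "_comment": [
    "SYNTHETIC FIXTURE topology for the J1-family immobile four-way junction.",
    "Full 16-nt strand sequences of the original construct are not available",
    "in machine-readable form; these strands are constructed to be fully",
    "Watson-Crick consistent and to carry the documented core dinucleotide",
    "steps: CT at isomer 1 helix 1 (strand I, steps 8-9) and TG at isomer 2",
    "helix 2 (strand IV, steps 8-9).  Arms are 8 bp, pseudo-duplexes 16 bp."
  ],
  "name": "J1",
  "topology_code": "J",
  "strands": {
    "I":   "CGCAATCCTGAGCACG",
    "II":  "CGTGCTCACCGAATGC",
    "III": "GCATTCGGACTATGGC",
    "IV":  "GCCATAGTGGATTGCG"
  },
  "pairing_blocks": [
    {"strand_a": "I",   "from_a": 1, "to_a": 8,  "strand_b": "IV", "from_b": 16},
    {"strand_a": "I",   "from_a": 9, "to_a": 16, "strand_b": "II", "from_b": 8},
    {"strand_a": "II",  "from_a": 9, "to_a": 16, "strand_b": "III", "from_b": 8},
    {"strand_a": "III", "from_a": 9, "to_a": 16, "strand_b": "IV", "from_b": 8}
  ],
  "helices": {
    "1,1": {"strand": "I",   "from": 1, "to": 16},
    "1,2": {"strand": "III", "from": 1, "to": 16},
    "2,1": {"strand": "II",  "from": 1, "to": 16},
    "2,2": {"strand": "IV",  "from": 1, "to": 16}
  },
  "crossovers": {
    "1": ["II", "IV"],
    "2": ["III", "I"]
  }
}
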