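{
  "_comment": [
    "Standard nucleic-acid base geometries in the standard base reference",
    "frame (Olson et al. consensus frame, Tsukuba convention): x points away",
    "from the minor-groove edge, y toward the paired base's C1', z along the",
    "helical rise; all bases are planar at z=0.  Coordinates in Angstrom.",
    "Ring atoms (purines: N9 C8 N7 C5 C6 N1 C2 N3 C4; pyrimidines: N1 C2 N3",
    "C4 C5 C6) are the frame-fitting set; C1' and exocyclic atoms are",
    "included for structure rebuilding only."
  ],
  "ring_atoms": {
    "A": ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"],
    "G": ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"],
    "C": ["N1", "C2", "N3", "C4", "C5", "C6"],
    "T": ["N1", "C2", "N3", "C4", "C5", "C6"]
  },
  "coordinates": {
    "A": {
      "C1'": [-2.479, 5.346, 0.0],
      "N9": [-1.291, 4.498, 0.0],
      "C8": [0.024, 4.897, 0.0],
      "N7": [0.877, 3.902, 0.0],
      "C5": [0.071, 2.771, 0.0],
      "C6": [0.369, 1.398, 0.0],
      "N6": [1.611, 0.909, 0.0],
      "N1": [-0.668, 0.532, 0.0],
      "C2": [-1.912, 1.023, 0.0],
      "N3": [-2.320, 2.290, 0.0],
      "C4": [-1.267, 3.124, 0.0]
    },
    "G": {
      "C1'": [-2.477, 5.399, 0.0],
      "N9": [-1.289, 4.551, 0.0],
      "C8": [0.023, 4.962, 0.0],
      "N7": [0.870, 3.969, 0.0],
      "C5": [0.071, 2.833, 0.0],
      "C6": [0.424, 1.460, 0.0],
      "O6": [1.554, 0.955, 0.0],
      "N1": [-0.700, 0.641, 0.0],
      "C2": [-2.022, 1.087, 0.0],
      "N2": [-2.979, 0.139, 0.0],
      "N3": [-2.342, 2.364, 0.0],
      "C4": [-1.265, 3.177, 0.0]
    },
    "C": {
      "C1'": [-2.477, 5.402, 0.0],
      "N1": [-1.285, 4.542, 0.0],
      "C2": [-1.472, 3.158, 0.0],
      "O2": [-2.628, 2.709, 0.0],
      "N3": [-0.391, 2.344, 0.0],
      "C4": [0.837, 2.868, 0.0],
      "N4": [1.875, 2.027, 0.0],
      "C5": [1.056, 4.275, 0.0],
      "C6": [-0.023, 5.068, 0.0]
    },
    "T": {
      "C1'": [-2.481, 5.354, 0.0],
      "N1": [-1.284, 4.500, 0.0],
      "C2": [-1.462, 3.135, 0.0],
      "O2": [-2.562, 2.608, 0.0],
      "N3": [-0.298, 2.407, 0.0],
      "C4": [0.994, 2.897, 0.0],
      "O4": [1.944, 2.119, 0.0],
      "C5": [1.106, 4.338, 0.0],
      "C7": [2.466, 4.961, 0.0],
      "C6": [-0.024, 5.057, 0.0]
    }
  }
}
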