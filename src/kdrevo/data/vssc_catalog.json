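{
  "version": "1.0",
  "description": "Vssc (voltage-sensitive sodium channel) amplicon architecture and kdr codon catalog for Aedes aegypti. Residue numbers follow the house-fly VSSC convention and are labels, not coordinates. All intervals are 0-based half-open columns on the region alignment.",
  "regions": {
    "E6-8": {
      "width": 482,
      "nominal_length": 482,
      "features": [
        {"name": "exon6", "kind": "exon", "start": 0, "end": 60},
        {"name": "intron6", "kind": "intron", "start": 60, "end": 200},
        {"name": "exon7", "kind": "exon", "start": 200, "end": 320},
        {"name": "intron7", "kind": "intron", "start": 320, "end": 420},
        {"name": "exon8", "kind": "exon", "start": 420, "end": 482}
      ]
    },
    "E20-21": {
      "width": 581,
      "nominal_length": 581,
      "features": [
        {"name": "exon20", "kind": "exon", "start": 0, "end": 180},
        {"name": "intron20", "kind": "intron", "start": 180, "end": 430},
        {"name": "exon21", "kind": "exon", "start": 430, "end": 581}
      ]
    },
    "E31-32": {
      "width": 1029,
      "nominal_length": 1029,
      "features": [
        {"name": "exon31", "kind": "exon", "start": 0, "end": 90},
        {"name": "intron31", "kind": "intron", "start": 90, "end": 190},
        {"name": "exon32", "kind": "exon", "start": 190, "end": 1029}
      ]
    }
  },
  "concatenation": {
    "order": ["E6-8", "codon410", "E20-21", "codon1534", "E31-32"],
    "comment": "Pattern sequence = E6-8 + V410L codon + E20-21 + F1534C codon + E31-32."
  },
  "loci": {
    "410": {
      "residue": 410,
      "location": "standalone",
      "codon_states": {"GTA": "V", "TTA": "L"},
      "susceptible_codons": ["GTA"],
      "resistance_residues": {"L": "410L"},
      "annotation_only": false
    },
    "982": {
      "residue": 982,
      "location": {"region": "E20-21", "start": 78, "end": 81},
      "codon_states": {"CTG": "L"},
      "susceptible_codons": ["CTG"],
      "resistance_residues": {"W": "982W"},
      "annotation_only": false
    },
    "989": {
      "residue": 989,
      "location": {"region": "E20-21", "start": 99, "end": 102},
      "codon_states": {"TCC": "S", "CCC": "P"},
      "susceptible_codons": ["TCC"],
      "resistance_residues": {"P": "989P"},
      "annotation_only": false
    },
    "1007": {
      "residue": 1007,
      "location": {"region": "E20-21", "start": 153, "end": 156},
      "codon_states": {"GCT": "A"},
      "susceptible_codons": ["GCT"],
      "resistance_residues": {"G": "1007G"},
      "annotation_only": false
    },
    "1011": {
      "residue": 1011,
      "location": {"region": "E20-21", "start": 165, "end": 168},
      "codon_states": {"ATT": "I"},
      "susceptible_codons": ["ATT"],
      "resistance_residues": {"M": "1011M", "V": "1011V"},
      "annotation_only": false
    },
    "1016": {
      "residue": 1016,
      "location": {"region": "E20-21", "start": 442, "end": 445},
      "codon_states": {"GTA": "V", "ATA": "I", "GGA": "G"},
      "susceptible_codons": ["GTA"],
      "resistance_residues": {"I": "1016I", "G": "1016G"},
      "annotation_only": false
    },
    "1534": {
      "residue": 1534,
      "location": "standalone",
      "codon_states": {"TTC": "F", "TGC": "C"},
      "susceptible_codons": ["TTC"],
      "resistance_residues": {"C": "1534C"},
      "annotation_only": false
    },
    "1835": {
      "residue": 1835,
      "location": {"region": "E31-32", "start": 400, "end": 403},
      "codon_states": {"CAA": "Q", "CGA": "R"},
      "susceptible_codons": ["CAA"],
      "resistance_residues": {"R": "1835R"},
      "annotation_only": true
    }
  },
  "sites": {
    "V410L": {"locus": "410", "mutant_residue": "L"},
    "L982W": {"locus": "982", "mutant_residue": "W"},
    "S989P": {"locus": "989", "mutant_residue": "P"},
    "A1007G": {"locus": "1007", "mutant_residue": "G"},
    "I1011M": {"locus": "1011", "mutant_residue": "M"},
    "I1011V": {"locus": "1011", "mutant_residue": "V"},
    "V1016G": {"locus": "1016", "mutant_residue": "G"},
    "V1016I": {"locus": "1016", "mutant_residue": "I"},
    "F1534C": {"locus": "1534", "mutant_residue": "C"},
    "Q1835R": {"locus": "1835", "mutant_residue": "R"}
  },
  "intron_groups": {
    "region": "E20-21",
    "feature": "intron20",
    "groups": {"A": 250, "B": 234}
  }
}
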