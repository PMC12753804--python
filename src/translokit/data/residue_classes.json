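{
  "_comment": [
    "Per-residue chemical classes used to annotate topologies.",
    "Atom names follow PDB v3 conventions. Backbone N/O donor/acceptor flags",
    "are added for every amino acid automatically.",
    "Charge conventions: Arg/Lys positive, Asp/Glu negative, His neutral",
    "(no protonation-state inference is attempted). Phosphate P/OP1/OP2 of",
    "nucleotides carry the negative charge; in coarse-grained models with a",
    "single P pseudo-atom this makes the phosphate a salt-bridge partner.",
    "Aromatic-ring atom lists define ring centroids for pi-stacking."
  ],
  "ALA": {"donor": [], "acceptor": [], "positive": [], "negative": [], "ring": [], "nonpolar": ["CB"]},
  "GLY": {"donor": [], "acceptor": [], "positive": [], "negative": [], "ring": [], "nonpolar": []},
  "VAL": {"donor": [], "acceptor": [], "positive": [], "negative": [], "ring": [], "nonpolar": ["CB", "CG1", "CG2"]},
  "LEU": {"donor": [], "acceptor": [], "positive": [], "negative": [], "ring": [], "nonpolar": ["CB", "CG", "CD1", "CD2"]},
  "ILE": {"donor": [], "acceptor": [], "positive": [], "negative": [], "ring": [], "nonpolar": ["CB", "CG1", "CG2", "CD1"]},
  "PRO": {"donor": [], "acceptor": [], "positive": [], "negative": [], "ring": [], "nonpolar": ["CB", "CG", "CD"]},
  "MET": {"donor": [], "acceptor": [], "positive": [], "negative": [], "ring": [], "nonpolar": ["CB", "CG", "SD", "CE"]},
  "PHE": {"donor": [], "acceptor": [], "positive": [], "negative": [], "ring": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"], "nonpolar": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"]},
  "TRP": {"donor": ["NE1"], "acceptor": [], "positive": [], "negative": [], "ring": ["CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"], "nonpolar": ["CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"]},
  "TYR": {"donor": ["OH"], "acceptor": ["OH"], "positive": [], "negative": [], "ring": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"], "nonpolar": ["CB", "CG", "CD1", "CD2", "CE1", "CE2"]},
  "SER": {"donor": ["OG"], "acceptor": ["OG"], "positive": [], "negative": [], "ring": [], "nonpolar": []},
  "THR": {"donor": ["OG1"], "acceptor": ["OG1"], "positive": [], "negative": [], "ring": [], "nonpolar": ["CG2"]},
  "CYS": {"donor": ["SG"], "acceptor": [], "positive": [], "negative": [], "ring": [], "nonpolar": ["CB", "SG"]},
  "ASN": {"donor": ["ND2"], "acceptor": ["OD1"], "positive": [], "negative": [], "ring": [], "nonpolar": []},
  "GLN": {"donor": ["NE2"], "acceptor": ["OE1"], "positive": [], "negative": [], "ring": [], "nonpolar": ["CB", "CG"]},
  "ASP": {"donor": [], "acceptor": ["OD1", "OD2"], "positive": [], "negative": ["OD1", "OD2", "CG"], "ring": [], "nonpolar": []},
  "GLU": {"donor": [], "acceptor": ["OE1", "OE2"], "positive": [], "negative": ["OE1", "OE2", "CD"], "ring": [], "nonpolar": ["CB", "CG"]},
  "LYS": {"donor": ["NZ"], "acceptor": [], "positive": ["NZ"], "negative": [], "ring": [], "nonpolar": ["CB", "CG", "CD"]},
  "ARG": {"donor": ["NE", "NH1", "NH2"], "acceptor": [], "positive": ["NE", "NH1", "NH2", "CZ"], "negative": [], "ring": [], "nonpolar": ["CB", "CG"]},
  "HIS": {"donor": ["ND1", "NE2"], "acceptor": ["ND1", "NE2"], "positive": [], "negative": [], "ring": ["CG", "ND1", "CD2", "CE1", "NE2"], "nonpolar": ["CB"]},
  "DA": {"donor": ["N6"], "acceptor": ["N1", "N3", "N7", "OP1", "OP2", "O4'"], "positive": [], "negative": ["P", "OP1", "OP2"], "ring": ["N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6"], "nonpolar": ["C1'", "C2'", "C3'", "C4'", "C5'"]},
  "DG": {"donor": ["N1", "N2"], "acceptor": ["N3", "N7", "O6", "OP1", "OP2", "O4'"], "positive": [], "negative": ["P", "OP1", "OP2"], "ring": ["N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6"], "nonpolar": ["C1'", "C2'", "C3'", "C4'", "C5'"]},
  "DC": {"donor": ["N4"], "acceptor": ["N3", "O2", "OP1", "OP2", "O4'"], "positive": [], "negative": ["P", "OP1", "OP2"], "ring": ["N1", "C2", "N3", "C4", "C5", "C6"], "nonpolar": ["C1'", "C2'", "C3'", "C4'", "C5'"]},
  "DT": {"donor": ["N3"], "acceptor": ["O2", "O4", "OP1", "OP2", "O4'"], "positive": [], "negative": ["P", "OP1", "OP2"], "ring": ["N1", "C2", "N3", "C4", "C5", "C6"], "nonpolar": ["C1'", "C2'", "C3'", "C4'", "C5'", "C7"]}
}
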