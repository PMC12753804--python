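{
  "_comment": "Disease-associated missense mutations of human XPD (1-based residue numbering). paper_class is the literature's structural class annotation (A: DNA binding/translocation, B: nucleotide binding or ATPase-cleft dynamics, C: indirect/distal); the rule-based classifier recomputes the class from contact tables and disagreements are surfaced.",
  "mutations": [
    {"position": 112, "wild_type": "R", "substitutions": ["H", "C"], "phenotype": "XP/TTD", "paper_class": "A"},
    {"position": 76, "wild_type": "T", "substitutions": ["A"], "phenotype": "XP", "paper_class": "A"},
    {"position": 511, "wild_type": "R", "substitutions": ["Q"], "phenotype": "XP", "paper_class": "A"},
    {"position": 541, "wild_type": "S", "substitutions": ["R"], "phenotype": "XP", "paper_class": "A"},
    {"position": 542, "wild_type": "Y", "substitutions": ["C"], "phenotype": "XP", "paper_class": "A"},
    {"position": 601, "wild_type": "R", "substitutions": ["L", "W"], "phenotype": "XP", "paper_class": "A"},
    {"position": 681, "wild_type": "D", "substitutions": ["G", "N", "H"], "phenotype": "XP", "paper_class": "A"},
    {"position": 683, "wild_type": "R", "substitutions": ["W", "Q"], "phenotype": "XP", "paper_class": "A"},
    {"position": 18, "wild_type": "Y", "substitutions": ["H"], "phenotype": "XP/TTD", "paper_class": "B"},
    {"position": 234, "wild_type": "D", "substitutions": ["N"], "phenotype": "XP", "paper_class": "B"},
    {"position": 461, "wild_type": "L", "substitutions": ["V"], "phenotype": "XP/CS", "paper_class": "B"},
    {"position": 666, "wild_type": "R", "substitutions": ["W"], "phenotype": "XP/CS", "paper_class": "B"},
    {"position": 47, "wild_type": "G", "substitutions": ["R"], "phenotype": "XP/CS", "paper_class": "C"},
    {"position": 602, "wild_type": "G", "substitutions": ["D"], "phenotype": "XP/CS", "paper_class": "C"}
  ]
}
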