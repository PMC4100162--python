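# Functional annotation of Zea mays cysteine protease 1 (zmCP1), mature-enzyme
# numbering.  Papain-family (C1A) protease: Cys-His-Asn triad, Gln/Cys oxyanion
# hole, S1/S2 specificity subsites.
catalytic_triad: [149, 285, 306]      # Cys149, His285, Asn306
oxyanion_hole: [143, 149]             # Gln143 (NE2), Cys149 (backbone N)
subsites:
  S1: [147, 189, 190, 191]            # Gly147, Cys189, Asp190, Gly191
  # S2 membership of Ala259 is reported inconsistently in the source
  # literature; it is included here and can be removed by overriding this file.
  S2: [193, 194, 259, 283, 286]       # Leu193, Met194, Ala259, Leu283, Ala286
nucleophile_atom:
  residue: 149
  atom: SG                            # catalytic cysteine thiolate sulfur
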