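# Residue-class table used by the interaction fingerprint.  Classes may
# overlap (His is aromatic, polar and charged).  Override by passing your own
# table of the same shape.
hydrophobic: [ALA, VAL, LEU, ILE, MET, PHE, PRO, GLY]
aromatic: [PHE, TYR, TRP, HIS]
polar: [SER, THR, ASN, GLN, CYS, TYR, HIS, TRP]
charged: [ASP, GLU, LYS, ARG, HIS]
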