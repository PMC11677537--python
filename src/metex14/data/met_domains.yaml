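# Protein-domain table for human Met (UniProt P08581 numbering).
# The juxtamembrane (JM) region is encoded largely by exon 14 and carries
# the c-Cbl docking site (Y1003); the tyrosine-kinase (TK) domain bounds
# follow the UniProt kinase-domain annotation.  Residues outside every
# configured domain map to "other".
domains:
  - {name: JM, start: 956, end: 1009}
  - {name: TK, start: 1078, end: 1345}
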