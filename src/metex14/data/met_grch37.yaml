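# MET (hepatocyte growth factor receptor) exon model, GRCh37.p13.
# Coordinates are 1-based closed intervals for exons 13-15 of the canonical
# transcript NM_000245 (MET-201), transcribed from the GRCh37.p13 RefSeq
# annotation; exon 14 is the 141-bp in-frame exon whose skipping fuses
# exon 13 to exon 15 in the tumour transcript.  Override this file to use
# other coordinates or another transcript.
gene_symbol: MET
chromosome: "7"
strand: "+"
transcript_id: NM_000245
exons:
  - {number: 13, start: 116411552, end: 116411697}
  - {number: 14, start: 116411903, end: 116412043}
  - {number: 15, start: 116414935, end: 116415165}
# Splice-window extents (bp).  The acceptor window covers the 3' end of
# intron 13 plus the first exonic bases; the donor window covers the last
# exonic bases plus the 5' end of intron 14.  Extents follow common
# clinical METex14 reporting practice and are fully configurable.
window_config:
  acceptor_intronic_bp: 25
  acceptor_exonic_bp: 2
  donor_exonic_bp: 2
  donor_intronic_bp: 10
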