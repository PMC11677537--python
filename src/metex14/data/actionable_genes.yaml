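# Actionability gene sets for the co-occurring-variant screen.
#
# actionable_lung: genes with an approved or guideline-recommended targeted
#   therapy in NSCLC (ASCO/ESMO panel).
# actionable_any_solid: additionally, genes actionable in at least one other
#   solid-tumour indication but not in lung cancer.
actionable_lung:
  [EGFR, ALK, ROS1, ERBB2, MET, BRAF, KRAS, RET, NTRK1, NTRK2, NTRK3]
actionable_any_solid:
  [EGFR, ALK, ROS1, ERBB2, MET, BRAF, KRAS, RET, NTRK1, NTRK2, NTRK3,
   ESR1, ERBB4, PIK3CA, IDH2, MTOR]
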