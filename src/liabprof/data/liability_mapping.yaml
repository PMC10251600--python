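# Target-to-liability-group reference mapping.
#
# Groups: CV cardiovascular, CNS central nervous system, GI gastrointestinal,
# ED endocrine disruption, PU pulmonary, RE renal, IM immune.
# Targets may belong to more than one group (e.g. DRD1/DRD2).
#
# Note: the source reference labels the cardiovascular group with 25 targets
# but enumerates 24 symbols, and the union of all listed symbols is 45
# unique targets against a stated panel of 46. This file follows the printed
# lists verbatim rather than inventing the missing entry.
CV:
  [ACHE, ADORA2A, ADRA1A, ADRA2A, ADRB2, AVPR1A, CHRM1, DRD1, DRD2, HRH1,
   HRH2, HTR1B, HTR2A, HTR2B, KCNH2, MAOA, OPRD1, OPRK1, OPRM1, PDE3A,
   PTGS2, SCN5A, SLC6A2, SLC6A4]
CNS:
  [ADORA2A, ADRA1A, ADRA2A, CHRM1, CNR1, DRD1, DRD2, EDNRA, HTR1A, HTR1B,
   HTR2A, MAOA, OPRD1, OPRK1, OPRM1, PDE4D, SLC6A2, SLC6A3, SLC6A4]
GI:
  [ACHE, ADRA1A, ADRB1, CCKAR, CHRM1, CHRM3, HRH2, HTR3A, OPRK1, OPRM1,
   PPARA, PPARD, PTGS1]
ED:
  [AR, DRD2, EDNRA, ESR1, HTR1A, HTR3A, NR3C1]
PU:
  [ACHE, ADRB2, CHRM3, HTR2B, PTGS1]
RE:
  [AVPR1A, PTGS1]
IM:
  [CNR2, HRH1, LCK, NR3C1, PDE4D, PTGS2]
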