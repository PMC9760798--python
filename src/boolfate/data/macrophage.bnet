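# Curated macrophage polarization mini-network (17 nodes).
# Environmental cytokines and the hypoxia/metabolic factors are identity-rule
# inputs: their value persists, modeling a held microenvironment condition.
# Each TF rule encodes one documented interaction set:
#   STAT1: activated by IFNG; repressed by STAT6
#   NFKB:  activated by TNFA, GMCSF or IL1B; repressed by STAT6
#          (the GMCSF route is an interpretation choice; the pro-inflammatory
#          action of GMCSF is routed through NFKB here)
#   AP1:   activated by IL6 or IL1B; repressed by STAT6 and by PPARG
#          (PPARG->AP1 negative feedback)
#   STAT3: activated independently by IL10, IL6 or TGFB; repressed by SOCS3
#   STAT6: activated by IL4, PPARG or KLF4
#   SOCS3: activated by STAT1 or NFKB
targets, factors
IFNG, IFNG
GMCSF, GMCSF
IL4, IL4
IL6, IL6
IL10, IL10
IL1B, IL1B
TNFA, TNFA
TGFB, TGFB
HIF1A, HIF1A
PPARG, PPARG
KLF4, KLF4
STAT1, IFNG & !STAT6
NFKB, (TNFA | GMCSF | IL1B) & !STAT6
AP1, (IL6 | IL1B) & !STAT6 & !PPARG
STAT3, (IL10 | IL6 | TGFB) & !SOCS3
STAT6, IL4 | PPARG | KLF4
SOCS3, STAT1 | NFKB
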