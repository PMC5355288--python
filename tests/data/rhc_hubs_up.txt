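# Reported hub genes of the up-regulated-gene network in the RHC (red hair
# color MC1R variant) co-culture analysis (GSE44805-derived interactome study).
# BUB1B and SNX2 entered by betweenness rescue despite low degree.
GBAS
PRKAA1
ICT1
ATG4C
ATG10
PIK3C3
PCNA
CDK1
BRCA1
RPA1
BUB1B
SNX2
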