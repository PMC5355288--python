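# Reported hub genes of the down-regulated-gene network in the RHC (red hair
# color MC1R variant) co-culture analysis (GSE44805-derived interactome study).
GABARAPL2
SQSTM1
GABARAPL1
MAP1LC3B
WIPI2
MAP1LC3A
CLN3
YWHAG
SMAD3
TRAF2
PABPC1
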