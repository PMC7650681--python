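# Homologous-recombination panel genes (13)
ATM
BARD1
BRCA1
BRCA2
BRIP1
MUS81
PALB2
POLD1
RAD50
RAD51B
RAD51C
RAD51D
XRCC2
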