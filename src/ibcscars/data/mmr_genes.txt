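# Mismatch-repair panel genes (6)
MLH1
MLH3
MSH2
MSH3
MSH6
PMS2
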