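>MT2_HUMAN metallothionein-2, 61 aa, 20 Cys
MDPNCSCAAGDSCTCAGSCKCKECKCTSCKKSCCSCCPVGCAKCAQGCICKGASDKCSCCA
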