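# Extended LIR (xLIR) consensus: one line per window position,
# residues allowed at that position as a contiguous string.
ADEFGLPRSK
DEGMSTV
WFY
DEILQTV
ADEFHIKLMPSTV
ILV
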