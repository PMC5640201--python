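# W/F/Y-x-x-I/L/V core consensus: one line per core position.
WFY
ACDEFGHIKLMNPQRSTVWY
ACDEFGHIKLMNPQRSTVWY
ILV
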