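# Default PSSM training set: 6-residue windows (2 residues of upstream
# context + 4-residue core) around experimentally characterised canonical
# LIR motifs, compiled from the autophagy literature. This is a replaceable
# curated default, not a definitive census; swap in your own TSV to retrain.
# Columns: window<TAB>source_protein<TAB>organism
DDWTHL	SQSTM1/p62	Homo sapiens
EDYIII	NBR1	Homo sapiens
DSFVEI	OPTN	Homo sapiens
DSYEVL	FUNDC1	Homo sapiens
NSWVEL	BNIP3L/NIX	Homo sapiens
DDFVMI	ATG13	Homo sapiens
DDFVMV	ULK1	Homo sapiens
LTWEEL	Atg19	Saccharomyces cerevisiae
SHFVSI	M2	Influenza A virus
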