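ref_id	sequence	annotation
SYN-IMM-01	STPPQVSNEVLKAH	synthetic demonstration entry; serine/threonine-rich secreted-peptide-like motif
SYN-IMM-02	VQGPSSDKEAALQ	synthetic demonstration entry; polar surface-layer-like motif
SYN-IMM-03	LDAVHAEGMAIVAK	synthetic demonstration entry; amphipathic helical motif
SYN-IMM-04	GDSIQNEVDHALK	synthetic demonstration entry; acidic cytoplasmic-loop-like motif
SYN-IMM-05	TNVAGESLIDSAMQ	synthetic demonstration entry; polar transglycosylase-like motif
SYN-IMM-06	ADQVESNIGHTLSE	synthetic demonstration entry; acidic beta-strand-like motif
SYN-IMM-07	MSIDENAVQTLHG	synthetic demonstration entry; mixed-polarity linker-like motif
SYN-IMM-08	QAVHDSELNIGTSM	synthetic demonstration entry; polar hydrolase-surface-like motif
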