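sample_id	coverage_class
DDRD_P02	GENOME
DDRD_P03	EXOME
DDRD_P04	EXOME
DDRD_P06	EXOME
DDRD_P07	EXOME
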