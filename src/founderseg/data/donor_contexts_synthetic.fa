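>HSPG2_intron54_donor authentic_offset=40 exon_length_bp=136 strand=+ note=synthetic_context_for_c.7006+1G>A
ACAACAACAACAACAACAACAACAACAACAACAACAACAGGTAAGCGTCACACACACACA
CACACACACACACACACACACA
>HSPG2_intron84_donor authentic_offset=40 exon_length_bp=110 strand=+ note=synthetic_context_for_c.11562+2T>G
ACAACAACAACAACAACAACGTCACACACACACACACAAGGTAAGCCACACACACACACA
CACACACACACACGTCACACACACA
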