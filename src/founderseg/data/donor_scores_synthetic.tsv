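# Donor 9-mer (3 exonic + 6 intronic) -> 5' splice-site strength.
# Synthetic fixture table: the 9-mers are those of the synthetic donor
# contexts packaged alongside; the scores are the published MaxEnt-style
# values for the corresponding authentic and candidate cryptic donors.
CAGGTAAGC	9.40
AGCGTCACA	-6.23
AAGGTAAGC	6.54
AACGTCACA	-11.07
CACGTCACA	-11.54
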