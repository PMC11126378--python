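# Perlecan domain codon ranges on NM_001291860.2 protein coordinates.
# Only domain IV (21 immunoglobulin-like repeats) has a published codon
# range; add further closed, non-overlapping intervals as needed.
domain IV	1695	3655
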