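>miR390 canonical 21-mer (ath-miR390a-type); user-replaceable reference
AAGCUCAGGAGGGAUAGCGCC
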