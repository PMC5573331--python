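>tasiARF_D7 canonical ARF-targeting tasiRNA 21-mer (Arabidopsis TAS3 5'D7(+)-type); user-replaceable reference
UUCUUGACCUUGUAAGACCCC
>tasiARF_D8 canonical ARF-targeting tasiRNA 21-mer (Arabidopsis TAS3 5'D8(+)-type); user-replaceable reference
UUCUUGACCUUGUAAGGCCUU
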