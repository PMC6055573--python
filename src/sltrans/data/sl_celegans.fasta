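>SL1 class=SL1
GGTTTAATTACCCAAGTTTGAG
>SL2 class=SL2
GGTTTTAACCCAGTTACTCAAG
>SL3 class=SL2
GGTTTTAACCCAGTTAACCAAG
>SL4 class=SL2
GGTTTTAACCCAGTTTAACCAAG
>SL5 class=SL2
GGTTTTAACCCAGTTACCAAG
>SL6 class=SL2
GGTTTAAAACCCAGTTACCAAG
>SL7 class=SL2
GGTTTTAACCCAGTTAATTGAG
>SL8 class=SL2
GGTTTTTACCCAGTTAACCAAG
>SL9 class=SL2
GGTTTATACCCAGTTAACCAAG
>SL10 class=SL2
GGTTTTAACCCAAGTTAACCAAG
>SL11 class=SL2
GGTTTTAACCAGTTAACTAAG
>SL12 class=SL2
GGTTTTAACCCATATAACCAAG
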